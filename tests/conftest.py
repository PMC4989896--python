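import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from kqdist.io_readsets import ReadRecord, ReadSet


@pytest.fixture
def rng():
    return np.random.default_rng(20160812)


@pytest.fixture
def toy_readset():
    """One read AAC with flat Q30."""
    return ReadSet("toy", [ReadRecord("r1", "AAC", [30, 30, 30])])


@pytest.fixture
def small_pair(rng):
    """Two small random read sets from related sequences."""
    from kqdist.simulate import ReadSimConfig, random_sequence, sample_reads

    seq = random_sequence(400, seed=rng)
    cfg = ReadSimConfig(M=20, beta=60, mismatch_prob=0.05, quality_spread=5)
    a = sample_reads(seq, cfg, label="a", seed=rng)
    b = sample_reads(seq, cfg, label="b", seed=rng)
    return a, b


@pytest.fixture
def fastq_file(tmp_path):
    path = tmp_path / "sample.fastq"
    path.write_text(
        "@r1\nACGT\n+\nIIII\n"
        "@r2\nTTAA\n+\n!I5I\n"
    )
    return path


def write_fastq_text(path, records):
    """records: list of (id, seq, qual_string)."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return path


@pytest.fixture
def make_fastq(tmp_path):
    def _make(name, records):
        return write_fastq_text(tmp_path / name, records)

    return _make
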