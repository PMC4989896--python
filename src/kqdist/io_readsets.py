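"""FASTQ input/output with phred decoding, and sample-list handling.

Only strict 4-line-per-record FASTQ is accepted (no wrapped records).
Qualities are decoded as ``ord(char) - offset`` with offset 33 (default)
or 64; a negative decoded score raises :class:`PhredDialectError`
suggesting the other dialect.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import FastqParseError, PhredDialectError, SampleListError

__all__ = [
    "ReadRecord",
    "ReadSet",
    "quality_to_error_prob",
    "read_correctness_prob",
    "read_fastq",
    "write_fastq",
    "load_sample_list",
]

_VALID_BASES = frozenset("ACGTN")
PHRED_OFFSETS = (33, 64)


@dataclass
class ReadRecord:
    """A single read: id, sequence over {A,C,G,T,N}, per-base phred scores."""

    id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.qualities) != len(self.sequence):
            raise FastqParseError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if len(self.qualities) and self.qualities.min() < 0:
            raise PhredDialectError(
                f"record {self.id!r}: negative phred score "
                f"{int(self.qualities.min())}; wrong --phred-offset? "
                "(try the other of 33/64)"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FastqParseError(
                f"record {self.id!r}: invalid bases {sorted(bad)} "
                "(DNA only: A,C,G,T,N)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    """A labelled collection of reads — the unit of comparison.

    ``M`` is the number of *original* reads (before any reverse-complement
    supplementation); ``supplemented`` records whether the set already
    contains the complements.
    """

    label: str
    reads: list = field(default_factory=list)
    supplemented: bool = False

    def __post_init__(self):
        if not self.supplemented:
            self._M = len(self.reads)
        else:
            self._M = len(self.reads) // 2

    @property
    def M(self) -> int:
        return self._M

    @property
    def beta(self) -> float:
        """Read length: exact if uniform, otherwise the mean."""
        if not self.reads:
            raise ValueError(f"read set {self.label!r} is empty")
        return float(np.mean([len(r) for r in self.reads]))

    @property
    def uniform_length(self) -> bool:
        lengths = {len(r) for r in self.reads}
        return len(lengths) <= 1

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


def quality_to_error_prob(q) -> float:
    """Error probability implied by a phred score: 10^(−q/10)."""
    if q < 0:
        raise ValueError(f"phred score must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def read_correctness_prob(read: ReadRecord) -> float:
    """Probability the whole read is correct: ∏_j (1 − 10^(−Q(j)/10))."""
    if len(read) == 0:
        raise ValueError("empty read")
    q = np.asarray(read.qualities, dtype=float)
    return float(np.prod(1.0 - 10.0 ** (-q / 10.0)))


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path, phred_offset: int = 33, label: str | None = None) -> ReadSet:
    """Parse a strict 4-line-per-record FASTQ file into a :class:`ReadSet`."""
    if phred_offset not in PHRED_OFFSETS:
        raise ValueError(f"phred_offset must be one of {PHRED_OFFSETS}")
    if not os.path.exists(path):
        raise FastqParseError(f"no such file: {path}")
    reads = []
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(
                    f"{path}:{lineno}: expected '@' header, got {header[:30]!r} "
                    "(wrapped/multi-line FASTQ is not supported)"
                )
            rid = header[1:].split()[0] if len(header) > 1 else f"read{lineno}"
            seq = fh.readline().rstrip("\n").upper()
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            lineno += 3
            if not plus.startswith("+"):
                raise FastqParseError(
                    f"{path}: record {rid!r}: expected '+' separator "
                    "(wrapped/multi-line FASTQ is not supported)"
                )
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: record {rid!r}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            scores = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                np.int16
            ) - phred_offset
            if len(scores) and scores.min() < 0:
                other = 33 if phred_offset == 64 else 64
                raise PhredDialectError(
                    f"{path}: record {rid!r}: negative phred score with "
                    f"offset {phred_offset}; try --phred-offset {other}"
                )
            reads.append(ReadRecord(rid, seq, scores))
    if label is None:
        label = os.path.basename(str(path))
        for ext in (".gz", ".fastq", ".fq"):
            if label.endswith(ext):
                label = label[: -len(ext)]
    return ReadSet(label=label, reads=reads)


def write_fastq(readset: ReadSet, path, phred_offset: int = 33) -> None:
    """Write a ReadSet as 4-line FASTQ; round-trips exactly with read_fastq."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in readset:
            qual = "".join(chr(int(q) + phred_offset) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def load_sample_list(path) -> list:
    """Parse a file-of-files: one ``path[TAB]label`` per line, '#' comments.

    Returns an ordered list of (label, path) tuples; the order defines
    matrix row/column order. Labels default to file basenames.
    """
    entries = []
    base = os.path.dirname(os.path.abspath(str(path)))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            fpath = parts[0].strip()
            if not os.path.isabs(fpath):
                fpath = os.path.join(base, fpath)
            if not os.path.exists(fpath):
                raise SampleListError(
                    f"{path}:{lineno}: no such file: {parts[0].strip()}"
                )
            if len(parts) > 1 and parts[1].strip():
                label = parts[1].strip()
            else:
                label = os.path.basename(fpath)
                for ext in (".gz", ".fastq", ".fq"):
                    if label.endswith(ext):
                        label = label[: -len(ext)]
            entries.append((label, fpath))
    if not entries:
        raise SampleListError(f"{path}: empty sample list — nothing to compare")
    labels = [lbl for lbl, _ in entries]
    dupes = {lbl for lbl in labels if labels.count(lbl) > 1}
    if dupes:
        raise SampleListError(
            f"{path}: duplicate sample labels {sorted(dupes)} — "
            "matrix rows would be ambiguous"
        )
    return entries
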