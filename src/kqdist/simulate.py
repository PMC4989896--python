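"""Synthetic data: evolved sequence families with a known tree, reads
with phred-calibrated errors, and metagenome mixtures — plus the two
benchmark pipelines (phylogeny reconstruction, metagenome clustering).

All generators are pure functions of their seed; per-replicate and
per-sample streams are derived with numpy SeedSequence spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_readsets import ReadRecord, ReadSet
from .kmer_core import _CODE  # shared base <-> code tables
from .measures import canonical_measure, pairwise_matrices
from .phylo import (
    Tree,
    TreeNode,
    clustering_accuracy,
    discriminating_node_height,
    robinson_foulds,
    upgma,
)

__all__ = [
    "EvolutionConfig",
    "ReadSimConfig",
    "MetagenomeSpec",
    "random_sequence",
    "evolve_family",
    "sample_reads",
    "make_metagenome",
    "make_disjoint_metagenome_specs",
    "run_phylogeny_benchmark",
    "run_metagenome_benchmark",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _str_to_codes(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes.astype(np.int64)


def random_sequence(length: int, gc: float = 0.5, seed=None) -> str:
    """i.i.d. DNA with the requested GC fraction (split evenly G/C)."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0,1]")
    rng = _rng(seed)
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]  # A C G T
    return _codes_to_str(rng.choice(4, size=length, p=probs))


@dataclass
class EvolutionConfig:
    root_length: int = 5000
    n_sequences: int = 50
    relatedness: float = 70.0  # expected substitutions per 100 sites per edge
    indel_rate: float = 0.0
    gc: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.root_length <= 0:
            raise ValueError("root_length must be positive")
        if self.n_sequences < 2:
            raise ValueError("need at least 2 sequences")
        if self.relatedness < 0:
            raise ValueError("relatedness must be >= 0")


def _mutate(codes: np.ndarray, sub_prob: float, indel_rate: float,
            rng) -> np.ndarray:
    out = codes.copy()
    if sub_prob > 0:
        mask = rng.random(len(out)) < sub_prob
        if mask.any():
            # substituted base uniform over the other three
            out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()))
                         ) % 4
    if indel_rate > 0:
        events = rng.random(len(out)) < indel_rate
        if events.any():
            pieces = []
            prev = 0
            for pos in np.nonzero(events)[0]:
                pieces.append(out[prev:pos])
                if rng.random() < 0.5:  # deletion: drop this site
                    prev = pos + 1
                else:  # insertion: keep site, add a random base after it
                    pieces.append(out[pos:pos + 1])
                    pieces.append(rng.integers(0, 4, size=1))
                    prev = pos + 1
            pieces.append(out[prev:])
            out = np.concatenate(pieces)
    return out


def evolve_family(config: EvolutionConfig):
    """Random bifurcating topology with point substitutions down the tree.

    Returns ``(leaf_sequences, true_tree)`` where leaf_sequences is a
    list of (label, sequence) in label order S1..Sn.
    """
    rng = _rng(config.seed)
    root_codes = _str_to_codes(
        random_sequence(config.root_length, config.gc, rng))
    n = config.n_sequences
    leaves = [TreeNode(label=f"S{i + 1}", height=0.0) for i in range(n)]
    active = list(leaves)
    # coalescent-style ultrametric heights: joins at increasing depth,
    # root at relatedness/100 substitutions per site from every leaf
    total = config.relatedness / 100.0
    step = 0
    while len(active) > 1:
        step += 1
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        h = total * step / (n - 1)
        parent = TreeNode(children=[a, b], height=h, merge_value=2.0 * h)
        a.length = h - a.height
        b.length = h - b.height
        active[i] = parent
        active.pop(j)
    tree = Tree(root=active[0])

    seqs = {}

    def descend(node, codes):
        for child in node.children:
            child_codes = _mutate(codes, min(child.length, 0.75),
                                  config.indel_rate, rng)
            if child.is_leaf:
                seqs[child.label] = _codes_to_str(child_codes)
            else:
                descend(child, child_codes)

    descend(tree.root, root_codes)
    ordered = [(f"S{i + 1}", seqs[f"S{i + 1}"]) for i in range(n)]
    return ordered, tree


@dataclass
class ReadSimConfig:
    M: int = 300
    beta: int = 300
    mismatch_prob: float = 0.1
    quality_spread: int = 0  # per-base phred drawn uniform in Q0 +/- spread
    max_quality: int = 40
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.mismatch_prob < 1.0:
            raise ValueError("mismatch_prob must be in [0,1)")
        if self.M <= 0 or self.beta <= 0:
            raise ValueError("M and beta must be positive")

    def coverage(self, genome_length: int) -> float:
        return self.beta * self.M / genome_length

    @property
    def base_quality(self) -> int:
        if self.mismatch_prob <= 0:
            return self.max_quality
        return int(round(-10.0 * math.log10(self.mismatch_prob)))


def _simulate_read_block(seq_codes: np.ndarray, m: int, config: ReadSimConfig,
                         rng):
    """(bases, quals) arrays of shape (m, beta) for m reads from one genome."""
    beta = config.beta
    n = len(seq_codes)
    if beta > n:
        raise ValueError(f"read length {beta} exceeds sequence length {n}")
    starts = rng.integers(0, n - beta + 1, size=m)
    windows = seq_codes[starts[:, None] + np.arange(beta)[None, :]]
    rev = rng.random(m) < 0.5
    windows[rev] = 3 - windows[rev][:, ::-1]  # reverse complement
    q0 = config.base_quality
    if config.quality_spread > 0:
        lo = max(q0 - config.quality_spread, 1)
        hi = min(q0 + config.quality_spread, config.max_quality)
        quals = rng.integers(lo, hi + 1, size=(m, beta))
    else:
        quals = np.full((m, beta), q0, dtype=np.int64)
    if config.mismatch_prob > 0:
        perr = 10.0 ** (-quals / 10.0)
        flips = rng.random((m, beta)) < perr
        nflip = int(flips.sum())
        if nflip:
            windows[flips] = (windows[flips]
                              + rng.integers(1, 4, size=nflip)) % 4
    return windows, quals


def sample_reads(sequence: str, config: ReadSimConfig,
                 label: str = "sample", seed=None) -> ReadSet:
    """M reads of length beta: uniform start, either strand, per-base
    substitution errors with exactly-calibrated emitted qualities
    (Q = round(−10·log10 p) for each base's true error probability p)."""
    rng = _rng(seed if seed is not None else config.seed)
    codes = _str_to_codes(sequence)
    windows, quals = _simulate_read_block(codes, config.M, config, rng)
    reads = [
        ReadRecord(f"{label}_r{i}", _codes_to_str(windows[i]),
                   quals[i].astype(np.int16))
        for i in range(config.M)
    ]
    return ReadSet(label=label, reads=reads)


@dataclass
class MetagenomeSpec:
    """A mixture of genomes with relative abundances."""

    genomes: list  # list of (label, sequence)
    weights: list = field(default_factory=list)
    reads_total: int = 10000

    def __post_init__(self):
        if not self.genomes:
            raise ValueError("need at least one genome")
        if not self.weights:
            self.weights = [1.0 / len(self.genomes)] * len(self.genomes)
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("abundance weights must be >= 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundance weights sum to {w.sum()}, not 1")
        self.weights = list(w)


def make_metagenome(spec: MetagenomeSpec, read_config: ReadSimConfig,
                    label: str = "metagenome", seed=None) -> ReadSet:
    """Sample a read set from the mixture: each read's source genome is
    drawn from the abundance profile, then sequenced as in sample_reads."""
    rng = _rng(seed if seed is not None else read_config.seed)
    n_genomes = len(spec.genomes)
    sources = rng.choice(n_genomes, size=spec.reads_total, p=spec.weights)
    counts = np.bincount(sources, minlength=n_genomes)
    reads = []
    idx = 0
    for g, (glabel, seq) in enumerate(spec.genomes):
        m = int(counts[g])
        if m == 0:
            continue
        windows, quals = _simulate_read_block(
            _str_to_codes(seq), m, read_config, rng)
        for i in range(m):
            reads.append(ReadRecord(f"{label}_r{idx}",
                                    _codes_to_str(windows[i]),
                                    quals[i].astype(np.int16)))
            idx += 1
    return ReadSet(label=label, reads=reads)


def make_disjoint_metagenome_specs(n_genomes: int = 10,
                                   genome_length: int = 50000,
                                   reads_total: int = 20000,
                                   seed=None):
    """Two metagenome types with disjoint genome content and equal
    abundances — the 'two distinct communities' regime."""
    rng = _rng(seed)
    specs = []
    for t in ("A", "B"):
        genomes = [
            (f"type{t}_g{i}", random_sequence(genome_length, seed=rng))
            for i in range(n_genomes)
        ]
        specs.append(MetagenomeSpec(genomes=genomes, reads_total=reads_total))
    return specs[0], specs[1]


def run_phylogeny_benchmark(evolution: EvolutionConfig,
                            reads: ReadSimConfig,
                            k: int = 7,
                            measures=("d2", "d2star", "d2q", "d2qstar"),
                            replicates: int = 10,
                            seed=None) -> pd.DataFrame:
    """Evolve a family, sample reads per leaf, build UPGMA trees per
    measure, score Robinson–Foulds against the true tree; averaged over
    replicates.

    Returns a DataFrame indexed by measure with one column per replicate
    and a ``mean_rf`` column.
    """
    measures = [canonical_measure(m) for m in measures]
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(replicates)
    rows = {m: [] for m in measures}
    for rep, rep_ss in enumerate(rep_seeds):
        child = rep_ss.spawn(2)
        evo = EvolutionConfig(**{**evolution.__dict__,
                                 "seed": np.random.default_rng(child[0])})
        family, true_tree = evolve_family(evo)
        read_rng = np.random.default_rng(child[1])
        samples = [
            sample_reads(seq, reads, label=lbl, seed=read_rng)
            for lbl, seq in family
        ]
        mats = pairwise_matrices(samples, k=k, measures=measures)
        for mat in mats:
            est = upgma(mat)
            rows[mat.measure_name].append(robinson_foulds(est, true_tree))
    df = pd.DataFrame(
        {f"rep{r + 1}": [rows[m][r] for m in measures]
         for r in range(replicates)},
        index=list(measures),
    )
    df["mean_rf"] = df.mean(axis=1)
    df.index.name = "measure"
    return df


def run_metagenome_benchmark(spec_a: MetagenomeSpec, spec_b: MetagenomeSpec,
                             reads: ReadSimConfig,
                             samples_per_type: int = 5,
                             k: int = 8,
                             measure: str = "d2qstar",
                             seed=None) -> dict:
    """Sample replicate metagenomes of two types, cluster the chosen
    dissimilarity matrix (UPGMA = average linkage), and score the
    two-class partition.

    Returns {'accuracy': fraction, 'height': merge value or None,
    'matrix': DissimilarityMatrix, 'tree': Tree, 'partition': dict}.
    """
    measure = canonical_measure(measure)
    ss = np.random.SeedSequence(seed)
    sample_seeds = ss.spawn(2 * samples_per_type)
    samples = []
    partition = {}
    for t, spec in (("A", spec_a), ("B", spec_b)):
        for i in range(samples_per_type):
            label = f"{t}{i + 1}"
            idx = (0 if t == "A" else samples_per_type) + i
            rs = make_metagenome(spec, reads, label=label,
                                 seed=np.random.default_rng(sample_seeds[idx]))
            samples.append(rs)
            partition[label] = t
    (mat,) = pairwise_matrices(samples, k=k, measures=[measure])
    tree = upgma(mat)
    return {
        "accuracy": clustering_accuracy(tree, partition),
        "height": discriminating_node_height(tree, partition),
        "matrix": mat,
        "tree": tree,
        "partition": partition,
    }
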