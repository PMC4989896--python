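"""D2-family statistics for pairs of read sets, with quality weighting.

Raw statistics
    D2      = sum_w X_w Y_w
    D2*     = sum_w Xt_w Yt_w / (W (p_w + p_wbar))
    D2^q    = sum_w Xq_w Yq_w
    D2^q*   = sum_w Xqt_w Yqt_w / (W (p_w + p_wbar) E_w)

with Xt_w = X_w − W_X (p_w + p_wbar), Xqt_w = Xq_w − W_X (p_w+p_wbar) E_w,
E_w = (Xq_w + Yq_w)/(X_w + Y_w) the pooled estimate of the expected
occurrence correctness of w and its complement, W_X = sum_reads(len−k+1)
the one-strand window total, and W = sqrt(W_X W_Y).

Starred sums run over words observed in at least one of the two samples
(E_w is 0/0 elsewhere). Normalized d-type values are ½(1 − cosine-like
ratio), lying in [0,1] with 0 for identical profiles; ``literal=True``
emits ½·ratio instead. Accumulation is in lexicographic word order, so
results are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, NumericalError
from .kmer_core import (
    BackgroundModel,
    QualityWeightedCountVector,
    count_kmers_weighted,
    nucleotide_counts,
    rc_permutation,
)

__all__ = [
    "PairContext",
    "DissimilarityMatrix",
    "MEASURES",
    "canonical_measure",
    "build_pair_context",
    "d2_raw",
    "d2star_raw",
    "d2q_raw",
    "d2qstar_raw",
    "centralized_count",
    "expected_correctness_pair",
    "normalize_to_dissimilarity",
    "compute_pair",
    "pairwise_matrices",
    "expected_unique_word_length",
]

#: canonical measure tokens, D-type (raw) then d-type (normalized)
MEASURES = ("D2", "D2star", "D2q", "D2qstar", "d2", "d2star", "d2q", "d2qstar")

_ALIASES = {
    "d2*": "d2star", "d2^q": "d2q", "d2^q*": "d2qstar", "d2q*": "d2qstar",
    "D2*": "D2star", "D2^q": "D2q", "D2^q*": "D2qstar", "D2q*": "D2qstar",
}


def canonical_measure(name: str) -> str:
    name = _ALIASES.get(name, name)
    if name not in MEASURES:
        raise ValueError(
            f"unknown measure {name!r}; choose from {', '.join(MEASURES)}")
    return name


@dataclass
class PairContext:
    """Aligned count/background vectors over the pair's observed words."""

    k: int
    codes: np.ndarray       # sorted (lexicographic) union support
    X: np.ndarray           # plain counts, sample 1
    Y: np.ndarray
    Xq: np.ndarray          # quality-weighted counts
    Yq: np.ndarray
    W_X: float              # one-strand window total, sample 1
    W_Y: float
    p: np.ndarray           # background p_w per word
    p_bar: np.ndarray       # p of the reverse complement

    def __post_init__(self):
        if self.W_X <= 0 or self.W_Y <= 0:
            raise NumericalError("window totals must be positive")

    @property
    def p_pair(self) -> np.ndarray:
        return self.p + self.p_bar

    @property
    def W(self) -> float:
        """Symmetrized M(β−k+1) stand-in for unequal samples."""
        return math.sqrt(self.W_X * self.W_Y)

    def word_index(self, w: str) -> int:
        from .kmer_core import word_to_code
        idx = np.searchsorted(self.codes, word_to_code(w))
        if idx >= len(self.codes) or self.codes[idx] != word_to_code(w):
            raise KeyError(f"word {w!r} not observed in this pair")
        return int(idx)


def build_pair_context(
    vx: QualityWeightedCountVector,
    vy: QualityWeightedCountVector,
    background: BackgroundModel,
) -> PairContext:
    if vx.k != vy.k:
        raise ValueError(f"k mismatch: {vx.k} != {vy.k}")
    k = vx.k
    if vx.dense is not None and vy.dense is not None:
        support = np.nonzero((vx.plain.dense > 0) | (vy.plain.dense > 0))[0]
        X = vx.plain.dense[support].astype(float)
        Y = vy.plain.dense[support].astype(float)
        Xq = vx.dense[support]
        Yq = vy.dense[support]
        perm = rc_permutation(k)
        rc_codes = perm[support]
    else:
        cset = sorted(set(vx.plain.sparse) | set(vy.plain.sparse))
        support = np.array(cset, dtype=np.int64)
        X = np.array([vx.plain.sparse.get(c, 0) for c in cset], dtype=float)
        Y = np.array([vy.plain.sparse.get(c, 0) for c in cset], dtype=float)
        Xq = np.array([(vx.sparse or {}).get(c, 0.0) for c in cset])
        Yq = np.array([(vy.sparse or {}).get(c, 0.0) for c in cset])
        from .kmer_core import code_to_word, reverse_complement, word_to_code
        rc_codes = np.array(
            [word_to_code(reverse_complement(code_to_word(c, k))) for c in cset],
            dtype=np.int64,
        )
    p = background.p_codes(support, k)
    p_bar = background.p_codes(rc_codes, k)
    if np.any((p + p_bar) <= 0.0):
        raise NumericalError(
            "background assigns zero probability to an observed word — "
            "null model inconsistent with the data")
    return PairContext(
        k=k, codes=support, X=X, Y=Y, Xq=Xq, Yq=Yq,
        W_X=vx.plain.total_positions / 2.0,
        W_Y=vy.plain.total_positions / 2.0,
        p=p, p_bar=p_bar,
    )


def centralized_count(count: float, windows: float, p_pair: float) -> float:
    """X_w − W·(p_w + p_wbar); may be negative."""
    if windows <= 0:
        raise ValueError("window total must be positive")
    return count - windows * p_pair


def expected_correctness_pair(ctx: PairContext, w: str) -> float:
    """(Xq_w + Yq_w)/(X_w + Y_w) — pooled mean occurrence correctness."""
    i = ctx.word_index(w)
    denom = ctx.X[i] + ctx.Y[i]
    if denom <= 0:
        raise NumericalError(f"word {w!r} unobserved: E(P_w) undefined")
    return float((ctx.Xq[i] + ctx.Yq[i]) / denom)


def _centralized(ctx: PairContext):
    xt = ctx.X - ctx.W_X * ctx.p_pair
    yt = ctx.Y - ctx.W_Y * ctx.p_pair
    return xt, yt


def _centralized_q(ctx: PairContext):
    denom = ctx.X + ctx.Y
    E = np.divide(ctx.Xq + ctx.Yq, denom,
                  out=np.zeros_like(ctx.Xq), where=denom > 0)
    xqt = ctx.Xq - ctx.W_X * ctx.p_pair * E
    yqt = ctx.Yq - ctx.W_Y * ctx.p_pair * E
    return xqt, yqt, E


def d2_raw(ctx: PairContext) -> float:
    return float(ctx.X @ ctx.Y)


def d2q_raw(ctx: PairContext) -> float:
    return float(ctx.Xq @ ctx.Yq)


def d2star_raw(ctx: PairContext) -> float:
    xt, yt = _centralized(ctx)
    return float(np.sum(xt * yt / (ctx.W * ctx.p_pair)))


def d2qstar_raw(ctx: PairContext) -> float:
    xqt, yqt, E = _centralized_q(ctx)
    mask = E > 0  # E == 0 terms are exactly 0/0 -> contribute 0
    return float(np.sum(
        xqt[mask] * yqt[mask] / (ctx.W * ctx.p_pair[mask] * E[mask])))


def normalize_to_dissimilarity(raw: float, self_norm_x: float,
                               self_norm_y: float,
                               literal: bool = False) -> float:
    """½(1 − raw/√(nx·ny)), clamped into [0,1]; literal form is ½·ratio."""
    if self_norm_x <= 0 or self_norm_y <= 0:
        raise NumericalError("empty k-mer profile: zero self-norm")
    ratio = raw / math.sqrt(self_norm_x * self_norm_y)
    ratio = min(1.0, max(-1.0, ratio))
    return 0.5 * ratio if literal else 0.5 * (1.0 - ratio)


def compute_pair(vx, vy, background, measures=MEASURES,
                 literal: bool = False) -> dict:
    """All requested statistics for one pair of weighted count vectors."""
    ctx = build_pair_context(vx, vy, background)
    measures = [canonical_measure(m) for m in measures]
    out = {}
    need_star = any(m in measures for m in ("D2star", "d2star"))
    need_qstar = any(m in measures for m in ("D2qstar", "d2qstar"))
    if "D2" in measures:
        out["D2"] = d2_raw(ctx)
    if "D2q" in measures:
        out["D2q"] = d2q_raw(ctx)
    if "d2" in measures:
        out["d2"] = normalize_to_dissimilarity(
            d2_raw(ctx), float(ctx.X @ ctx.X), float(ctx.Y @ ctx.Y), literal)
    if "d2q" in measures:
        out["d2q"] = normalize_to_dissimilarity(
            d2q_raw(ctx), float(ctx.Xq @ ctx.Xq), float(ctx.Yq @ ctx.Yq),
            literal)
    if need_star:
        xt, yt = _centralized(ctx)
        raw = float(np.sum(xt * yt / (ctx.W * ctx.p_pair)))
        if "D2star" in measures:
            out["D2star"] = raw
        if "d2star" in measures:
            # numerator W·D2* as printed; self-norms divide by p_w
            out["d2star"] = normalize_to_dissimilarity(
                ctx.W * raw,
                float(np.sum(xt * xt / ctx.p)),
                float(np.sum(yt * yt / ctx.p)),
                literal,
            )
    if need_qstar:
        xqt, yqt, E = _centralized_q(ctx)
        mask = E > 0
        raw = float(np.sum(
            xqt[mask] * yqt[mask] / (ctx.W * ctx.p_pair[mask] * E[mask])))
        if "D2qstar" in measures:
            out["D2qstar"] = raw
        if "d2qstar" in measures:
            out["d2qstar"] = normalize_to_dissimilarity(
                ctx.W * raw,
                float(np.sum(xqt * xqt / ctx.p)),
                float(np.sum(yqt * yqt / ctx.p)),
                literal,
            )
    return out


@dataclass
class DissimilarityMatrix:
    """Symmetric n×n matrix of one measure over labelled samples."""

    labels: list
    values: np.ndarray
    measure_name: str
    k: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} labels")
        if np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ValueError("matrix is not symmetric within 1e-10")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for lbl, row in zip(self.labels, self.values):
                fh.write(lbl + "\t" + "\t".join(f"{v:.10g}" for v in row)
                         + "\n")

    def to_phylip(self, path, relaxed: bool = False) -> None:
        """PHYLIP square matrix; labels padded/truncated to 10 chars
        unless ``relaxed``."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for lbl, row in zip(self.labels, self.values):
                name = lbl if relaxed else f"{lbl[:10]:<10}"
                fh.write(name + "  " + "  ".join(f"{v:.10f}" for v in row)
                         + "\n")

    @classmethod
    def from_phylip(cls, path, measure_name: str = "unknown",
                    k: int = 0) -> "DissimilarityMatrix":
        with open(path) as fh:
            tokens = fh.read().split()
        if not tokens:
            raise InputError(f"{path}: empty matrix file")
        try:
            n = int(tokens[0])
        except ValueError:
            raise InputError(f"{path}: first token must be the matrix size")
        if len(tokens) != 1 + n * (n + 1):
            raise InputError(
                f"{path}: expected {1 + n * (n + 1)} tokens for a square "
                f"PHYLIP matrix of size {n}, found {len(tokens)}")
        labels, rows = [], []
        pos = 1
        for _ in range(n):
            labels.append(tokens[pos])
            rows.append([float(t) for t in tokens[pos + 1:pos + 1 + n]])
            pos += 1 + n
        return cls(labels=labels, values=np.array(rows),
                   measure_name=measure_name, k=k)

    @classmethod
    def from_tsv(cls, path, measure_name: str = "unknown",
                 k: int = 0) -> "DissimilarityMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            labels = header[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(v) for v in parts[1:]])
        return cls(labels=labels, values=np.array(rows),
                   measure_name=measure_name, k=k)


def pairwise_matrices(samples, k: int, measures=MEASURES,
                      background: str = "pooled",
                      literal: bool = False) -> list:
    """All-pairs matrices for the requested measures.

    ``background='pooled'`` estimates the order-0 null from each pair's
    own reads; ``'global'`` uses one null pooled across all samples.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if background not in ("pooled", "global"):
        raise ValueError("background must be 'pooled' or 'global'")
    measures = [canonical_measure(m) for m in measures]
    vecs = [count_kmers_weighted(s, k) for s in samples]
    labels = [s.label for s in samples]
    n = len(samples)
    global_bg = None
    if background == "global":
        total = np.sum([v.base_counts for v in vecs], axis=0)
        global_bg = BackgroundModel.from_base_counts(total)
    mats = {m: np.zeros((n, n)) for m in measures}
    for i in range(n):
        for j in range(i, n):
            if i == j and not any(m.startswith("D") for m in measures):
                continue
            bg = global_bg or BackgroundModel.from_base_counts(
                vecs[i].base_counts + vecs[j].base_counts)
            vals = compute_pair(vecs[i], vecs[j], bg,
                                measures=measures, literal=literal)
            for m, v in vals.items():
                if i == j and m.startswith("d") and not literal:
                    v = 0.0  # identical sample: dissimilarity is exactly 0
                mats[m][i, j] = v
                mats[m][j, i] = v
    return [
        DissimilarityMatrix(labels=list(labels), values=mats[m],
                            measure_name=m, k=k)
        for m in measures
    ]


def expected_unique_word_length(sequence_length: float) -> float:
    """Word length at which a uniform i.i.d. DNA sequence of the given
    length is expected to contain each word about once: log4(length)."""
    if sequence_length <= 0:
        raise ValueError("sequence length must be positive")
    return math.log(sequence_length) / math.log(4.0)
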