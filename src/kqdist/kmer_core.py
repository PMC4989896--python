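"""k-mer counting over reverse-complement-supplemented read sets.

Counting is strand-symmetric by construction: every read contributes its
windows on both strands. For k <= 12 counts live in a dense 4^k array
(codes are 2-bit packed, A=0 C=1 G=2 T=3, lexicographic order); larger k
falls back to a sparse dict. Windows containing N (or any non-ACGT base)
are skipped entirely.

The quality-weighted count X^q_w sums, over the occurrences of w, the
probability that the occurrence was sequenced correctly:
prod_j (1 - 10^(-Q(i+j)/10)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import KqdistError
from .io_readsets import ReadRecord, ReadSet

__all__ = [
    "reverse_complement",
    "supplement_with_complements",
    "occurrence_correctness",
    "count_kmers",
    "count_kmers_weighted",
    "estimate_background",
    "nucleotide_counts",
    "KmerCountVector",
    "QualityWeightedCountVector",
    "BackgroundModel",
    "code_to_word",
    "word_to_code",
    "rc_permutation",
]

DENSE_K_MAX = 12
_ALPHABET = "ACGT"

# byte -> 2-bit code; N and everything else -> -1 (invalid)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(w: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    bad = set(w) - set("ACGTNacgtn")
    if bad:
        raise ValueError(f"non-DNA characters in {w!r}: {sorted(bad)}")
    return w.translate(_COMPLEMENT)[::-1]


def supplement_with_complements(readset: ReadSet) -> ReadSet:
    """Return the joint set of the M reads and their M reverse complements.

    A complement's quality list is the reversal of the original's: base i
    of the complement derives from base len-1-i of the original.
    """
    if readset.supplemented:
        return readset
    out = list(readset.reads)
    for r in readset.reads:
        out.append(
            ReadRecord(r.id + "/rc", reverse_complement(r.sequence),
                       np.asarray(r.qualities)[::-1].copy())
        )
    return ReadSet(label=readset.label, reads=out, supplemented=True)


def occurrence_correctness(qualities_slice) -> float:
    """P(word correct) for one occurrence: prod(1 - 10^(-Q/10))."""
    q = np.asarray(qualities_slice, dtype=float)
    return float(np.prod(1.0 - 10.0 ** (-q / 10.0)))


@lru_cache(maxsize=8)
def rc_permutation(k: int) -> np.ndarray:
    """Permutation p with p[code(w)] == code(reverse_complement(w))."""
    codes = np.arange(4 ** k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


def word_to_code(w: str) -> int:
    code = 0
    for ch in w:
        c = _CODE[ord(ch)]
        if c < 0:
            raise ValueError(f"word {w!r} contains non-ACGT character")
        code = (code << 2) | int(c)
    return code


def code_to_word(code: int, k: int) -> str:
    return "".join(_ALPHABET[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


@dataclass
class KmerCountVector:
    """Strand-symmetric integer k-mer counts X_w.

    ``dense`` is a length-4^k int64 array for k <= DENSE_K_MAX, else None
    and ``sparse`` holds {code: count}. ``total_positions`` is the number
    of counted windows (both strands, N windows excluded) and equals the
    sum of counts.
    """

    k: int
    dense: np.ndarray | None = None
    sparse: dict | None = None
    total_positions: int = 0

    @property
    def counts(self) -> dict:
        """{word: count} over observed words, lexicographic word order."""
        if self.dense is not None:
            nz = np.nonzero(self.dense)[0]
            return {code_to_word(int(c), self.k): int(self.dense[c]) for c in nz}
        return {
            code_to_word(c, self.k): v
            for c, v in sorted(self.sparse.items()) if v
        }

    def __getitem__(self, word: str) -> int:
        code = word_to_code(word)
        if self.dense is not None:
            return int(self.dense[code])
        return int(self.sparse.get(code, 0))

    @property
    def support_codes(self) -> np.ndarray:
        if self.dense is not None:
            return np.nonzero(self.dense)[0]
        return np.array(sorted(c for c, v in self.sparse.items() if v),
                        dtype=np.int64)


@dataclass
class QualityWeightedCountVector:
    """Quality-weighted counts X^q_w alongside the matching plain counts."""

    k: int
    dense: np.ndarray | None = None
    sparse: dict | None = None
    plain: KmerCountVector | None = None
    base_counts: np.ndarray = field(
        default_factory=lambda: np.zeros(4, dtype=np.int64))

    @property
    def weighted(self) -> dict:
        if self.dense is not None:
            nz = np.nonzero(self.dense)[0]
            return {code_to_word(int(c), self.k): float(self.dense[c]) for c in nz}
        return {
            code_to_word(c, self.k): v
            for c, v in sorted(self.sparse.items()) if v
        }

    def __getitem__(self, word: str) -> float:
        code = word_to_code(word)
        if self.dense is not None:
            return float(self.dense[code])
        return float(self.sparse.get(code, 0.0))


def _encode_readset(readset: ReadSet, k: int, with_quals: bool):
    """Concatenate reads (k-1 sentinel gap) into code and quality arrays."""
    gap = k - 1
    lengths = [len(r) for r in readset.reads]
    total = sum(lengths) + gap * len(lengths)
    codes = np.full(total, -1, dtype=np.int8)
    quals = np.zeros(total, dtype=np.int16) if with_quals else None
    pos = 0
    for r in readset.reads:
        n = len(r)
        codes[pos:pos + n] = _CODE[
            np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8)]
        if with_quals:
            quals[pos:pos + n] = r.qualities
        pos += n + gap
    return codes, quals


def _forward_window_stats(readset: ReadSet, k: int, with_quals: bool):
    """Window codes, validity mask and (optionally) weights, forward strand."""
    codes, quals = _encode_readset(readset, k, with_quals)
    n = len(codes) - k + 1
    if n <= 0:
        return (np.empty(0, np.int64), np.empty(0, bool), None)
    safe = np.where(codes >= 0, codes, 0).astype(np.int64)
    kcodes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        kcodes = (kcodes << 2) | safe[j:j + n]
    bad = np.concatenate(([0], np.cumsum((codes < 0).astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    weights = None
    if with_quals:
        err = 10.0 ** (-quals.astype(float) / 10.0)
        c = 1.0 - err
        zero = c <= 0.0
        logc = np.log(np.where(zero, 1.0, c))
        cum = np.concatenate(([0.0], np.cumsum(logc)))
        weights = np.exp(cum[k:] - cum[:-k])
        zcum = np.concatenate(([0], np.cumsum(zero.astype(np.int64))))
        weights[(zcum[k:] - zcum[:-k]) > 0] = 0.0
        np.minimum(weights, 1.0, out=weights)
    return kcodes, valid, weights


def _check_k(readset: ReadSet, k: int) -> None:
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not readset.reads:
        raise KqdistError(f"read set {readset.label!r} is empty")
    if k > max(len(r) for r in readset.reads):
        raise KqdistError(
            f"k={k} exceeds the longest read in {readset.label!r}")


def count_kmers(readset: ReadSet, k: int) -> KmerCountVector:
    """Count every length-k window (with overlaps) over the supplemented set."""
    return count_kmers_weighted(readset, k, _weighted=False).plain


def count_kmers_weighted(readset: ReadSet, k: int,
                         _weighted: bool = True) -> QualityWeightedCountVector:
    """Plain and quality-weighted counts in one streaming pass."""
    _check_k(readset, k)
    base = readset
    already = readset.supplemented
    kcodes, valid, weights = _forward_window_stats(base, k, _weighted)
    vcodes = kcodes[valid]
    n_valid = int(valid.sum())
    if k <= DENSE_K_MAX:
        perm = rc_permutation(k)
        fwd = np.bincount(vcodes, minlength=4 ** k).astype(np.int64)
        if already:
            plain_dense = fwd
            total = n_valid
        else:
            plain_dense = fwd + fwd[perm]
            total = 2 * n_valid
        plain = KmerCountVector(k=k, dense=plain_dense, total_positions=total)
        out = QualityWeightedCountVector(k=k, plain=plain)
        if _weighted:
            wfwd = np.bincount(vcodes, weights=weights[valid],
                               minlength=4 ** k)
            wd = wfwd if already else wfwd + wfwd[perm]
            out.dense = np.minimum(wd, plain_dense.astype(float))
    else:
        perm = None
        plain_sparse: dict = {}
        weighted_sparse: dict = {}
        wts = weights[valid] if _weighted else None
        for idx, c in enumerate(vcodes):
            c = int(c)
            plain_sparse[c] = plain_sparse.get(c, 0) + 1
            if _weighted:
                weighted_sparse[c] = weighted_sparse.get(c, 0.0) + wts[idx]
        if not already:
            rc_plain: dict = {}
            rc_weighted: dict = {}
            for c, v in plain_sparse.items():
                rc = word_to_code(reverse_complement(code_to_word(c, k)))
                rc_plain[rc] = rc_plain.get(rc, 0) + v
            for c, v in weighted_sparse.items():
                rc = word_to_code(reverse_complement(code_to_word(c, k)))
                rc_weighted[rc] = rc_weighted.get(rc, 0.0) + v
            for c, v in rc_plain.items():
                plain_sparse[c] = plain_sparse.get(c, 0) + v
            for c, v in rc_weighted.items():
                weighted_sparse[c] = weighted_sparse.get(c, 0.0) + v
            total = 2 * n_valid
        else:
            total = n_valid
        plain = KmerCountVector(k=k, sparse=plain_sparse,
                                total_positions=total)
        out = QualityWeightedCountVector(k=k, plain=plain)
        if _weighted:
            out.sparse = {
                c: min(v, plain_sparse[c]) for c, v in weighted_sparse.items()
            }
    out.base_counts = nucleotide_counts(readset)
    return out


def nucleotide_counts(readset: ReadSet) -> np.ndarray:
    """A/C/G/T tallies over the original-strand reads (N excluded)."""
    counts = np.zeros(4, dtype=np.int64)
    for r in readset.reads:
        codes = _CODE[np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8)]
        counts += np.bincount(codes[codes >= 0], minlength=4).astype(np.int64)
    return counts


@dataclass
class BackgroundModel:
    """Order-0 null model: p_w is the product of per-letter frequencies.

    Frequencies are tallied over complement-supplemented reads, so
    freq(A)==freq(T) and freq(C)==freq(G), making p_w + p_wbar
    strand-symmetric by construction.
    """

    nucleotide_freqs: np.ndarray
    order: int = 0

    def __post_init__(self):
        self.nucleotide_freqs = np.asarray(self.nucleotide_freqs, dtype=float)
        s = self.nucleotide_freqs.sum()
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"nucleotide frequencies sum to {s}, not 1")
        if self.order != 0:
            raise NotImplementedError("only order-0 backgrounds are supported")

    @classmethod
    def from_base_counts(cls, counts) -> "BackgroundModel":
        counts = np.asarray(counts, dtype=np.int64)
        # symmetrize: complement supplementation pairs A<->T, C<->G
        supp = counts + counts[[3, 2, 1, 0]]
        total = supp.sum()
        if total == 0:
            raise KqdistError("cannot estimate background: no unambiguous bases")
        return cls(nucleotide_freqs=supp / total)

    def p_word(self, w: str) -> float:
        codes = _CODE[np.frombuffer(w.upper().encode("ascii"), dtype=np.uint8)]
        if (codes < 0).any():
            raise ValueError(f"word {w!r} contains non-ACGT character")
        return float(np.prod(self.nucleotide_freqs[codes]))

    def p_codes(self, codes: np.ndarray, k: int) -> np.ndarray:
        """Vectorized p_w for an array of 2-bit-packed word codes."""
        codes = np.asarray(codes, dtype=np.int64)
        p = np.ones(len(codes), dtype=float)
        for j in range(k):
            p *= self.nucleotide_freqs[(codes >> (2 * j)) & 3]
        return p


def estimate_background(readsets, order: int = 0) -> BackgroundModel:
    """Order-0 background pooled over the given read sets."""
    if not readsets:
        raise KqdistError("no read sets given")
    total = np.zeros(4, dtype=np.int64)
    for rs in readsets:
        if not rs.reads:
            raise KqdistError(f"read set {rs.label!r} is empty")
        total += nucleotide_counts(rs)
    model = BackgroundModel.from_base_counts(total)
    if order != 0:
        raise NotImplementedError("only order-0 backgrounds are supported")
    return model
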