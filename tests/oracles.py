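"""Independent brute-force oracles used to validate the fast paths.

Everything here is deliberately naive: plain dicts, string slices and
straight-from-the-formula arithmetic. Nothing imports the counting or
measure internals beyond the public data types.
"""

from itertools import product
from math import prod, sqrt

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(w):
    return "".join(_COMP[c] for c in reversed(w))


def supplemented_reads(readset):
    """[(sequence, qualities)] for reads plus reverse complements."""
    out = []
    for r in readset.reads:
        quals = [int(q) for q in r.qualities]
        out.append((r.sequence, quals))
        if not readset.supplemented:
            out.append((rc(r.sequence), quals[::-1]))
    return out


def naive_counts(readset, k):
    """{word: count} scanning every window with string comparison."""
    counts = {}
    for seq, _ in supplemented_reads(readset):
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if "N" in w:
                continue
            counts[w] = counts.get(w, 0) + 1
    return counts


def naive_weighted_counts(readset, k):
    """{word: sum of per-occurrence correctness probabilities}."""
    counts = {}
    for seq, quals in supplemented_reads(readset):
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if "N" in w:
                continue
            p = prod(1.0 - 10.0 ** (-q / 10.0) for q in quals[i:i + k])
            counts[w] = counts.get(w, 0.0) + p
    return counts


def naive_background_freqs(readsets):
    """Order-0 nucleotide frequencies over pooled supplemented reads."""
    tally = {b: 0 for b in "ACGT"}
    for rs in readsets:
        for seq, _ in supplemented_reads(rs):
            for ch in seq:
                if ch in tally:
                    tally[ch] += 1
    total = sum(tally.values())
    return {b: v / total for b, v in tally.items()}


def p_word(freqs, w):
    return prod(freqs[c] for c in w)


def window_total(readset, k):
    """One-strand window count: sum over reads of (len - k + 1)."""
    return sum(max(len(r.sequence) - k + 1, 0) for r in readset.reads)


def naive_pair_stats(rs_x, rs_y, k, literal=False, raw_only=False):
    """All eight statistics straight from the formulas.

    The starred sums run over words observed in at least one sample,
    with each sample centralized by its own window total and the shared
    M(beta-k+1) factor symmetrized to sqrt(W_X * W_Y).
    """
    X = naive_counts(rs_x, k)
    Y = naive_counts(rs_y, k)
    Xq = naive_weighted_counts(rs_x, k)
    Yq = naive_weighted_counts(rs_y, k)
    freqs = naive_background_freqs([rs_x, rs_y])
    W_X = window_total(rs_x, k)
    W_Y = window_total(rs_y, k)
    W = sqrt(W_X * W_Y)
    universe = sorted(set(X) | set(Y))

    d2_num = sum(X.get(w, 0) * Y.get(w, 0) for w in universe)
    d2q_num = sum(Xq.get(w, 0.0) * Yq.get(w, 0.0) for w in universe)

    d2star_num = 0.0
    d2qstar_num = 0.0
    nx = ny = nxq = nyq = 0.0
    sx2 = sum(v * v for v in X.values())
    sy2 = sum(v * v for v in Y.values())
    sxq2 = sum(v * v for v in Xq.values())
    syq2 = sum(v * v for v in Yq.values())
    for w in universe:
        pw = p_word(freqs, w)
        ppair = pw + p_word(freqs, rc(w))
        xt = X.get(w, 0) - W_X * ppair
        yt = Y.get(w, 0) - W_Y * ppair
        d2star_num += xt * yt / (W * ppair)
        nx += xt * xt / pw
        ny += yt * yt / pw
        tot = X.get(w, 0) + Y.get(w, 0)
        E = (Xq.get(w, 0.0) + Yq.get(w, 0.0)) / tot
        xqt = Xq.get(w, 0.0) - W_X * ppair * E
        yqt = Yq.get(w, 0.0) - W_Y * ppair * E
        if E > 0:
            d2qstar_num += xqt * yqt / (W * ppair * E)
        nxq += xqt * xqt / pw
        nyq += yqt * yqt / pw

    out = {
        "D2": float(d2_num),
        "D2q": d2q_num,
        "D2star": d2star_num,
        "D2qstar": d2qstar_num,
    }
    if raw_only:
        return out

    def norm(num, a, b):
        r = num / (sqrt(a) * sqrt(b))
        r = min(1.0, max(-1.0, r))
        return 0.5 * r if literal else 0.5 * (1.0 - r)

    out["d2"] = norm(d2_num, sx2, sy2)
    out["d2q"] = norm(d2q_num, sxq2, syq2)
    out["d2star"] = norm(W * d2star_num, nx, ny)
    out["d2qstar"] = norm(W * d2qstar_num, nxq, nyq)
    return out


def all_words(k):
    return ["".join(t) for t in product("ACGT", repeat=k)]


def naive_upgma_merge_order(labels, d):
    """Merge sequence [(set_i, set_j, dissimilarity)] for cross-checks."""
    import numpy as np

    d = np.asarray(d, dtype=float).copy()
    clusters = [frozenset([lbl]) for lbl in labels]
    sizes = [1] * len(labels)
    active = list(range(len(labels)))
    merges = []
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                if best is None or d[i, j] < best[0]:
                    best = (d[i, j], ai, aj)
        dij, ai, aj = best
        i, j = active[ai], active[aj]
        merges.append((clusters[i], clusters[j], dij))
        for m in active:
            if m in (i, j):
                continue
            d[i, m] = d[m, i] = (
                sizes[i] * d[i, m] + sizes[j] * d[j, m]) / (sizes[i] + sizes[j])
        clusters[i] = clusters[i] | clusters[j]
        sizes[i] += sizes[j]
        active.pop(aj)
    return merges


def random_readset(rng, label="s", max_reads=5, max_len=20, min_len=None,
                   with_n=False, quality_range=(0, 40)):
    """Small random ReadSet for oracle comparisons."""
    from kqdist.io_readsets import ReadRecord, ReadSet

    n_reads = int(rng.integers(1, max_reads + 1))
    reads = []
    alphabet = "ACGTN" if with_n else "ACGT"
    for i in range(n_reads):
        lo = min_len or 4
        length = int(rng.integers(lo, max_len + 1))
        seq = "".join(rng.choice(list(alphabet), size=length))
        quals = rng.integers(quality_range[0], quality_range[1] + 1,
                             size=length)
        reads.append(ReadRecord(f"{label}_r{i}", seq, quals))
    return ReadSet(label=label, reads=reads)
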