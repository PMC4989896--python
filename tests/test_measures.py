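import numpy as np
import pytest

from kqdist.errors import NumericalError
from kqdist.io_readsets import ReadRecord, ReadSet
from kqdist.kmer_core import BackgroundModel, count_kmers_weighted
from kqdist.measures import (
    MEASURES,
    DissimilarityMatrix,
    PairContext,
    build_pair_context,
    canonical_measure,
    centralized_count,
    compute_pair,
    d2_raw,
    d2q_raw,
    d2qstar_raw,
    d2star_raw,
    expected_correctness_pair,
    expected_unique_word_length,
    normalize_to_dissimilarity,
    pairwise_matrices,
)
from kqdist.simulate import ReadSimConfig, random_sequence, sample_reads

import oracles


def _ctx_from_dicts(k, X, Y, Xq=None, Yq=None, W_X=10.0, W_Y=10.0,
                    freqs=(0.25, 0.25, 0.25, 0.25)):
    """Hand-built PairContext over the union support."""
    from kqdist.kmer_core import word_to_code

    words = sorted(set(X) | set(Y))
    codes = np.array([word_to_code(w) for w in words], dtype=np.int64)
    order = np.argsort(codes)
    words = [words[i] for i in order]
    codes = codes[order]
    bg = BackgroundModel(np.asarray(freqs))
    Xq = Xq if Xq is not None else {w: float(v) for w, v in X.items()}
    Yq = Yq if Yq is not None else {w: float(v) for w, v in Y.items()}
    return PairContext(
        k=k,
        codes=codes,
        X=np.array([X.get(w, 0) for w in words], float),
        Y=np.array([Y.get(w, 0) for w in words], float),
        Xq=np.array([Xq.get(w, 0.0) for w in words]),
        Yq=np.array([Yq.get(w, 0.0) for w in words]),
        W_X=W_X, W_Y=W_Y,
        p=np.array([bg.p_word(w) for w in words]),
        p_bar=np.array([bg.p_word(oracles.rc(w)) for w in words]),
    )


class TestD2Raw:
    def test_inner_product(self):
        ctx = _ctx_from_dicts(2, {"AA": 2, "AC": 1}, {"AA": 1, "AC": 3})
        assert d2_raw(ctx) == 5.0

    def test_disjoint_supports(self):
        ctx = _ctx_from_dicts(2, {"AA": 2}, {"CC": 3})
        assert d2_raw(ctx) == 0.0

    def test_self_is_sum_of_squares(self):
        ctx = _ctx_from_dicts(2, {"AA": 2, "AC": 3}, {"AA": 2, "AC": 3})
        assert d2_raw(ctx) == 13.0


class TestCentralizedCount:
    def test_toy(self):
        assert centralized_count(5, 460, 0.002) == pytest.approx(4.08)

    def test_at_expectation(self):
        assert centralized_count(0.92, 460, 0.002) == pytest.approx(0.0)

    def test_zero_background(self):
        assert centralized_count(7, 100, 0.0) == 7.0

    def test_bad_windows(self):
        with pytest.raises(ValueError):
            centralized_count(1, 0, 0.1)


class TestD2StarRaw:
    def test_single_word_toy(self):
        # Xt = 4.08, Yt = 2.04, W = 460, p_pair = 0.002
        # -> 4.08 * 2.04 / 0.92 ~= 9.047
        ctx = _ctx_from_dicts(
            1, {"A": 5.0}, {"A": 2.96}, W_X=460, W_Y=460,
            freqs=(0.001, 0.499, 0.499, 0.001))
        assert ctx.p_pair[0] == pytest.approx(0.002)
        assert d2star_raw(ctx) == pytest.approx(4.08 * 2.04 / 0.92, rel=1e-9)

    def test_zero_at_expectation(self):
        ctx = _ctx_from_dicts(1, {"A": 0.5}, {"A": 0.5}, W_X=1.0, W_Y=1.0)
        assert d2star_raw(ctx) == pytest.approx(0.0, abs=1e-12)

    def test_sign_flip(self):
        up = _ctx_from_dicts(1, {"A": 6.0}, {"A": 6.0}, W_X=10, W_Y=10)
        down = _ctx_from_dicts(1, {"A": 6.0}, {"A": 4.0}, W_X=10, W_Y=10)
        assert d2star_raw(up) > 0
        assert d2star_raw(down) < 0


class TestD2QRaw:
    def test_weighted_inner_product(self):
        ctx = _ctx_from_dicts(2, {"AA": 1}, {"AA": 1, "AC": 1},
                              Xq={"AA": 0.9}, Yq={"AA": 0.5, "AC": 0.2})
        assert d2q_raw(ctx) == pytest.approx(0.45)

    def test_perfect_quality_equals_d2(self):
        ctx = _ctx_from_dicts(2, {"AA": 2, "AC": 1}, {"AA": 1, "AC": 3})
        assert d2q_raw(ctx) == pytest.approx(d2_raw(ctx))


class TestExpectedCorrectness:
    def test_pooled_ratio(self):
        ctx = _ctx_from_dicts(2, {"AA": 1}, {"AA": 1},
                              Xq={"AA": 0.9}, Yq={"AA": 0.8})
        assert expected_correctness_pair(ctx, "AA") == pytest.approx(0.85)

    def test_perfect_qualities(self):
        ctx = _ctx_from_dicts(2, {"AA": 3}, {"AA": 2})
        assert expected_correctness_pair(ctx, "AA") == 1.0

    def test_equals_mean_occurrence_correctness(self, rng):
        # brute-force: average correctness over all occurrences of w
        rs_x = oracles.random_readset(rng, label="x", max_reads=3,
                                      max_len=12, min_len=6)
        rs_y = oracles.random_readset(rng, label="y", max_reads=3,
                                      max_len=12, min_len=6)
        k = 2
        vx = count_kmers_weighted(rs_x, k)
        vy = count_kmers_weighted(rs_y, k)
        bg = BackgroundModel.from_base_counts(
            vx.base_counts + vy.base_counts)
        ctx = build_pair_context(vx, vy, bg)
        Xq = oracles.naive_weighted_counts(rs_x, k)
        Yq = oracles.naive_weighted_counts(rs_y, k)
        X = oracles.naive_counts(rs_x, k)
        Y = oracles.naive_counts(rs_y, k)
        for w in list(X)[:5]:
            expect = (Xq.get(w, 0) + Yq.get(w, 0)) / (X[w] + Y.get(w, 0))
            assert expected_correctness_pair(ctx, w) == pytest.approx(
                expect, abs=1e-9)


class TestD2QStarRaw:
    def test_perfect_quality_equals_d2star(self, rng):
        rs_x = oracles.random_readset(rng, label="x", quality_range=(90, 93))
        rs_y = oracles.random_readset(rng, label="y", quality_range=(90, 93))
        vx = count_kmers_weighted(rs_x, 2)
        vy = count_kmers_weighted(rs_y, 2)
        bg = BackgroundModel.from_base_counts(vx.base_counts + vy.base_counts)
        ctx = build_pair_context(vx, vy, bg)
        assert d2qstar_raw(ctx) == pytest.approx(d2star_raw(ctx), abs=1e-4)

    def test_zero_when_weighted_at_expectation(self):
        # Xq equals W * p_pair * E for every word -> centralized 0
        ctx = _ctx_from_dicts(1, {"A": 4}, {"A": 4},
                              Xq={"A": 2.0}, Yq={"A": 2.0},
                              W_X=8.0, W_Y=8.0)
        # p_pair = 0.5, E = 0.5 -> expectation = 8*0.5*0.5 = 2.0
        assert d2qstar_raw(ctx) == pytest.approx(0.0, abs=1e-12)


class TestNormalize:
    def test_identical_vectors(self):
        assert normalize_to_dissimilarity(13.0, 13.0, 13.0) == 0.0

    def test_orthogonal(self):
        assert normalize_to_dissimilarity(0.0, 4.0, 9.0) == 0.5

    def test_anticorrelated(self):
        assert normalize_to_dissimilarity(-6.0, 6.0, 6.0) == 1.0

    def test_literal_form(self):
        assert normalize_to_dissimilarity(13.0, 13.0, 13.0, literal=True) \
            == 0.5

    def test_empty_profile(self):
        with pytest.raises(NumericalError):
            normalize_to_dissimilarity(1.0, 0.0, 1.0)


class TestBruteForceOracle:
    """Every statistic vs. an independent straight-from-the-formula
    implementation on random tiny instances."""

    def test_100_random_instances(self, rng):
        for i in range(100):
            k = int(rng.integers(1, 4))
            rs_x = oracles.random_readset(rng, label="x", max_reads=4,
                                          max_len=12, min_len=max(4, k))
            rs_y = oracles.random_readset(rng, label="y", max_reads=4,
                                          max_len=12, min_len=max(4, k))
            vx = count_kmers_weighted(rs_x, k)
            vy = count_kmers_weighted(rs_y, k)
            bg = BackgroundModel.from_base_counts(
                vx.base_counts + vy.base_counts)
            try:
                got = compute_pair(vx, vy, bg)
            except NumericalError:
                # profile exactly at expectation (e.g. a homopolymer
                # sample at k=1): the ratio is 0/0 in the oracle too
                with pytest.raises(ZeroDivisionError):
                    oracles.naive_pair_stats(rs_x, rs_y, k)
                continue
            expect = oracles.naive_pair_stats(rs_x, rs_y, k)
            for m in MEASURES:
                assert got[m] == pytest.approx(expect[m], abs=1e-9), \
                    f"instance {i}, measure {m}"

    def test_literal_form_matches_oracle(self, rng):
        rs_x = oracles.random_readset(rng, label="x", min_len=5)
        rs_y = oracles.random_readset(rng, label="y", min_len=5)
        vx = count_kmers_weighted(rs_x, 2)
        vy = count_kmers_weighted(rs_y, 2)
        bg = BackgroundModel.from_base_counts(vx.base_counts + vy.base_counts)
        got = compute_pair(vx, vy, bg, literal=True)
        expect = oracles.naive_pair_stats(rs_x, rs_y, 2, literal=True)
        for m in ("d2", "d2star", "d2q", "d2qstar"):
            assert got[m] == pytest.approx(expect[m], abs=1e-9)


class TestQualityDegeneracy:
    def test_high_quality_pairs(self, rng):
        seq = random_sequence(500, seed=rng)
        cfg = ReadSimConfig(M=30, beta=80, mismatch_prob=1e-7)
        for _ in range(5):
            a = sample_reads(seq, cfg, label="a", seed=rng)
            b = sample_reads(seq, cfg, label="b", seed=rng)
            assert min(np.min(r.qualities) for r in a) >= 60
            va = count_kmers_weighted(a, 4)
            vb = count_kmers_weighted(b, 4)
            bg = BackgroundModel.from_base_counts(
                va.base_counts + vb.base_counts)
            vals = compute_pair(va, vb, bg)
            assert abs(vals["d2q"] - vals["d2"]) < 1e-3
            assert abs(vals["d2qstar"] - vals["d2star"]) < 1e-3


class TestPairwiseMatrices:
    def test_shapes_and_symmetry(self, small_pair, rng):
        a, b = small_pair
        seq = random_sequence(400, seed=rng)
        c = sample_reads(seq, ReadSimConfig(M=20, beta=60), label="c",
                         seed=rng)
        mats = pairwise_matrices([a, b, c], k=4)
        assert len(mats) == 8
        for m in mats:
            assert m.values.shape == (3, 3)
            assert np.max(np.abs(m.values - m.values.T)) <= 1e-10

    def test_d_type_range_and_diagonal(self, small_pair):
        a, b = small_pair
        mats = pairwise_matrices([a, b], k=4,
                                 measures=["d2", "d2star", "d2q", "d2qstar"])
        for m in mats:
            assert np.all(m.values >= 0.0) and np.all(m.values <= 1.0)
            assert np.all(np.diag(m.values) == 0.0)

    def test_duplicated_sample_d2_zero(self, small_pair):
        a, _ = small_pair
        twin = ReadSet("twin", list(a.reads))
        (m,) = pairwise_matrices([a, twin], k=4, measures=["d2"])
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reordering_invariance(self, small_pair, rng):
        a, b = small_pair
        seq = random_sequence(400, seed=rng)
        c = sample_reads(seq, ReadSimConfig(M=20, beta=60), label="c",
                         seed=rng)
        (m1,) = pairwise_matrices([a, b, c], k=4, measures=["d2star"])
        (m2,) = pairwise_matrices([c, a, b], k=4, measures=["d2star"])
        perm = [m2.labels.index(lbl) for lbl in m1.labels]
        np.testing.assert_allclose(m1.values,
                                   m2.values[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_determinism(self, small_pair):
        a, b = small_pair
        (m1,) = pairwise_matrices([a, b], k=4, measures=["d2qstar"])
        (m2,) = pairwise_matrices([a, b], k=4, measures=["d2qstar"])
        assert np.array_equal(m1.values, m2.values)

    def test_global_background_option(self, small_pair):
        a, b = small_pair
        (m,) = pairwise_matrices([a, b], k=4, measures=["d2star"],
                                 background="global")
        assert np.isfinite(m.values).all()

    def test_needs_two_samples(self, small_pair):
        a, _ = small_pair
        with pytest.raises(ValueError):
            pairwise_matrices([a], k=4)

    def test_raw_diagonal_holds_self_statistic(self, small_pair):
        a, b = small_pair
        (m,) = pairwise_matrices([a, b], k=4, measures=["D2"])
        va = count_kmers_weighted(a, 4)
        bg = BackgroundModel.from_base_counts(2 * va.base_counts)
        self_stat = compute_pair(va, va, bg, measures=["D2"])["D2"]
        assert m.values[0, 0] == pytest.approx(self_stat)


class TestNoiseDiscrimination:
    def test_same_source_closer_than_diverged(self, rng):
        # 70-PAM-style divergence: ~0.5 substitutions/site accumulated
        from kqdist.simulate import EvolutionConfig, evolve_family

        wins = 0
        trials = 100
        cfg = ReadSimConfig(M=50, beta=100, mismatch_prob=0.05)
        for t in range(trials):
            fam, _ = evolve_family(EvolutionConfig(
                root_length=5000, n_sequences=2, relatedness=70,
                seed=rng))
            (la, seq_a), (lb, seq_b) = fam
            r1 = sample_reads(seq_a, cfg, label="r1", seed=rng)
            r2 = sample_reads(seq_a, cfg, label="r2", seed=rng)
            r3 = sample_reads(seq_b, cfg, label="r3", seed=rng)
            mats = pairwise_matrices([r1, r2, r3], k=5, measures=["d2"])
            d = mats[0].values
            if d[0, 1] < d[0, 2] and d[0, 1] < d[1, 2]:
                wins += 1
        assert wins >= 95


class TestMatrixIO:
    def test_phylip_roundtrip(self, tmp_path, small_pair):
        a, b = small_pair
        (m,) = pairwise_matrices([a, b], k=4, measures=["d2"])
        path = tmp_path / "m.phylip"
        m.to_phylip(path)
        back = DissimilarityMatrix.from_phylip(path)
        np.testing.assert_allclose(back.values, m.values, atol=1e-9)
        assert back.labels == ["a", "b"]

    def test_phylip_label_padding(self, tmp_path):
        m = DissimilarityMatrix(["longlabelname", "b"],
                                np.array([[0.0, 0.5], [0.5, 0.0]]), "d2", 4)
        path = tmp_path / "m.phylip"
        m.to_phylip(path)
        first = path.read_text().splitlines()[1]
        assert first.startswith("longlabeln")
        m.to_phylip(path, relaxed=True)
        assert "longlabelname" in path.read_text()

    def test_tsv_roundtrip(self, tmp_path, small_pair):
        a, b = small_pair
        (m,) = pairwise_matrices([a, b], k=4, measures=["d2qstar"])
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = DissimilarityMatrix.from_tsv(path)
        np.testing.assert_allclose(back.values, m.values, atol=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DissimilarityMatrix(["a", "b"],
                                np.array([[0.0, 0.5], [0.1, 0.0]]), "d2", 4)


class TestMisc:
    def test_canonical_aliases(self):
        assert canonical_measure("d2*") == "d2star"
        assert canonical_measure("D2^q*") == "D2qstar"
        with pytest.raises(ValueError):
            canonical_measure("euclid")

    def test_expected_unique_word_length(self):
        assert expected_unique_word_length(5000) == pytest.approx(6.1439,
                                                                  abs=1e-3)
        assert expected_unique_word_length(4 ** 6) == pytest.approx(6.0)
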