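import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from topohic.errors import ValidationError
from topohic.integrate import (
    FusionConfig,
    affinity,
    concordance_network,
    distance_binary,
    distance_continuous,
    embed_2d,
    filter_features,
    fused_distance,
    nmf_consensus,
    nmi,
    snf_fuse,
    spectral_cluster,
)


def _three_group_matrix(rng, n_per=6, n_features=30, shift=3.0):
    """Samples x features with three planted groups shifted apart."""
    blocks = []
    for g in range(3):
        centre = np.zeros(n_features)
        centre[g * 5: g * 5 + 5] = shift
        blocks.append(centre + rng.normal(size=(n_per, n_features)))
    x = np.vstack(blocks)
    labels = np.repeat([0, 1, 2], n_per)
    return x, labels


class TestFilterFeatures:
    def test_spec_arithmetic_36_of_100(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 100))
        x[: 3, :10] = np.nan  # 10 columns with 3/40 = 7.5% >= 5% missing
        cfg = FusionConfig()
        out = filter_features(x, cfg)
        assert out.shape == (40, 36)  # 90 pass filter 1, floor(0.4 * 90) = 36

    def test_constant_columns_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 50))
        x[:, :15] = 7.0
        out = filter_features(x, FusionConfig())
        assert out.shape[1] == 20  # top 40% of 50
        assert not np.any(np.all(out == 7.0, axis=0))

    def test_imputation_fills_mean(self):
        x = np.array([[1.0, 0.0], [3.0, 1.0], [np.nan, 2.0], [5.0, 100.0],
                      [3.0, 50.0]] * 5)
        cfg = FusionConfig(max_missing=0.5, variance_keep=1.0)
        out = filter_features(x, cfg)
        assert np.isfinite(out).all()

    def test_no_survivors_errors(self):
        x = np.full((10, 5), np.nan)
        with pytest.raises(ValidationError):
            filter_features(x, FusionConfig())


class TestDistances:
    def test_identical_rows_zero(self):
        x = np.tile([1.0, 2.0, 3.0], (4, 1))
        np.testing.assert_allclose(distance_continuous(x), 0.0, atol=1e-12)

    def test_analytic_25(self):
        d = distance_continuous(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == pytest.approx(25.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 7))
        d = distance_continuous(x)
        for s in range(5):
            for t in range(5):
                ref = np.sum((x[s] - x[t]) ** 2)
                assert d[s, t] == pytest.approx(ref, abs=1e-10)

    def test_jaccard_cases(self):
        x = np.array([
            [1, 1, 1, 0, 0],   # {0,1,2}
            [0, 1, 1, 1, 0],   # {1,2,3}
            [0, 0, 0, 0, 1],   # {4}
            [0, 0, 0, 0, 0],   # empty
            [0, 0, 0, 0, 0],   # empty
        ])
        d = distance_binary(x)
        assert d[0, 0] == 0.0
        assert d[0, 1] == pytest.approx(0.5)  # 1 - 2/4
        assert d[0, 2] == 1.0
        assert d[3, 4] == 0.0  # both empty by convention

    def test_jaccard_rejects_non_binary(self):
        with pytest.raises(ValidationError):
            distance_binary(np.array([[0.5, 1.0]]))


class TestAffinity:
    def test_matches_bruteforce_4x4(self):
        d = np.array([[0.0, 1.0, 4.0, 2.0],
                      [1.0, 0.0, 3.0, 5.0],
                      [4.0, 3.0, 0.0, 1.5],
                      [2.0, 5.0, 1.5, 0.0]])
        cfg = FusionConfig(K=2, sigma=0.3)
        w = affinity(d, cfg)
        n = 4
        mu = np.array([np.sort(d[s][np.arange(n) != s])[:2].mean()
                       for s in range(n)])
        ref = np.zeros((n, n))
        for s in range(n):
            for t in range(n):
                eps = (mu[s] + mu[t] + d[s, t]) / 3.0
                scale = 0.3 * eps
                ref[s, t] = (np.exp(-d[s, t] ** 2 / (2 * scale ** 2))
                             / (scale * np.sqrt(2 * np.pi)))
        ref = (ref + ref.T) / 2
        np.testing.assert_allclose(w, ref, atol=1e-12)

    def test_monotone_in_distance(self):
        # at fixed bandwidth the kernel strictly decreases in distance
        for d1, d2 in ((0.5, 1.0), (1.0, 2.0)):
            eps = 1.0
            scale = 0.3 * eps
            w1 = np.exp(-d1 ** 2 / (2 * scale ** 2)) / scale
            w2 = np.exp(-d2 ** 2 / (2 * scale ** 2)) / scale
            assert w1 > w2

    def test_duplicated_samples_get_max_affinity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 5))
        x[5] = x[2]
        d = distance_continuous(x)
        w = affinity(d, FusionConfig(K=3))
        off = w[2].copy()
        off[2] = -np.inf
        assert np.argmax(off) == 5

    def test_k_too_large_clamped_with_warning(self):
        d = distance_continuous(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.warns(UserWarning):
            affinity(d, FusionConfig(K=20))


class TestSNF:
    def test_single_view_is_full_kernel(self):
        rng = np.random.default_rng(4)
        d = distance_continuous(rng.normal(size=(10, 6)))
        cfg = FusionConfig(K=3)
        w = affinity(d, cfg)
        net = snf_fuse([w], cfg)
        np.testing.assert_allclose(net.fused, net.per_view_full_kernel[0])

    def test_row_stochastic_invariants(self):
        rng = np.random.default_rng(5)
        cfg = FusionConfig(K=4, T=5)
        ws = [affinity(distance_continuous(rng.normal(size=(12, 8))), cfg)
              for _ in range(3)]
        net = snf_fuse(ws, cfg)
        p = net.fused
        np.testing.assert_allclose(np.diag(p), 0.5, atol=1e-10)
        off = p.sum(axis=1) - np.diag(p)
        np.testing.assert_allclose(off, 0.5, atol=1e-10)

    def test_two_views_recover_planted_groups(self):
        rng = np.random.default_rng(6)
        cfg = FusionConfig(K=5, T=10)
        x1, labels = _three_group_matrix(rng)
        x2, _ = _three_group_matrix(rng)
        ws = [affinity(distance_continuous(x), cfg) for x in (x1, x2)]
        net = snf_fuse(ws, cfg)
        pred = spectral_cluster(net.fused, 3, seed=0)
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(ValidationError):
            snf_fuse([np.ones((4, 4)), np.ones((5, 5))], FusionConfig(K=2))


class TestFusedDistance:
    def test_bounds_and_diagonal(self):
        rng = np.random.default_rng(7)
        cfg = FusionConfig(K=3)
        w = affinity(distance_continuous(rng.normal(size=(8, 4))), cfg)
        net = snf_fuse([w], cfg)
        d = fused_distance(net.fused)
        assert np.all((d >= 0) & (d <= 0.5))
        np.testing.assert_allclose(np.diag(d), 0.0)
        np.testing.assert_allclose(d, d.T)

    def test_zero_similarity_max_distance(self):
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        d = fused_distance(p)
        assert d[0, 1] == 0.5


class TestEmbed:
    def test_deterministic(self):
        rng = np.random.default_rng(8)
        d = distance_continuous(rng.normal(size=(12, 5)))
        xy1 = embed_2d(d, seed=1)
        xy2 = embed_2d(d, seed=1)
        np.testing.assert_allclose(xy1, xy2)
        assert xy1.shape == (12, 2)

    def test_single_sample(self):
        assert embed_2d(np.zeros((1, 1)), seed=0).shape == (1, 2)

    def test_separated_groups_recoverable(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(9)
        x, labels = _three_group_matrix(rng, shift=6.0)
        d = distance_continuous(x)
        xy = embed_2d(d, seed=0)
        pred = KMeans(3, random_state=0, n_init=10).fit_predict(xy)
        assert adjusted_rand_score(labels, pred) >= 0.9


class TestSpectral:
    def test_block_diagonal_exact(self):
        w = np.zeros((8, 8))
        w[:4, :4] = 1.0
        w[4:, 4:] = 1.0
        labels = spectral_cluster(w, 2, seed=0)
        assert adjusted_rand_score([0] * 4 + [1] * 4, labels) == 1.0

    def test_c_equals_n_singletons(self):
        rng = np.random.default_rng(10)
        w = affinity(distance_continuous(rng.normal(size=(6, 4))),
                     FusionConfig(K=2))
        labels = spectral_cluster(w, 6, seed=0)
        assert len(set(labels)) == 6

    def test_too_many_clusters(self):
        with pytest.raises(ValidationError):
            spectral_cluster(np.ones((3, 3)), 5)


class TestNMI:
    def test_identical(self):
        assert nmi([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_relabelled(self):
        assert nmi([0, 0, 1, 1], ["b", "b", "a", "a"]) == 1.0

    def test_independent_partitions_zero(self):
        assert nmi([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_trivial_partitions(self):
        assert nmi([0, 0, 0], [0, 0, 0]) == 1.0
        assert nmi([0, 0, 0], [0, 1, 2]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            nmi([0, 1], [0, 1, 2])


class TestConcordance:
    def test_identical_view_full_concordance(self):
        rng = np.random.default_rng(11)
        cfg = FusionConfig(K=4, C=2)
        x, _ = _three_group_matrix(rng, n_per=6)
        w = affinity(distance_continuous(x), cfg)
        conc, dist = concordance_network({"v": w}, w, cfg, seed=0)
        assert conc[("v", "fused")] == 1.0
        assert dist[("v", "fused")] == 0.0

    def test_symmetry_unit_diagonal(self):
        rng = np.random.default_rng(12)
        cfg = FusionConfig(K=4, C=2)
        w1 = affinity(distance_continuous(rng.normal(size=(12, 6))), cfg)
        w2 = affinity(distance_continuous(rng.normal(size=(12, 6))), cfg)
        conc, _ = concordance_network({"a": w1, "b": w2}, w1, cfg, seed=0)
        assert conc[("a", "b")] == conc[("b", "a")]
        assert conc[("a", "a")] == 1.0


class TestNMFConsensus:
    def test_planted_groups_recovered(self):
        rng = np.random.default_rng(13)
        x, labels = _three_group_matrix(rng, n_per=6, shift=3.0)
        res = nmf_consensus(x, k=3, n_runs=10, seed=0)
        assert adjusted_rand_score(labels, res["labels"]) == 1.0
        assert np.all(res["silhouettes"] > 0.5)

    def test_single_run_binary_consensus(self):
        rng = np.random.default_rng(14)
        x, _ = _three_group_matrix(rng)
        res = nmf_consensus(x, k=3, n_runs=1, seed=0)
        assert set(np.unique(res["consensus"])) <= {0.0, 1.0}

    def test_duplicated_rows_always_cocluster(self):
        rng = np.random.default_rng(15)
        x, _ = _three_group_matrix(rng)
        x[7] = x[6]
        res = nmf_consensus(x, k=3, n_runs=8, seed=0)
        assert res["consensus"][6, 7] == 1.0

    def test_k_exceeds_samples(self):
        with pytest.raises(ValidationError):
            nmf_consensus(np.ones((3, 4)), k=5)

    def test_negative_shift_applied(self):
        rng = np.random.default_rng(16)
        x, labels = _three_group_matrix(rng)
        res = nmf_consensus(x - 100.0, k=3, n_runs=5, seed=0)
        assert adjusted_rand_score(labels, res["labels"]) == 1.0
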