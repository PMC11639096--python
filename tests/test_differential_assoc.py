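import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from topohic.differential_assoc import (
    bh_adjust,
    closest_boundaries,
    count_de_near_differential,
    de_genes,
    differential_boundaries,
    percent_significant,
    reldist,
    reldist_histogram,
    welch_t_two_sided,
    window_assign,
)
from topohic.errors import ValidationError


class TestWelch:
    def test_equal_samples(self):
        t, p = welch_t_two_sided([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        # equal variances, n=5 each: diff=-1, se=1 -> t=-1
        t, _p = welch_t_two_sided([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert t == pytest.approx(-1.0)

    def test_matches_scipy_on_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 12))
            y = rng.normal(loc=0.3, size=rng.integers(3, 12))
            t, p = welch_t_two_sided(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_conventions(self):
        t, p = welch_t_two_sided([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        t, p = welch_t_two_sided([2.0, 2.0], [3.0, 3.0])
        assert p == 0.0 and np.isinf(t)

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            welch_t_two_sided([1.0], [1.0, 2.0])


class TestBH:
    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_hand_computed(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, 0.04)

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=64)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestPercentSignificant:
    def test_shh_vs_g3_printed_counts(self):
        assert percent_significant(2803, 13885) == 20.2

    def test_g3_vs_g4_printed_counts(self):
        assert percent_significant(1486, 13885) == 10.7

    def test_zero_tested_rejected(self):
        with pytest.raises(ValidationError):
            percent_significant(1, 0)


class TestDifferentialBoundaries:
    def _matrix(self, rng, effect=0.0, n_a=8, n_b=13, n_pos=60):
        x = rng.normal(size=(n_a + n_b, n_pos))
        x[:n_a, :5] += effect
        groups = np.array(["A"] * n_a + ["B"] * n_b)
        return x, groups

    def test_effect_detected(self):
        rng = np.random.default_rng(3)
        x, groups = self._matrix(rng, effect=3.0)
        results, summary = differential_boundaries(x, groups, "A", "B")
        sig = {r.position for r in results if r.padj < 0.05}
        assert {0, 1, 2, 3, 4} <= sig
        assert summary["n_tested"] == 60
        assert summary["percent_significant"] == percent_significant(
            summary["n_significant"], summary["n_tested"])

    def test_group_absent_errors(self):
        rng = np.random.default_rng(4)
        x, groups = self._matrix(rng)
        with pytest.raises(ValidationError):
            differential_boundaries(x, groups, "A", "Z")

    def test_positions_need_two_defined_per_group(self):
        rng = np.random.default_rng(5)
        x, groups = self._matrix(rng)
        x[np.array(groups) == "A", 10] = np.nan
        x[0, 11] = np.nan  # one missing: still >= 2 defined
        results, summary = differential_boundaries(x, groups, "A", "B")
        tested = {r.position for r in results}
        assert 10 not in tested and 11 in tested

    def test_zdiff_sign(self):
        rng = np.random.default_rng(6)
        x, groups = self._matrix(rng, effect=2.0)
        results, _ = differential_boundaries(x, groups, "A", "B")
        r0 = next(r for r in results if r.position == 0)
        assert r0.z_diff > 0 and r0.z_diff == pytest.approx(r0.mean_a - r0.mean_b)

    def test_null_fdr_controlled(self):
        rng = np.random.default_rng(7)
        fracs = []
        for _ in range(30):
            x, groups = self._matrix(rng, effect=0.0, n_pos=100)
            results, summary = differential_boundaries(x, groups, "A", "B")
            fracs.append(summary["n_significant"] / summary["n_tested"])
        assert np.mean(fracs) <= 0.05 + 2 * np.sqrt(0.05 / (30 * 100))


class TestDEGenes:
    def _counts(self, spec, groups_n=(("G3", 6), ("G4", 6))):
        from topohic.synthetic_cohort import simulate_expression

        cols = {}
        labels = []
        k = 0
        for group, n in groups_n:
            for _ in range(n):
                cols[f"{group}_{k}"] = simulate_expression(spec, group, k)
                labels.append(group)
                k += 1
        return pd.DataFrame(cols), np.array(labels)

    def test_planted_fold_change_power(self):
        from topohic.synthetic_cohort import default_spec

        spec = default_spec(seed=8)
        counts, labels = self._counts(spec)
        results = de_genes(counts, labels, "G4", "G3")
        de_names = {d.gene for d in spec.de_genes}
        hits = {r.gene for r in results if r.padj < 0.05}
        assert len(de_names & hits) / len(de_names) >= 0.9
        for r in results:
            if r.gene in de_names:
                assert r.log2_fc > 1.0  # planted 4-fold up in G4

    def test_type_one_error_near_alpha(self):
        from topohic.synthetic_cohort import default_spec

        spec = default_spec(seed=9, de_genes=(), n_genes=300)
        counts, labels = self._counts(spec)
        results = de_genes(counts, labels, "G4", "G3")
        frac_raw = np.mean([r.p < 0.05 for r in results])
        assert frac_raw < 0.12
        assert np.mean([r.padj < 0.05 for r in results]) <= 0.05

    def test_all_zero_gene_excluded(self):
        counts = pd.DataFrame({
            "s1": [0, 5, 9], "s2": [0, 9, 3], "s3": [0, 4, 4], "s4": [0, 7, 2]},
            index=["dead", "alive", "other"])
        results = de_genes(counts, ["A", "A", "B", "B"], "A", "B")
        assert "dead" not in {r.gene for r in results}
        assert {"alive", "other"} <= {r.gene for r in results}


class TestReldist:
    def test_on_boundary_zero(self):
        r = reldist([100.0], [100.0, 200.0])
        assert r[0] == 0.0

    def test_midpoint_half(self):
        r = reldist([150.0], [100.0, 200.0])
        assert r[0] == 0.5

    def test_outside_span_excluded(self):
        r = reldist([50.0, 150.0, 900.0], [100.0, 200.0])
        assert r.size == 1

    def test_uniform_calibration(self):
        rng = np.random.default_rng(10)
        bounds = np.arange(0, 101_000, 1_000)
        genes = rng.uniform(0, 100_000, size=1000)
        r = reldist(genes, bounds)
        scaled = r / 0.5
        stat = sps.kstest(scaled, "uniform")
        assert stat.statistic < 1.63 / np.sqrt(r.size)  # KS critical at 0.01

    def test_too_few_boundaries(self):
        with pytest.raises(ValidationError):
            reldist([10.0], [100.0])

    def test_histogram_shape(self):
        r = np.linspace(0, 0.49999, 200)
        hist = reldist_histogram(r)
        assert hist.shape[0] == 10
        assert hist["count"].sum() == 200
        np.testing.assert_allclose(hist["expected_fraction"], 0.1)


class TestClosest:
    def test_hand_case(self):
        genes = pd.DataFrame({"start": [100], "end": [200]}, index=["g"])
        out = closest_boundaries(genes, [50, 500])
        row = out.loc["g"]
        assert row["upstream"] == 50 and row["upstream_dist"] == -50
        assert row["downstream"] == 500 and row["downstream_dist"] == 300

    def test_boundary_inside_gene(self):
        genes = pd.DataFrame({"start": [100], "end": [200]}, index=["g"])
        out = closest_boundaries(genes, [150])
        row = out.loc["g"]
        assert row["upstream_dist"] == 0 and row["downstream_dist"] == 0

    def test_no_upstream(self):
        genes = pd.DataFrame({"start": [10], "end": [20]}, index=["g"])
        out = closest_boundaries(genes, [500, 900])
        row = out.loc["g"]
        assert row["upstream"] is None and row["downstream"] == 500


class TestWindowAssign:
    def _results(self):
        from topohic.differential_assoc import DifferentialBoundaryResult

        return [
            DifferentialBoundaryResult(9, 1, 0, 1, 2.0, 0.01, 0.2),
            DifferentialBoundaryResult(19, 1, 0, 1, 3.0, 0.001, 0.01),
            DifferentialBoundaryResult(399, 1, 0, 1, 3.0, 0.001, 0.005),
        ]

    def test_single_in_range(self):
        genes = pd.DataFrame({"start": [400_000], "end": [410_000]}, index=["g"])
        out = window_assign(genes, self._results()[:1], bin_size=50_000)
        assert out.loc["g", "boundary_position"] == 9

    def test_most_significant_wins(self):
        genes = pd.DataFrame({"start": [600_000], "end": [610_000]}, index=["g"])
        out = window_assign(genes, self._results()[:2], bin_size=50_000)
        assert out.loc["g", "boundary_position"] == 19

    def test_none_in_range(self):
        genes = pd.DataFrame({"start": [0], "end": [10_000]}, index=["g"])
        out = window_assign(genes, self._results()[2:], bin_size=50_000)
        assert out.loc["g", "boundary_position"] is None

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        from topohic.differential_assoc import DifferentialBoundaryResult

        results = [DifferentialBoundaryResult(
            int(pos), 0, 0, 0, 0.0, float(p), float(q))
            for pos, p, q in zip(rng.integers(0, 200, 30),
                                 rng.uniform(size=30), rng.uniform(size=30))]
        genes = pd.DataFrame({
            "start": rng.integers(0, 9_000_000, 10),
        }, index=[f"g{i}" for i in range(10)])
        genes["end"] = genes["start"] + 10_000
        out = window_assign(genes, results, bin_size=50_000)
        for gene, row in genes.iterrows():
            best = None
            for r in results:
                bp = (r.position + 1) * 50_000
                if row["start"] - 1_000_000 <= bp <= row["end"] + 1_000_000:
                    dist = max(row["start"] - bp, bp - row["end"], 0)
                    key = (r.padj, r.p, dist, bp)
                    if best is None or key < best[0]:
                        best = (key, r.position)
            expected = best[1] if best else None
            assert out.loc[gene, "boundary_position"] == expected


class TestCountDENearDifferential:
    def test_no_de_genes(self):
        count, table = count_de_near_differential([], [], pd.DataFrame(), 50_000)
        assert count == 0

    def test_planted_adjacency(self):
        from topohic.differential_assoc import (
            DEGeneResult,
            DifferentialBoundaryResult,
        )

        bin_size = 50_000
        # significant boundaries cluster low, non-significant cluster high so
        # genes between two non-significant neighbours exist
        bounds = [DifferentialBoundaryResult(p, 1, 0, 1, 5.0, 1e-5, 1e-4)
                  for p in (10, 20, 30, 40, 50)]
        bounds += [DifferentialBoundaryResult(p, 1, 0, 1, 0.1, 0.9, 0.95)
                   for p in (70, 80, 90, 100)]
        genes = {}
        de = []
        for k, p in enumerate((10, 20, 30, 40, 45)):  # flanked by significant
            name = f"de{k}"
            start = (p + 1) * bin_size + 1000
            genes[name] = (start, start + 5_000)
            de.append(DEGeneResult(name, 2.0, 1e-6, 1e-5, "c", start, start + 5000))
        for k, p in enumerate((70, 80, 90)):  # flanked by non-significant only
            name = f"null{k}"
            start = (p + 1) * bin_size + 1000
            genes[name] = (start, start + 5_000)
            de.append(DEGeneResult(name, 2.0, 1e-6, 1e-5, "c", start, start + 5000))
        frame = pd.DataFrame(
            {"start": [genes[g][0] for g in genes],
             "end": [genes[g][1] for g in genes]}, index=list(genes))
        count, table = count_de_near_differential(de, bounds, frame, bin_size)
        assert count == 5
        assert count <= len(de)
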