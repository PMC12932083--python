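import numpy as np
import pandas as pd
import pytest

from wmconn.stats import (
    bonferroni,
    clinical_correlation,
    compare_global,
    compare_nodal,
    two_sample_t,
)


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # pooled sd = 1, se = sqrt(2/3), diff = -3 -> t = -3.674, df = 4
        t, p = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.674, abs=1e-3)
        from scipy import stats as sps

        assert p == pytest.approx(2 * sps.t.sf(3.674, df=4), abs=1e-4)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([1.0, 1.0], [1.0, 1.0])

    def test_welch_variant_runs(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 9.0], pooled=False)
        assert np.isfinite(t) and 0 <= p <= 1

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha = 0.05 over 1000 simulations."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            _, p = two_sample_t(rng.standard_normal(42), rng.standard_normal(42))
            rejections += p < 0.05
        assert 0.037 <= rejections / n_sim <= 0.064


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, corrected, significant",
        [
            (0.004, 10, 0.04, True),
            (0.034, 10, 0.34, False),
            (0.0003, 128, 0.0384, True),
        ],
    )
    def test_correction_arithmetic(self, p, m, corrected, significant):
        corr, flags = bonferroni([p], m=m)
        assert corr[0] == pytest.approx(corrected)
        assert bool(flags[0]) is significant

    def test_corrected_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        corr, _ = bonferroni(p, m=60)
        assert np.all(corr >= p)
        assert np.all(corr <= 1.0)

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], m=2)


class TestCompareGlobal:
    def _table(self, rng, shift=0.0):
        n = 12
        data = {
            "cp": np.r_[rng.standard_normal(n) + shift, rng.standard_normal(n)],
            "lp": rng.standard_normal(2 * n),
        }
        groups = ["smoker"] * n + ["control"] * n
        return pd.DataFrame(data), groups

    def test_group_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(8)
        table, groups = self._table(rng, shift=1.0)
        fwd = compare_global(table, groups)
        swapped = ["control" if g == "smoker" else "smoker" for g in groups]
        rev = compare_global(table, swapped)
        for f, r in zip(fwd, rev):
            assert f.p == pytest.approx(r.p)
            assert f.t == pytest.approx(-r.t)

    def test_shift_detected_in_correct_metric(self):
        rng = np.random.default_rng(15)
        table, groups = self._table(rng, shift=2.0)
        results = {r.metric: r for r in compare_global(table, groups)}
        assert results["cp"].p < 0.01
        assert results["cp"].t > 0  # smoker minus control orientation
        assert results["cp"].m == 10

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            compare_global(pd.DataFrame(), ["smoker", "control"])


class TestCompareNodal:
    def test_identical_groups_give_zero_t(self):
        vals = np.tile(np.arange(6.0)[:, None], (2, 4))
        groups = ["smoker"] * 6 + ["control"] * 6
        results = compare_nodal({"dc": vals}, groups)
        assert all(r.t == pytest.approx(0.0) for r in results)
        assert all(r.m == 4 for r in results)

    def test_effect_localizes_to_shifted_nodes(self):
        rng = np.random.default_rng(21)
        n, nodes = 20, 32
        table = rng.standard_normal((2 * n, nodes))
        table[:n, :8] += 1.5  # effect confined to the first 8 nodes
        groups = ["smoker"] * n + ["control"] * n
        results = compare_nodal({"ncp": table}, groups)
        top8 = sorted(results, key=lambda r: -abs(r.t))[:8]
        hits = sum(1 for r in top8 if r.node <= 8)
        assert hits >= 6


class TestClinicalCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = clinical_correlation(x, x)
        assert res.r == pytest.approx(1.0)

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        sp_raw = clinical_correlation(x, y, method="spearman")
        sp_exp = clinical_correlation(x, np.exp(y), method="spearman")
        assert sp_raw.r == pytest.approx(sp_exp.r)
        pe_raw = clinical_correlation(x, y, method="pearson")
        pe_exp = clinical_correlation(x, np.exp(y), method="pearson")
        assert pe_raw.r != pytest.approx(pe_exp.r, abs=1e-6)

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        y = np.array([2.0, 4.0, 6.0, 8.0, 1.0])
        res = clinical_correlation(x, y)
        assert res.n == 4
        assert res.r == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            clinical_correlation(np.ones(5), np.arange(5.0))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            clinical_correlation(np.arange(5.0), np.arange(5.0), method="kendall")
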