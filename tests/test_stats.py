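"""Statistical layer: depletion, Dunnett, binned KS, R^2, calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from mgquant import stats
from mgquant.ihc import IntensityHistogram


def _cohort(groups: dict[str, list[float]], region: str = "r") -> pd.DataFrame:
    rows = []
    for g, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "animal_id": f"{g}-{i}",
                    "group": g,
                    "sex": "M" if i % 2 == 0 else "F",
                    "region": region,
                    "density": v,
                }
            )
    return pd.DataFrame(rows)


class TestDepletion:
    def test_equal_means_zero_percent(self):
        t = _cohort({"control": [100, 100], "trt": [100, 100]})
        (d,) = stats.depletion_percent(t, "control", "r")
        assert d.percent_depletion == 0.0

    def test_arithmetic(self):
        t = _cohort({"control": [90, 110], "trt": [30, 40]})
        (d,) = stats.depletion_percent(t, "control", "r")
        assert d.percent_depletion == pytest.approx(100 * (1 - 35 / 100))

    def test_repopulation_negative(self):
        t = _cohort({"control": [100, 100], "trt": [115, 125]})
        (d,) = stats.depletion_percent(t, "control", "r")
        assert d.percent_depletion == pytest.approx(-20.0)

    def test_zero_control_mean_errors(self):
        t = _cohort({"control": [0, 0], "trt": [10, 20]})
        with pytest.raises(ZeroDivisionError):
            stats.depletion_percent(t, "control", "r")

    def test_delta_method_se_matches_bootstrap(self, rng):
        ctrl = rng.normal(100, 10, 6)
        trt = rng.normal(40, 6, 6)
        t = _cohort({"control": list(ctrl), "trt": list(trt)})
        (d,) = stats.depletion_percent(t, "control", "r")
        boot = []
        for _ in range(4000):
            bc = rng.choice(ctrl, 6)
            bt = rng.choice(trt, 6)
            boot.append(100 * (1 - bt.mean() / bc.mean()))
        assert d.se == pytest.approx(np.std(boot), rel=0.25)


class TestAnovaDunnett:
    def test_single_treatment_equals_pooled_t_test(self, rng):
        for _ in range(5):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.5, 1, 8)
            t = _cohort({"control": list(a), "trt": list(b)})
            res = stats.anova_dunnett(t, "control", "r")
            t_p = sps.ttest_ind(b, a, equal_var=True).pvalue
            assert res.p_adjusted[0] == pytest.approx(t_p, abs=1e-8)

    def test_identical_groups_degenerate_null(self):
        vals = [10.0, 12.0, 11.0, 9.0]
        t = _cohort({"control": vals, "a": vals, "b": vals})
        res = stats.anova_dunnett(t, "control", "r")
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert np.all(res.p_adjusted > 0.999)

    def test_adjusted_p_dominates_unadjusted(self, rng):
        a = rng.normal(0, 1, 6)
        groups = {"control": list(a)}
        for i in range(3):
            groups[f"g{i}"] = list(rng.normal(0.3, 1, 6))
        t = _cohort(groups)
        res = stats.anova_dunnett(t, "control", "r")
        for tt, p_adj in zip(res.t_statistics, res.p_adjusted):
            p_raw = 2 * sps.t.sf(abs(tt), res.df_resid)
            assert p_adj >= p_raw - 1e-10

    def test_adjusted_p_monotone_in_comparisons(self, rng):
        data = {f"g{i}": list(rng.normal(0, 1, 6)) for i in range(4)}
        data["control"] = list(rng.normal(0, 1, 6))
        # same focal contrast, growing family: adjusted p non-decreasing
        t_focal = 2.2
        prev = 0.0
        for k in (1, 2, 3, 4):
            p = stats.dunnett_pvalue(t_focal, [6] * k, 6, df=25)
            assert p >= prev - 1e-12
            prev = p

    def test_f_matches_reference_on_random_cohorts(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 6))
            groups = {
                (f"g{i}" if i else "control"): list(
                    rng.normal(rng.normal(), 1, int(rng.integers(3, 9)))
                )
                for i in range(k)
            }
            t = _cohort(groups)
            res = stats.anova_dunnett(t, "control", "r")
            ref = sps.f_oneway(*[np.asarray(v) for v in groups.values()])
            assert res.f_statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert res.f_pvalue == pytest.approx(ref.pvalue, abs=1e-8)

    def test_matches_scipy_dunnett(self, rng):
        for _ in range(3):
            control = rng.normal(size=6)
            groups = [rng.normal(0.4, 1, size=6) for _ in range(3)]
            ref = sps.dunnett(*groups, control=control, random_state=99)
            t = _cohort(
                {"control": list(control), **{f"g{i}": list(g) for i, g in enumerate(groups)}}
            )
            res = stats.anova_dunnett(t, "control", "r")
            assert np.allclose(res.p_adjusted, ref.pvalue, atol=2e-3)

    def test_insufficient_replication_errors(self):
        t = _cohort({"control": [1.0, 2.0], "trt": [3.0]})
        with pytest.raises(ValueError):
            stats.anova_dunnett(t, "control", "r")


def _hist(counts):
    edges = np.arange(0, 256, 5)
    c = np.zeros(len(edges) - 1, dtype=int)
    c[: len(counts)] = counts
    return IntensityHistogram(edges, c)


def _ks_oracle(ca, cb):
    """Exhaustive scan of CDF gaps over all bin boundaries."""
    na, nb = sum(ca), sum(cb)
    best = 0.0
    fa = fb = 0
    for a, b in zip(ca, cb):
        fa += a
        fb += b
        best = max(best, abs(fa / na - fb / nb))
    return best


class TestKsBinned:
    def test_identical_histograms_d_zero(self):
        h = _hist([3, 4, 5])
        d, p = stats.ks_binned(h, h)
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_support_d_one(self):
        a = _hist([10, 0, 0, 0])
        b = _hist([0, 0, 0, 10])
        d, _ = stats.ks_binned(a, b)
        assert d == 1.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        hst.lists(hst.integers(0, 20), min_size=5, max_size=51),
        hst.lists(hst.integers(0, 20), min_size=5, max_size=51),
    )
    def test_d_matches_exhaustive_oracle(self, ca, cb):
        if sum(ca) == 0 or sum(cb) == 0:
            return
        ca = ca + [0] * (51 - len(ca))
        cb = cb + [0] * (51 - len(cb))
        d, _ = stats.ks_binned(_hist(ca), _hist(cb))
        assert d == pytest.approx(_ks_oracle(ca, cb), abs=1e-15)

    def test_mismatched_edges_error(self):
        a = _hist([1, 2])
        b = IntensityHistogram(np.arange(0, 256, 17), np.ones(15, int))
        with pytest.raises(ValueError):
            stats.ks_binned(a, b)


class TestConcentrationResponseR2:
    def test_perfect_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert stats.concentration_response_r2(x, 3 * x - 1) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        x = rng.uniform(0, 10, 200)
        y = rng.permutation(rng.normal(size=200))
        assert stats.concentration_response_r2(x, y) < 0.05

    def test_affine_invariance_in_x(self, rng):
        x = rng.uniform(0, 5, 30)
        y = 2 * x + rng.normal(0, 1, 30)
        r2 = stats.concentration_response_r2(x, y)
        assert stats.concentration_response_r2(7 * x - 3, y) == pytest.approx(r2)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            stats.concentration_response_r2([1, 2, 3], [5, 5, 5])


class TestCalibration:
    STANDARDS_X = np.array([0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0])

    def _exact_curve(self, a=0.1, b=2.0, c=0.05):
        x = self.STANDARDS_X
        return x, a + b * x + c * x**2

    def test_noiseless_recovery_machine_precision(self):
        x, y = self._exact_curve()
        curve = stats.fit_calibration(x, y)
        assert curve.coefficients == pytest.approx((0.1, 2.0, 0.05), abs=1e-10)

    def test_linear_data_gives_zero_quadratic(self):
        x = self.STANDARDS_X
        curve = stats.fit_calibration(x, 0.2 + 3.0 * x)
        assert curve.coefficients[2] == pytest.approx(0.0, abs=1e-9)

    def test_weighting_matters_on_heteroscedastic_data(self, rng):
        x = np.repeat(self.STANDARDS_X, 8)
        y = 2.0 * x + rng.normal(0, 1, len(x)) * (0.2 * x)  # noise ~ x
        wfit = stats.fit_calibration(x, y)
        X = np.column_stack([np.ones_like(x), x, x**2])
        ufit, *_ = np.linalg.lstsq(X, y, rcond=None)
        # low-x standards are fitted better by the weighted curve
        low = x <= 0.1
        wres = np.abs(wfit.predict(x[low]) - y[low]).mean()
        ures = np.abs(X[low] @ ufit - y[low]).mean()
        assert not np.allclose(wfit.coefficients, ufit)
        assert wres <= ures

    def test_back_calculation_inverts_standards(self):
        x, y = self._exact_curve()
        curve = stats.fit_calibration(x, y)
        for xi, yi in zip(x, y):
            res = stats.back_calculate(curve, yi)
            assert res.concentration == pytest.approx(xi, rel=1e-9)

    def test_below_lloq_flagged(self):
        x, y = self._exact_curve()
        curve = stats.fit_calibration(x, y)
        tiny = stats.back_calculate(curve, curve.predict(0.005))
        assert tiny.below_lloq  # 0.005 uM < default LLOQ of 0.0073 uM
        ok = stats.back_calculate(curve, curve.predict(0.5))
        assert not ok.below_lloq
        assert curve.lloq == pytest.approx(0.0073)

    def test_monotone_larger_ratio_larger_concentration(self):
        x, y = self._exact_curve()
        curve = stats.fit_calibration(x, y)
        c1 = stats.back_calculate(curve, 1.0).concentration
        c2 = stats.back_calculate(curve, 2.0).concentration
        assert c2 > c1

    def test_error_cases(self):
        with pytest.raises(ValueError):
            stats.fit_calibration([0.0, 1, 2, 3], [0, 1, 2, 3])  # zero conc
        with pytest.raises(ValueError):
            stats.fit_calibration([1, 1, 2, 2], [1, 1, 2, 2])  # <4 distinct
        x, y = self._exact_curve()
        curve = stats.fit_calibration(x, y)
        with pytest.raises(ValueError):
            stats.back_calculate(curve, 1e6)  # far outside response range

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        hst.floats(0.0, 1.0),
        hst.floats(0.5, 5.0),
        hst.floats(0.0, 0.2),
        hst.floats(0.02, 9.0),
    )
    def test_roundtrip_property(self, a, b, c, x0):
        x = self.STANDARDS_X
        curve = stats.fit_calibration(x, a + b * x + c * x**2)
        res = stats.back_calculate(curve, curve.predict(x0))
        assert res.concentration == pytest.approx(x0, rel=1e-6, abs=1e-9)


class TestAnalyzeCohort:
    def test_tidy_output_and_sex_strata(self, rng):
        from mgquant import synthetic as syn

        table, _ = syn.generate_cohort(syn.default_design(seed=5))
        out = stats.analyze_cohort(table, control="control", by_sex=True)
        assert set(out["stratum"]) == {"pooled", "M", "F"}
        pooled = out[out.stratum == "pooled"]
        assert len(pooled) == 3 * 3  # 3 regions x 3 treatment groups
        strong = pooled[
            (pooled.region == "fimbria") & (pooled.group == "anti-CSF1")
        ]
        assert strong.percent_depletion.iloc[0] == pytest.approx(65, abs=15)
        assert strong.p_adjusted.iloc[0] < 0.001
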