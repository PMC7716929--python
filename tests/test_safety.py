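import numpy as np
import pandas as pd
import pytest

from riskscreen.datasets import ATTENDANCE_FIRST_FOLLOWUP, STDR_24M
from riskscreen.safety import (
    Margin,
    PooledEstimate,
    ProportionDiff,
    equivalence_verdict,
    impute_missing,
    newcombe_diff_ci,
    noninferiority_verdict,
    rubin_pool,
    simple_imputation,
    subgroup_analysis,
    wilson_ci,
)


class TestWilson:
    def test_zero_events_closed_form(self):
        lo, hi = wilson_ci(0, 10)
        assert lo == 0.0
        z2 = 1.959963984540054**2
        assert hi == pytest.approx(z2 / (10 + z2))  # ~0.2775

    def test_all_events_upper_is_one(self):
        lo, hi = wilson_ci(10, 10)
        assert hi == 1.0
        assert lo == pytest.approx(1 - wilson_ci(0, 10)[1])

    def test_direct_formula_evaluation(self):
        lo, hi = wilson_ci(5, 10)
        assert (lo, hi) == (pytest.approx(0.2366, abs=5e-5), pytest.approx(0.7634, abs=5e-5))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)


class TestNewcombe:
    def test_overall_attendance_row(self):
        """Printed overall first-follow-up attendance row reproduces to 3 dp."""
        d, lo, hi = newcombe_diff_ci(ProportionDiff(1754, 2097, 1883, 2224))
        assert round(d, 3) == -0.010
        assert round(lo, 3) == -0.032
        assert round(hi, 3) == 0.012

    def test_low_risk_stdr_lower_bound(self):
        d, lo, hi = newcombe_diff_ci(ProportionDiff(4, 1650, 10, 1709))
        assert round(lo, 3) == -0.009

    def test_equal_arms_symmetric_about_zero(self):
        d, lo, hi = newcombe_diff_ci(ProportionDiff(50, 100, 50, 100))
        assert d == 0.0
        assert lo == pytest.approx(-hi)

    def test_antisymmetry_under_arm_swap(self):
        d1, l1, u1 = newcombe_diff_ci(ProportionDiff(30, 80, 55, 90))
        d2, l2, u2 = newcombe_diff_ci(ProportionDiff(55, 90, 30, 80))
        assert d2 == pytest.approx(-d1)
        assert l2 == pytest.approx(-u1)
        assert u2 == pytest.approx(-l1)

    def test_interval_contains_difference(self):
        pd_ = ProportionDiff(141, 195, 157, 203)
        d, lo, hi = newcombe_diff_ci(pd_)
        assert lo <= d <= hi

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ProportionDiff(11, 10, 0, 10)


class TestVerdicts:
    def test_equivalence_within_margin(self):
        v = equivalence_verdict((-0.032, 0.012))
        assert v.label == "equivalent"

    def test_equivalence_fails_for_wide_ci(self):
        v = equivalence_verdict((-0.136, 0.035))
        assert v.label == "not-established"

    def test_boundary_touching_not_established(self):
        v = equivalence_verdict((-0.05, 0.05))
        assert v.label == "not-established"

    def test_noninferior_when_lower_bound_above_margin(self):
        assert noninferiority_verdict((-0.011, 0.005)).label == "non-inferior"
        assert noninferiority_verdict((-0.009, 0.001)).label == "non-inferior"

    def test_not_noninferior_when_lower_bound_below_margin(self):
        assert noninferiority_verdict((-0.020, 0.001)).label == "not-established"

    def test_margin_monotonicity(self):
        ci = (-0.04, 0.03)
        assert equivalence_verdict(ci, Margin(equivalence=0.05)).established
        assert equivalence_verdict(ci, Margin(equivalence=0.06)).established
        assert not equivalence_verdict(ci, Margin(equivalence=0.03)).established

    def test_invalid_margin_rejected(self):
        with pytest.raises(ValueError):
            Margin(equivalence=0.0)


class TestSubgroups:
    def _tables(self, source, outcome="per_protocol"):
        t = source[outcome]
        return {
            g: (*t[g]["individualised"][::-1][::-1], *t[g]["control"])
            for g in ("high", "medium", "low")
        }

    def test_saturated_glm_reproduces_observed_proportions(self):
        """Arm x group interaction GLM is saturated for the 2x3 layout."""
        tables = {
            g: (
                ATTENDANCE_FIRST_FOLLOWUP["per_protocol"][g]["individualised"][0],
                ATTENDANCE_FIRST_FOLLOWUP["per_protocol"][g]["individualised"][1],
                ATTENDANCE_FIRST_FOLLOWUP["per_protocol"][g]["control"][0],
                ATTENDANCE_FIRST_FOLLOWUP["per_protocol"][g]["control"][1],
            )
            for g in ("high", "medium", "low")
        }
        res = subgroup_analysis(tables)
        fp = res.glm_fitted_props
        assert np.allclose(fp["fitted_prop"], fp["observed_prop"], atol=1e-8)

    def test_per_group_ci_matches_direct_newcombe(self):
        tables = {
            g: (
                STDR_24M["per_protocol"][g]["individualised"][0],
                STDR_24M["per_protocol"][g]["individualised"][1],
                STDR_24M["per_protocol"][g]["control"][0],
                STDR_24M["per_protocol"][g]["control"][1],
            )
            for g in ("high", "medium", "low")
        }
        res = subgroup_analysis(tables)
        for g, (x1, n1, x2, n2) in tables.items():
            direct = newcombe_diff_ci(ProportionDiff(x1, n1, x2, n2))
            assert res.per_group[g] == pytest.approx(direct)

    def test_identical_rates_give_null_interactions(self):
        tables = {"high": (80, 100, 160, 200), "low": (40, 100, 80, 200)}
        res = subgroup_analysis(tables)
        inter = [v for k, v in res.glm_params.items() if k.startswith("arm")]
        assert np.allclose(inter, 0.0, atol=1e-6)

    def test_empty_group_skipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="empty"):
            subgroup_analysis({"high": (1, 10, 0, 0), "low": (5, 10, 6, 10)})


class TestImputation:
    def test_rubin_formula_arithmetic(self):
        pooled = rubin_pool([0.1, 0.2, 0.3], [0.01, 0.01, 0.01])
        assert pooled.estimate == pytest.approx(0.2)
        assert pooled.between == pytest.approx(0.01)
        assert pooled.variance == pytest.approx(0.01 + (4 / 3) * 0.01)

    def test_pooling_needs_two_sets(self):
        with pytest.raises(ValueError):
            rubin_pool([0.1], [0.01])

    def test_no_missing_values_identity(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"y": rng.integers(0, 2, 200).astype(float), "age": rng.normal(60, 10, 200)}
        )
        sets = impute_missing(df, "y", ["age"], m=3, seed=1)
        for s in sets:
            assert (s["y"] == df["y"]).all()
        ests = [s["y"].mean() for s in sets]
        pooled = rubin_pool(ests, [0.001] * 3)
        assert pooled.between == pytest.approx(0.0)
        assert pooled.df == np.inf

    def test_mcar_missingness_pooled_estimate_unbiased(self):
        """Pooled attendance difference unbiased under 10% MCAR outcomes.

        Paired against each replicate's full-data difference before
        masking, which isolates the imputation step from data-generation
        noise.
        """
        reps = 200
        p_c, p_i = 0.85, 0.84
        bias = np.empty(reps)
        ss = np.random.SeedSequence(31).spawn(reps)
        for r, sub in enumerate(ss):
            rng = np.random.default_rng(sub)
            n = 600
            arm = np.repeat([0.0, 1.0], n)
            p = np.where(arm == 1, p_i, p_c)
            y_full = (rng.random(2 * n) < p).astype(float)
            full_diff = y_full[arm == 1].mean() - y_full[arm == 0].mean()
            y = y_full.copy()
            y[rng.random(2 * n) < 0.10] = np.nan
            df = pd.DataFrame({"y": y, "arm": arm, "age": rng.normal(60, 10, 2 * n)})
            sets = impute_missing(df, "y", ["arm", "age"], m=5,
                                  seed=int(sub.generate_state(1)[0] % 2**31))
            ests, variances = [], []
            for s in sets:
                pi_hat = s.loc[s["arm"] == 1, "y"].mean()
                pc_hat = s.loc[s["arm"] == 0, "y"].mean()
                ests.append(pi_hat - pc_hat)
                variances.append(pi_hat * (1 - pi_hat) / n + pc_hat * (1 - pc_hat) / n)
            bias[r] = rubin_pool(ests, variances).estimate - full_diff
        mc_se = bias.std(ddof=1) / np.sqrt(reps)
        assert abs(bias.mean()) < 2 * mc_se + 1e-4

    def test_simple_imputation_fill_rules(self):
        df = pd.DataFrame({"y": [1.0, np.nan, 0.0]})
        assert simple_imputation(df, "y", "all")["y"].tolist() == [1.0, 1.0, 0.0]
        assert simple_imputation(df, "y", "none")["y"].tolist() == [1.0, 0.0, 0.0]
        with pytest.raises(ValueError):
            simple_imputation(df, "y", "median")
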