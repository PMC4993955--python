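"""Propensity model estimation, nearest-neighbour matching, balance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

from kneeshape.propensity import (
    PropensityModel,
    SeparationError,
    balance,
    categorize_covariates,
    match,
    standardized_difference_binary,
    standardized_difference_continuous,
)


def _records(n, rng):
    return pd.DataFrame({
        "knee_id": [f"K{i:04d}" for i in range(n)],
        "participant_id": [f"P{i:04d}" for i in range(n)],
        "side": rng.choice(["left", "right"], n),
        "age": rng.uniform(45, 79, n),
        "gender": rng.choice(["female", "male"], n),
        "bmi": rng.uniform(19, 42, n),
        "nrs_pain": rng.integers(0, 11, n),
    })


class TestCategorize:
    def test_age_floors_to_band(self):
        df = pd.DataFrame({"knee_id": ["a", "b", "c"], "age": [64.9, 45.0, 80.0],
                           "bmi": [25.0, 25.0, 25.0]})
        out = categorize_covariates(df)
        assert list(out["age_band"]) == ["60-64", "45-49", "75+"]

    def test_who_weight_bins_with_underweight_merged(self):
        df = pd.DataFrame({"knee_id": list("abcd"), "age": [60.0] * 4,
                           "bmi": [18.0, 24.9, 29.9, 30.0]})
        out = categorize_covariates(df)
        assert list(out["weight_category"]) == [
            "normal/underweight", "normal/underweight", "overweight", "obese",
        ]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="age"):
            categorize_covariates(pd.DataFrame(
                {"knee_id": ["a"], "age": [44.0], "bmi": [25.0]}))
        with pytest.raises(ValueError, match="bmi"):
            categorize_covariates(pd.DataFrame(
                {"knee_id": ["a"], "age": [50.0], "bmi": [0.0]}))


class TestLogisticFit:
    def test_two_by_two_closed_form(self):
        """Single binary covariate: the slope is log(ad/bc)."""
        a, b, c, d = 30, 20, 15, 35  # (y=1,x=1), (y=1,x=0), (y=0,x=1), (y=0,x=0)
        y = np.r_[np.ones(a + b), np.zeros(c + d)]
        x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        exog = pd.DataFrame({"intercept": np.ones_like(y), "x": x})
        res = PropensityModel(y, exog).fit()
        assert res.params["x"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_matches_statsmodels_reference(self, rng):
        """MLE agrees with an independent IRLS implementation to 1e-6."""
        import statsmodels.api as sm

        n = 300
        x = rng.normal(size=(n, 3))
        eta = -0.5 + x @ np.array([0.8, -0.4, 0.2])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        exog = pd.DataFrame(np.column_stack([np.ones(n), x]),
                            columns=["intercept", "x1", "x2", "x3"])
        ours = PropensityModel(y, exog).fit()
        ref = sm.Logit(y, exog.to_numpy()).fit(disp=0, method="newton", tol=1e-10)
        np.testing.assert_allclose(ours.params.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.llf, ref.llf, atol=1e-6)

    def test_null_simulation_has_no_spurious_signal(self):
        """Outcome independent of covariates: non-intercept |z| stay below 4."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 400
            exog = pd.DataFrame(np.column_stack([np.ones(n), rng.normal(size=(n, 3))]),
                                columns=["intercept", "x1", "x2", "x3"])
            y = (rng.random(n) < 0.3).astype(float)
            res = PropensityModel(y, exog).fit()
            assert np.all(np.abs(res.zvalues.drop("intercept")) < 4.0)

    def test_perfect_separation_detected(self):
        x = np.r_[np.linspace(-3, -1, 20), np.linspace(1, 3, 20)]
        y = (x > 0).astype(float)
        exog = pd.DataFrame({"intercept": np.ones_like(x), "x": x})
        with pytest.raises(SeparationError):
            PropensityModel(y, exog).fit()

    def test_singular_design_rejected_with_column_hint(self, rng):
        n = 100
        x = rng.normal(size=n)
        exog = pd.DataFrame({"intercept": np.ones(n), "x": x, "x_copy": x})
        y = (rng.random(n) < 0.5).astype(float)
        with pytest.raises(ValueError, match="singular design"):
            PropensityModel(y, exog).fit()


class TestMatching:
    def _frames(self, ps_cases, ps_controls, rng):
        cases = _records(len(ps_cases), rng)
        controls = _records(len(ps_controls), np.random.default_rng(rng.integers(1 << 30)))
        controls["knee_id"] = [f"C{i:04d}" for i in range(len(ps_controls))]
        return cases, controls

    def test_single_pair(self, rng):
        cases, controls = self._frames([0.8], [0.7], rng)
        pairs, rep = match(cases, controls, np.array([0.8]), np.array([0.7]))
        assert rep.n_pairs == 1
        assert pairs.loc[0, "abs_diff"] == pytest.approx(0.1)

    def test_equidistant_tie_resolved_by_control_id(self, rng):
        """|0.9-0.8| == |0.7-0.8|: the lexicographically first control wins."""
        cases, controls = self._frames([0.8], [0.7, 0.9], rng)
        pairs, _ = match(cases, controls, np.array([0.8]), np.array([0.7, 0.9]))
        assert pairs.loc[0, "control_id"] == "C0000"
        again, _ = match(cases, controls, np.array([0.8]), np.array([0.7, 0.9]))
        pd.testing.assert_frame_equal(pairs, again)

    def test_no_control_reused_and_pool_exhaustion(self, rng):
        ps_c = rng.uniform(0.2, 0.8, 40)
        ps_k = rng.uniform(0.2, 0.8, 60)
        cases, controls = self._frames(ps_c, ps_k, rng)
        pairs, _ = match(cases, controls, ps_c, ps_k)
        assert not pairs["control_id"].duplicated().any()
        with pytest.raises(ValueError, match="shortfall"):
            match(controls, cases, ps_k, ps_c)

    def test_greedy_never_beats_hungarian_oracle(self, rng):
        """Total |dPS| of greedy matching is >= the optimal assignment."""
        for _ in range(60):
            n_case = int(rng.integers(2, 9))
            n_ctrl = int(rng.integers(n_case, n_case + 8))
            ps_c = rng.random(n_case)
            ps_k = rng.random(n_ctrl)
            cases, controls = self._frames(ps_c, ps_k, rng)
            pairs, _ = match(cases, controls, ps_c, ps_k)
            greedy_total = pairs["abs_diff"].sum()
            cost = np.abs(ps_c[:, None] - ps_k[None, :])
            rows, cols = linear_sum_assignment(cost)
            optimal_total = cost[rows, cols].sum()
            assert greedy_total >= optimal_total - 1e-12

    def test_exact_gender_constraint(self, rng):
        cases, controls = self._frames([0.5], [0.5, 0.5], rng)
        cases["gender"] = ["female"]
        controls["gender"] = ["male", "female"]
        pairs, _ = match(cases, controls, np.array([0.5]),
                         np.array([0.5, 0.5]), exact_gender=True)
        assert pairs.loc[0, "control_id"] == "C0001"


class TestBalance:
    def test_continuous_standardized_difference_arithmetic(self, rng):
        """Means 5 vs 4 with both sd = 2 give a 50% standardized difference."""
        x = rng.normal(5.0, 2.0, 20000)
        y = rng.normal(4.0, 2.0, 20000)
        assert standardized_difference_continuous(x, y) == pytest.approx(50.0, abs=2.0)

    def test_identical_arms_balance_exactly(self, rng):
        df = _records(50, rng)
        rep = balance(df, df.copy())
        assert np.allclose(rep["std_diff"].fillna(0.0), 0.0)

    def test_equal_prevalence_gives_zero(self):
        a = np.r_[np.ones(40), np.zeros(60)]
        assert standardized_difference_binary(a, np.roll(a, 7)) == 0.0

    def test_zero_pooled_sd_reported_undefined(self):
        assert np.isnan(standardized_difference_continuous([1.0, 1.0], [2.0, 2.0]))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_matching_is_deterministic_and_injective(seed):
    """Property: for arbitrary score configurations, matching never reuses a
    control and is a pure function of (scores, ids)."""
    rng = np.random.default_rng(seed)
    n_case = int(rng.integers(1, 12))
    n_ctrl = int(rng.integers(n_case, n_case + 15))
    ps_c = np.round(rng.random(n_case), 2)
    ps_k = np.round(rng.random(n_ctrl), 2)
    cases = _records(n_case, rng)
    controls = _records(n_ctrl, np.random.default_rng(seed + 1))
    controls["knee_id"] = [f"C{i:04d}" for i in range(n_ctrl)]
    p1, _ = match(cases, controls, ps_c, ps_k)
    p2, _ = match(cases, controls, ps_c, ps_k)
    pd.testing.assert_frame_equal(p1, p2)
    assert p1["control_id"].nunique() == n_case
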