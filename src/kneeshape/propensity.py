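"""Propensity (stratification) score estimation, matching and balance.

The propensity model is the probability of the TKR outcome given baseline
covariates: 5-year age bands, gender, WHO weight category (underweight
merged into normal), ipsilateral pain NRS (continuous) and knee side.
KL grade is deliberately omitted: it directly drives the decision to
operate (over-matching) and is moderately correlated with the shape vector
whose effect the matched analysis estimates.

Controls are matched to cases 1:1 by nearest propensity score without
replacement (greedy, cases in descending score order, deterministic
tie-breaks).  Balance is reported as standardized differences with the
conventional 10% (continuous) and 0.1 (dichotomous) thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "categorize_covariates",
    "build_design",
    "PropensityModel",
    "PropensityResults",
    "SeparationError",
    "ConvergenceError",
    "match",
    "MatchReport",
    "balance",
    "standardized_difference_continuous",
    "standardized_difference_binary",
]

AGE_BANDS = ("45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75+")
WEIGHT_CATEGORIES = ("normal/underweight", "overweight", "obese")


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class ConvergenceError(RuntimeError):
    """Newton iterations failed to converge."""


def categorize_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``age_band`` (5-year groups) and ``weight_category`` (WHO bins).

    WHO BMI bins: underweight (<18.5) merged with normal (18.5-24.9),
    overweight (25-29.9), obese (>=30).
    """
    out = df.copy()
    age = np.asarray(out["age"], dtype=float)
    bmi = np.asarray(out["bmi"], dtype=float)
    if np.any(age < 45):
        bad = out.loc[age < 45, "knee_id"].head(3).tolist()
        raise ValueError(f"age below 45 not supported (e.g. {bad})")
    if np.any(bmi <= 0) or np.any(~np.isfinite(bmi)):
        raise ValueError("bmi must be positive and finite")
    band_idx = np.minimum(((age - 45) // 5).astype(int), len(AGE_BANDS) - 1)
    out["age_band"] = pd.Categorical(
        np.asarray(AGE_BANDS)[band_idx], categories=AGE_BANDS
    )
    wc = np.where(bmi >= 30.0, "obese", np.where(bmi >= 25.0, "overweight", "normal/underweight"))
    out["weight_category"] = pd.Categorical(wc, categories=WEIGHT_CATEGORIES)
    return out


def build_design(df: pd.DataFrame) -> pd.DataFrame:
    """Propensity design matrix: intercept, age-band and weight dummies
    (first level as reference), female, pain (continuous), right side."""
    d = categorize_covariates(df) if "age_band" not in df else df
    x = pd.DataFrame(index=d.index)
    x["intercept"] = 1.0
    for band in AGE_BANDS[1:]:
        x[f"age_{band}"] = (d["age_band"] == band).astype(float)
    x["female"] = (d["gender"] == "female").astype(float)
    for cat in WEIGHT_CATEGORIES[1:]:
        x[f"weight_{cat}"] = (d["weight_category"] == cat).astype(float)
    x["pain"] = d["nrs_pain"].astype(float)
    x["side_right"] = (d["side"] == "right").astype(float)
    return x


def _newton_logistic(x, y, tol, max_iter):
    """Maximum-likelihood logistic fit by Newton-Raphson with step halving."""
    n, k = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        _, r = np.linalg.qr(x)
        small = np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max()
        raise ValueError(f"singular design; collinear columns at positions {np.where(small)[0].tolist()}")
    beta = np.zeros(k)
    ll = -n * np.log(2.0)
    for _ in range(max_iter):
        eta = x @ beta
        p = expit(eta)
        g = x.T @ (y - p)
        if np.max(np.abs(g)) < tol:
            if np.all(np.abs(y - p) < 1e-4):
                # the score vanishes only because every fitted probability
                # has been pushed onto its label
                raise SeparationError(
                    "complete separation: fitted probabilities equal the labels"
                )
            return beta, ll, True
        w = p * (1.0 - p)
        h = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            raise SeparationError("information matrix singular; separation likely")
        # step halving to guarantee the log-likelihood does not decrease
        for _ in range(30):
            cand = beta + step
            ll_new = float(np.sum(y * (x @ cand)) - np.sum(np.logaddexp(0.0, x @ cand)))
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll = cand, ll_new
        if np.max(np.abs(beta)) > 30.0:
            raise SeparationError(
                "diverging coefficients (|beta| > 30): complete separation suspected"
            )
    return beta, ll, False


class PropensityModel:
    """Logistic regression of case status on the matching covariates.

    Parameters
    ----------
    endog : array-like of {0, 1}
        1 for case knees, 0 for eligible control knees.
    exog : DataFrame
        Design matrix, typically from :func:`build_design`.
    """

    def __init__(self, endog, exog: pd.DataFrame):
        self.exog = exog.astype(float)
        self.endog = np.asarray(endog, dtype=float).ravel()
        if self.endog.shape[0] != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        if np.any(self.exog.isna()) or np.any(~np.isfinite(self.endog)):
            raise ValueError("missing values in the propensity design or outcome")

    @classmethod
    def from_arms(cls, cases: pd.DataFrame, controls: pd.DataFrame) -> "PropensityModel":
        """Build the model from the selected case and eligible-control tables."""
        pooled = pd.concat([cases, controls], ignore_index=True)
        y = np.r_[np.ones(len(cases)), np.zeros(len(controls))]
        return cls(y, build_design(pooled))

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> "PropensityResults":
        x = self.exog.to_numpy()
        beta, llf, converged = _newton_logistic(x, self.endog, tol, max_iter)
        if not converged:
            raise ConvergenceError(f"no convergence in {max_iter} Newton iterations")
        p = expit(x @ beta)
        w = p * (1.0 - p)
        cov = np.linalg.inv((x * w[:, None]).T @ x)
        return PropensityResults(
            params=pd.Series(beta, index=self.exog.columns),
            cov_params=pd.DataFrame(cov, index=self.exog.columns, columns=self.exog.columns),
            llf=llf,
            nobs=len(self.endog),
            fittedvalues=pd.Series(p, index=self.exog.index),
            model=self,
        )


@dataclass
class PropensityResults:
    params: pd.Series
    cov_params: pd.DataFrame
    llf: float
    nobs: int
    fittedvalues: pd.Series
    model: PropensityModel

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Propensity scores for new records (raw cohort columns accepted)."""
        if not set(self.params.index) <= set(df.columns):
            df = build_design(df)
        return expit(df[self.params.index].to_numpy() @ self.params.to_numpy())

    def summary(self) -> str:
        tab = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "z": self.zvalues, "p": self.pvalues}
        )
        return (
            f"Propensity (stratification) score model - logistic regression\n"
            f"n = {self.nobs}, log-likelihood = {self.llf:.3f}\n"
            + tab.to_string(float_format=lambda v: f"{v: .4f}")
        )


@dataclass
class MatchReport:
    n_pairs: int
    n_exact: int
    exact_pct: float
    max_abs_diff: float
    n_contralateral: int = 0


def match(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    ps_cases: np.ndarray,
    ps_controls: np.ndarray,
    exact_gender: bool = False,
) -> tuple[pd.DataFrame, MatchReport]:
    """Greedy 1:1 nearest-neighbour matching on the propensity score,
    without replacement.

    Cases are processed in descending propensity order (ties broken by
    knee id); each takes the unused control with the smallest absolute
    score difference (ties again by knee id).  A pair counts as *exact*
    when the two scores agree at two decimals.

    Raises if the control pool is smaller than the case list, reporting
    the shortfall.
    """
    ps_c = np.asarray(ps_cases, dtype=float)
    ps_k = np.asarray(ps_controls, dtype=float)
    if len(ps_c) != len(cases) or len(ps_k) != len(controls):
        raise ValueError("score vectors must align with the case/control tables")
    if len(controls) < len(cases):
        raise ValueError(
            f"control pool exhausted: {len(cases)} cases but only "
            f"{len(controls)} controls (shortfall {len(cases) - len(controls)})"
        )
    case_ids = cases["knee_id"].to_numpy()
    ctrl_ids = controls["knee_id"].to_numpy()
    order = np.lexsort((case_ids, -ps_c))
    used = np.zeros(len(ps_k), dtype=bool)
    ctrl_gender = controls["gender"].to_numpy() if exact_gender else None
    case_gender = cases["gender"].to_numpy() if exact_gender else None

    rows = []
    for i in order:
        avail = ~used
        if exact_gender:
            avail &= ctrl_gender == case_gender[i]
            if not avail.any():
                raise ValueError(
                    f"no unused control of matching gender for case {case_ids[i]}"
                )
        diffs = np.abs(ps_k - ps_c[i])
        diffs = np.where(avail, diffs, np.inf)
        best = diffs.min()
        # float-tolerant tie detection so e.g. |0.9-0.8| and |0.7-0.8| tie
        cand = np.flatnonzero(diffs <= best + 1e-12)
        j = cand[np.argsort(ctrl_ids[cand])[0]] if len(cand) > 1 else cand[0]
        used[j] = True
        rows.append(
            {
                "case_id": case_ids[i],
                "control_id": ctrl_ids[j],
                "case_index": int(cases.index[i]),
                "control_index": int(controls.index[j]),
                "ps_case": ps_c[i],
                "ps_control": ps_k[j],
                "abs_diff": float(best),
                "exact": bool(round(ps_c[i], 2) == round(ps_k[j], 2)),
            }
        )
    pairs = pd.DataFrame(rows)
    if pairs["control_id"].duplicated().any():
        raise AssertionError("matching reused a control")
    case_part = cases.set_index("knee_id")["participant_id"]
    ctrl_part = controls.set_index("knee_id")["participant_id"]
    n_contra = int(
        (case_part.loc[pairs["case_id"]].to_numpy()
         == ctrl_part.loc[pairs["control_id"]].to_numpy()).sum()
    )
    report = MatchReport(
        n_pairs=len(pairs),
        n_exact=int(pairs["exact"].sum()),
        exact_pct=round(100.0 * pairs["exact"].mean(), 0),
        max_abs_diff=float(pairs["abs_diff"].max()),
        n_contralateral=n_contra,
    )
    return pairs, report


def standardized_difference_continuous(x_case, x_ctrl) -> float:
    """Mean difference as a percentage of the average standard deviation."""
    x_case = np.asarray(x_case, dtype=float)
    x_ctrl = np.asarray(x_ctrl, dtype=float)
    pooled = np.sqrt((np.var(x_case, ddof=1) + np.var(x_ctrl, ddof=1)) / 2.0)
    if pooled == 0.0:
        return np.nan
    return float(100.0 * (x_case.mean() - x_ctrl.mean()) / pooled)


def standardized_difference_binary(b_case, b_ctrl) -> float:
    """Prevalence difference scaled by the within-group binomial SD."""
    p1 = float(np.mean(np.asarray(b_case, dtype=float)))
    p0 = float(np.mean(np.asarray(b_ctrl, dtype=float)))
    denom = np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2.0)
    if denom == 0.0:
        return 0.0 if p1 == p0 else np.nan
    return float((p1 - p0) / denom)


def balance(
    matched_cases: pd.DataFrame,
    matched_controls: pd.DataFrame,
    continuous: tuple = ("age", "bmi", "nrs_pain"),
    dichotomous: tuple = (("gender", "female"), ("side", "right")),
) -> pd.DataFrame:
    """Standardized-difference balance diagnostics on the matched sample.

    Continuous covariates are compared on their raw scale (not the
    categorized matching variables).  Flags use the 10% / 0.1 thresholds.
    """
    if len(matched_cases) < 2 or len(matched_cases) != len(matched_controls):
        raise ValueError("need >= 2 matched pairs with aligned arms")
    rows = []
    for cov in continuous:
        d = standardized_difference_continuous(matched_cases[cov], matched_controls[cov])
        rows.append(
            {"covariate": cov, "type": "continuous", "std_diff": d,
             "balanced": bool(np.abs(d) < 10.0) if np.isfinite(d) else None}
        )
    for cov, level in dichotomous:
        d = standardized_difference_binary(
            matched_cases[cov] == level, matched_controls[cov] == level
        )
        rows.append(
            {"covariate": f"{cov}={level}", "type": "dichotomous", "std_diff": d,
             "balanced": bool(np.abs(d) < 0.1) if np.isfinite(d) else None}
        )
    return pd.DataFrame(rows)
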