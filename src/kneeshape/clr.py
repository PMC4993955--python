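"""Matched-pair inference: paired t-tests, conditional logistic regression,
AIC model comparison, tertile and stratified analyses.

For 1:1 matched sets the conditional likelihood eliminates the per-pair
nuisance intercepts and depends only on within-pair covariate differences::

    L(beta) = prod_pairs exp(x_case . beta) / (exp(x_case . beta) + exp(x_control . beta))

which is algebraically an intercept-free logistic likelihood on the
differences ``x_case - x_control`` with all outcomes equal to one.  Pairs
whose members share identical covariates contribute the constant 1/2; they
carry no information about ``beta`` but are retained in the likelihood so
that AIC values of models fitted on the same pair set stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm, t as t_dist

__all__ = [
    "PairedTResult",
    "paired_t",
    "ConditionalLogit",
    "ConditionalLogitResults",
    "CLRConvergenceError",
    "compare_aic",
    "TertileAssignment",
    "assign_tertiles",
    "tertile_dummies",
    "kl_dummies",
    "stratified_clr",
]


class CLRConvergenceError(RuntimeError):
    """Conditional likelihood diverged (e.g. monotone likelihood)."""


# ---------------------------------------------------------------------------
# paired t-test
# ---------------------------------------------------------------------------


@dataclass
class PairedTResult:
    mean_diff: float
    ci95: tuple
    t: float
    df: int
    p: float
    mean_case: float
    mean_control: float
    sd_case: float
    sd_control: float
    degenerate: bool = False


def paired_t(case_values, control_values) -> PairedTResult:
    """Student's paired t-test of case minus control differences.

    Returns the mean difference with its symmetric 95% CI, the t statistic
    on n-1 degrees of freedom and the two-sided p-value.  A zero difference
    standard deviation yields a degenerate result (t undefined, flagged).
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired lists must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    d = x - y
    n = d.size
    mean = float(d.mean())
    sd = float(np.std(d, ddof=1))
    base = dict(
        mean_diff=mean,
        mean_case=float(x.mean()),
        mean_control=float(y.mean()),
        sd_case=float(np.std(x, ddof=1)),
        sd_control=float(np.std(y, ddof=1)),
        df=n - 1,
    )
    if sd == 0.0:
        return PairedTResult(ci95=(mean, mean), t=np.nan, p=np.nan, degenerate=True, **base)
    se = sd / np.sqrt(n)
    tcrit = float(t_dist.ppf(0.975, n - 1))
    tval = mean / se
    return PairedTResult(
        ci95=(mean - tcrit * se, mean + tcrit * se),
        t=float(tval),
        p=float(2.0 * t_dist.sf(abs(tval), n - 1)),
        **base,
    )


# ---------------------------------------------------------------------------
# conditional logistic regression (1:1 matched sets)
# ---------------------------------------------------------------------------


class ConditionalLogit:
    """Conditional logistic regression for 1:1 matched case-control pairs.

    Parameters
    ----------
    x_case, x_control : (n_pairs, k) arrays
        Covariate rows for the case and control member of each pair.
    names : sequence of str, optional
        Covariate names.
    """

    def __init__(self, x_case, x_control, names=None):
        xc = np.atleast_2d(np.asarray(x_case, dtype=float))
        xk = np.atleast_2d(np.asarray(x_control, dtype=float))
        if xc.ndim != 2 or xc.shape != xk.shape:
            raise ValueError("x_case and x_control must be equal-shape (n, k) arrays")
        if not (np.all(np.isfinite(xc)) and np.all(np.isfinite(xk))):
            raise ValueError(
                "missing/non-finite covariates; drop incomplete pairs before fitting"
            )
        self.d = xc - xk
        self.k = xc.shape[1]
        self.n_pairs = xc.shape[0]
        self.names = list(names) if names is not None else [f"x{i}" for i in range(self.k)]
        if len(self.names) != self.k:
            raise ValueError("names length mismatch")
        self._informative = np.any(self.d != 0.0, axis=1)

    @classmethod
    def from_pairs(
        cls, case_df: pd.DataFrame, control_df: pd.DataFrame, covariates
    ) -> "ConditionalLogit":
        """Build from aligned case/control DataFrames; pairs with a missing
        covariate in either member are dropped (count kept on the model)."""
        covariates = list(covariates)
        xc = case_df[covariates].to_numpy(dtype=float)
        xk = control_df[covariates].to_numpy(dtype=float)
        ok = np.all(np.isfinite(xc), axis=1) & np.all(np.isfinite(xk), axis=1)
        model = cls(xc[ok], xk[ok], names=covariates)
        model.n_dropped_missing = int((~ok).sum())
        model.complete_mask = ok
        return model

    def loglike(self, beta) -> float:
        return float(-np.sum(np.logaddexp(0.0, -self.d @ np.asarray(beta, float))))

    def fit(self, tol: float = 1e-8, maxiter: int = 50) -> "ConditionalLogitResults":
        """Newton-Raphson maximization of the conditional likelihood.

        Starts at beta = 0 and stops when the max absolute score falls
        below ``tol``.  Monotone likelihoods (all informative pairs
        concordant in sign for a single covariate, or diverging estimates)
        raise :class:`CLRConvergenceError` rather than returning a silent,
        arbitrarily large estimate.
        """
        n_info = int(self._informative.sum())
        if n_info == 0:
            raise ValueError("no informative pairs: every pair has x_case == x_control")
        zero_cols = np.flatnonzero(np.all(self.d == 0.0, axis=0))
        if len(zero_cols):
            bad = [self.names[i] for i in zero_cols]
            raise ValueError(
                f"covariates with no within-pair variation: {bad}; remove them"
            )
        if self.k == 1:
            dz = self.d[self._informative, 0]
            if np.all(dz > 0) or np.all(dz < 0):
                raise CLRConvergenceError(
                    "monotone likelihood: all informative pairs concordant in sign"
                )
        d = self.d
        beta = np.zeros(self.k)
        ll = self.loglike(beta)
        converged = False
        for _ in range(maxiter):
            p = expit(d @ beta)
            g = d.T @ (1.0 - p)
            if np.max(np.abs(g)) < tol:
                converged = True
                break
            w = p * (1.0 - p)
            h = (d * w[:, None]).T @ d
            try:
                step = np.linalg.solve(h, g)
            except np.linalg.LinAlgError:
                raise CLRConvergenceError("singular information matrix")
            for _ in range(30):
                cand = beta + step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                step /= 2.0
            beta, ll = cand, ll_new
            if np.max(np.abs(beta)) > 50.0:
                raise CLRConvergenceError(
                    "diverging estimate (|beta| > 50): monotone likelihood suspected"
                )
        if not converged:
            raise CLRConvergenceError(f"no convergence in {maxiter} iterations")
        if np.max(np.abs(beta)) > 15.0:
            # the score can vanish while beta drifts to infinity
            # (quasi-complete separation); refuse the silent huge estimate
            raise CLRConvergenceError(
                "estimate diverged (|beta| > 15): quasi-complete separation / "
                "monotone likelihood"
            )
        p = expit(d @ beta)
        w = p * (1.0 - p)
        h = (d * w[:, None]).T @ d
        cov = np.linalg.inv(h)
        return ConditionalLogitResults(
            params=pd.Series(beta, index=self.names),
            cov_params=pd.DataFrame(cov, index=self.names, columns=self.names),
            llf=ll,
            n_pairs=self.n_pairs,
            n_informative=n_info,
            n_dropped_missing=getattr(self, "n_dropped_missing", 0),
            model=self,
        )


@dataclass
class ConditionalLogitResults:
    """Fitted conditional logistic model for 1:1 matched pairs."""

    params: pd.Series
    cov_params: pd.DataFrame
    llf: float
    n_pairs: int
    n_informative: int
    n_dropped_missing: int
    model: ConditionalLogit

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.llf

    @property
    def llnull(self) -> float:
        return self.n_pairs * np.log(0.5)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {"low": self.params - z * self.bse, "high": self.params + z * self.bse}
        )

    def odds_ratios(self) -> pd.DataFrame:
        """OR = exp(beta) with Wald 95% CI and two-sided p-values."""
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "ci_low": np.exp(ci["low"]),
                "ci_high": np.exp(ci["high"]),
                "p": self.pvalues,
            }
        )

    def lr_test(self) -> tuple[float, float]:
        """Likelihood-ratio test against the null model (beta = 0)."""
        stat = 2.0 * (self.llf - self.llnull)
        return float(stat), float(chi2.sf(stat, self.k))

    def pair_influence(self) -> np.ndarray:
        """Per-pair influence: score contribution norm (simple diagnostic)."""
        d = self.model.d
        p = expit(d @ self.params.to_numpy())
        return np.linalg.norm(d * (1.0 - p)[:, None], axis=1)

    def summary(self) -> str:
        tab = self.odds_ratios()
        tab.insert(0, "coef", self.params)
        tab.insert(1, "se", self.bse)
        lr, lr_p = self.lr_test()
        return (
            "Conditional logistic regression (1:1 matched pairs)\n"
            f"pairs = {self.n_pairs} ({self.n_informative} informative, "
            f"{self.n_dropped_missing} dropped for missing covariates)\n"
            f"log-likelihood = {self.llf:.4f}, AIC = {self.aic:.2f}, "
            f"LR chi2({self.k}) = {lr:.2f} (p = {lr_p:.2g})\n"
            + tab.to_string(float_format=lambda v: f"{v: .4f}")
        )


def compare_aic(fits: dict) -> pd.DataFrame:
    """Rank fitted models by AIC (ascending).

    Refuses to rank models fitted on different pair sets: AIC values are
    only comparable on a common sample, and KL-adjusted models silently
    dropping missing-KL pairs is exactly the pitfall this guards against.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ns = {name: f.n_pairs for name, f in fits.items()}
    if len(set(ns.values())) > 1:
        raise ValueError(f"fits use different pair sets, refusing to rank: {ns}")
    rows = [
        {"model": name, "k": f.k, "loglik": f.llf, "aic": f.aic}
        for name, f in fits.items()
    ]
    return (
        pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# tertiles
# ---------------------------------------------------------------------------


@dataclass
class TertileAssignment:
    cut_points: tuple
    labels: np.ndarray  # 'lowest' | 'middle' | 'highest'


def assign_tertiles(scores) -> TertileAssignment:
    """Split scores at the empirical 1/3 and 2/3 quantiles of the pooled
    sample.  The highest tertile contains values closest to the mean OA
    shape.  Intervals are lower-open/upper-closed (lowest closed below);
    values exactly on a cut point go to the lower tertile.
    """
    x = np.asarray(scores, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct score values for tertiles")
    q33, q67 = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(x <= q33, "lowest", np.where(x <= q67, "middle", "highest"))
    return TertileAssignment(cut_points=(float(q33), float(q67)), labels=labels)


def tertile_dummies(labels) -> np.ndarray:
    """(n, 2) dummies for middle and highest tertile (lowest = reference)."""
    labels = np.asarray(labels)
    return np.column_stack([(labels == "middle"), (labels == "highest")]).astype(float)


def kl_dummies(kl) -> np.ndarray:
    """(n, 4) KL grade dummies for grades 1-4 with KL 0 as reference."""
    kl = np.asarray(kl, dtype=float)
    if np.any(np.isnan(kl)):
        raise ValueError("missing KL grades; restrict to complete-case pairs first")
    return np.column_stack([(kl == g) for g in (1, 2, 3, 4)]).astype(float)


# ---------------------------------------------------------------------------
# stratified analyses
# ---------------------------------------------------------------------------


def stratified_clr(
    x_case,
    x_control,
    strata,
    names=None,
    min_informative: int = 10,
):
    """Fit the conditional logistic model separately within case-defined
    strata (e.g. case KL grade, or time-to-TKR band).

    Returns ``(fits, log)``: a dict of stratum -> results with a
    ``wide_ci`` flag for strata below ``min_informative`` informative
    pairs, and a log of skipped strata.
    """
    x_case = np.atleast_2d(np.asarray(x_case, dtype=float))
    x_control = np.atleast_2d(np.asarray(x_control, dtype=float))
    strata = np.asarray(strata)
    if len(strata) != x_case.shape[0]:
        raise ValueError("one stratum label per pair required")
    fits, log = {}, []
    for s in pd.unique(strata):
        mask = strata == s
        if not mask.any():
            log.append((s, "empty stratum, skipped"))
            continue
        try:
            res = ConditionalLogit(x_case[mask], x_control[mask], names=names).fit()
        except (ValueError, CLRConvergenceError) as exc:
            log.append((s, f"skipped: {exc}"))
            continue
        fits[s] = {"fit": res, "wide_ci": res.n_informative < min_informative}
    return fits, log
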