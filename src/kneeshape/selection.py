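"""Case-definition and control-knee-selection rules for the nested design.

Cases are knees with a confirmed replacement for an osteoarthritis
indication; where a participant had both knees replaced the first-replaced
knee is included, and exact ties (same-day surgery) are broken by a seeded
random draw.  Surviving knees are eligible controls; when a participant has
two, the knee with the higher pain score is taken, right side on ties.

Every input knee ends up in exactly one of: the case list, the eligible
control list, or the exclusion log (one reason per knee).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SelectionResult", "select_case_control", "select_control_knee"]

#: Baseline fields that must be recorded for a knee to enter either arm.
REQUIRED_BASELINE = ("age", "gender", "nrs_pain", "bmi")


@dataclass
class SelectionResult:
    cases: pd.DataFrame
    eligible_controls: pd.DataFrame
    exclusions: pd.DataFrame  # columns: knee_id, reason

    def counts(self) -> dict:
        return {
            "cases": len(self.cases),
            "eligible_controls": len(self.eligible_controls),
            "excluded": len(self.exclusions),
        }


def select_control_knee(knees: pd.DataFrame) -> pd.Series:
    """Pick one control knee for a participant: highest pain, right on ties."""
    if len(knees) == 0:
        raise ValueError("no eligible knee")
    order = knees.sort_values(
        ["nrs_pain", "side"], ascending=[False, True], kind="mergesort"
    )
    # side sorts 'left' < 'right'; stable sort then prefer right on pain ties
    top_pain = order["nrs_pain"].iloc[0]
    tied = order[order["nrs_pain"] == top_pain]
    right = tied[tied["side"] == "right"]
    return (right.iloc[0] if len(right) else tied.iloc[0])


def _missing_baseline(df: pd.DataFrame) -> pd.Series:
    miss = pd.Series(False, index=df.index)
    for col in REQUIRED_BASELINE:
        miss |= df[col].isna()
    return miss


def select_case_control(cohort: pd.DataFrame, rng_seed: int = 0) -> SelectionResult:
    """Apply eligibility, case-definition and control-knee-selection rules.

    Parameters
    ----------
    cohort : DataFrame
        One row per knee; requires columns ``participant_id, knee_id, side,
        tkr, tkr_interval_years, nrs_pain, kl_grade`` plus the baseline
        fields; optional ``has_shape`` and ``indication`` columns.
    rng_seed : int
        Seed for the random choice between knees replaced on the same day.
    """
    df = cohort.reset_index(drop=True)
    rng = np.random.default_rng(rng_seed)
    excl: list[tuple[str, str]] = []

    has_shape = df["has_shape"] if "has_shape" in df else pd.Series(True, index=df.index)
    indication = df["indication"] if "indication" in df else pd.Series(None, index=df.index, dtype=object)

    # ---- cases ----------------------------------------------------------
    tkr = df[df["tkr"].astype(bool)].copy()
    tkr["_rand"] = rng.random(len(tkr))
    tkr = tkr.sort_values(
        ["participant_id", "tkr_interval_years", "_rand"], kind="mergesort"
    )
    first = tkr.groupby("participant_id", sort=False).head(1)
    later = tkr.loc[tkr.index.difference(first.index)]
    min_interval = tkr.groupby("participant_id")["tkr_interval_years"].transform("min")
    for idx, row in later.iterrows():
        if row["tkr_interval_years"] == min_interval.loc[idx]:
            excl.append((row["knee_id"], "same_day_not_selected"))
        else:
            excl.append((row["knee_id"], "later_replacement"))

    case_rows = []
    for idx, row in first.iterrows():
        kid = row["knee_id"]
        if _missing_baseline(first.loc[[idx]]).iloc[0]:
            excl.append((kid, "missing_baseline"))
            continue
        if not bool(has_shape.loc[idx]):
            excl.append((kid, "missing_shape"))
            continue
        ind = indication.loc[idx]
        if pd.notna(ind) and ind is not None:
            if str(ind) != "OA":
                excl.append((kid, "non_oa_indication"))
                continue
        else:
            # indication unrecorded: accept when an OA indication is highly
            # likely, i.e. baseline radiographic (KL >= 2) plus symptomatic
            # (pain NRS >= 1) evidence of OA
            kl = row["kl_grade"]
            if pd.isna(kl) or kl < 2 or row["nrs_pain"] < 1:
                excl.append((kid, "oa_indication_not_confirmed"))
                continue
        case_rows.append(idx)
    cases = df.loc[case_rows].drop(columns=[], errors="ignore")

    # ---- controls -------------------------------------------------------
    surv = df[~df["tkr"].astype(bool)].copy()
    miss = _missing_baseline(surv)
    for kid in surv.loc[miss, "knee_id"]:
        excl.append((kid, "missing_baseline"))
    surv = surv[~miss]
    noshape = ~has_shape.loc[surv.index].astype(bool)
    for kid in surv.loc[noshape, "knee_id"]:
        excl.append((kid, "missing_shape"))
    surv = surv[~noshape]

    surv = surv.copy()
    surv["_right"] = (surv["side"] == "right").astype(int)
    surv = surv.sort_values(
        ["participant_id", "nrs_pain", "_right"],
        ascending=[True, False, False],
        kind="mergesort",
    )
    chosen = surv.groupby("participant_id", sort=False).head(1)
    not_chosen = surv.loc[surv.index.difference(chosen.index)]
    for kid in not_chosen["knee_id"]:
        excl.append((kid, "contralateral_not_selected"))
    controls = df.loc[chosen.index.sort_values()]

    exclusions = pd.DataFrame(excl, columns=["knee_id", "reason"])
    # every knee appears exactly once across the three outputs
    n_total = len(cases) + len(controls) + len(exclusions)
    if n_total != len(df) or exclusions["knee_id"].duplicated().any():
        raise AssertionError("selection bookkeeping error: knees lost or duplicated")
    return SelectionResult(
        cases=cases.reset_index(drop=True),
        eligible_controls=controls.reset_index(drop=True),
        exclusions=exclusions,
    )
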