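"""End-to-end orchestration: generate -> train -> score -> select -> match ->
analyze, as one reproducible run under a single seed.

Stage seeds are derived deterministically from the run seed so stages can be
re-run in isolation from their intermediates.  All tabular intermediates are
plain CSV; fitted shape models are saved as ``.npz`` archives.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import io
from .reliability import smallest_detectable_difference
from .clr import (
    CLRConvergenceError,
    ConditionalLogit,
    assign_tertiles,
    compare_aic,
    kl_dummies,
    paired_t,
    stratified_clr,
    tertile_dummies,
)
from .datatypes import BONES
from .propensity import PropensityModel, balance, match
from .selection import select_case_control
from .shape import ShapeVectorModel
from .simulate import (
    SimConfig,
    generate_cohort,
    generate_shape_stack,
    generate_test_retest,
    generate_training_set,
    outcome_prevalence,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "STAGES"]

STAGES = ("cohort", "train", "select", "match", "score", "analyze", "report")


def stage_seed(seed: int, stage: str, extra: int = 0) -> int:
    """Deterministic child seed per stage, kept below 2**31."""
    return (seed * 1000003 + STAGES.index(stage) * 101 + extra) % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    sim: SimConfig = None
    var_frac: float = 0.98
    exact_gender: bool = False
    bones: tuple = BONES
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        else:
            self.sim.seed = self.seed
        self.bones = tuple(self.bones)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def _clr_dict(res) -> dict:
    ors = res.odds_ratios()
    return {
        "params": res.params.to_dict(),
        "se": res.bse.to_dict(),
        "or": ors["OR"].to_dict(),
        "or_ci_low": ors["ci_low"].to_dict(),
        "or_ci_high": ors["ci_high"].to_dict(),
        "p": ors["p"].to_dict(),
        "loglik": res.llf,
        "aic": res.aic,
        "k": res.k,
        "n_pairs": res.n_pairs,
        "n_informative": res.n_informative,
        "n_dropped_missing": res.n_dropped_missing,
    }


def _fit_or_note(x_case, x_control, names):
    try:
        return ConditionalLogit(x_case, x_control, names=names).fit(), None
    except (ValueError, CLRConvergenceError) as exc:
        return None, str(exc)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and optionally write) the report bundle."""
    timings: dict[str, float] = {}
    report: dict = {"config": {"seed": config.seed, "var_frac": config.var_frac,
                               "exact_gender": config.exact_gender,
                               "bones": list(config.bones),
                               "sim": asdict(config.sim)}}

    # ---- cohort ---------------------------------------------------------
    t0 = time.perf_counter()
    cohort, truth = generate_cohort(config.sim)
    timings["cohort"] = time.perf_counter() - t0
    report["cohort"] = {
        "n_participants": config.sim.n_participants,
        "n_knees": len(cohort),
        "tkr_prevalence_pct": outcome_prevalence(cohort, decimals=1),
    }

    # ---- shape models ---------------------------------------------------
    t0 = time.perf_counter()
    models = {}
    for bone in config.bones:
        training = generate_training_set(config.sim, bone)
        models[bone] = ShapeVectorModel(training).fit(var_frac=config.var_frac)
    timings["train"] = time.perf_counter() - t0
    # test-retest reliability of the score: 35 knees scanned twice
    report["reliability"] = {}
    for bone in config.bones:
        test, retest = generate_test_retest(35, config.sim, bone)
        bt = models[bone].score_stack(np.stack([s.points for s in test]))
        br = models[bone].score_stack(np.stack([s.points for s in retest]))
        report["reliability"][bone] = {
            "sdd": smallest_detectable_difference(bt, br), "n": 35,
        }
    report["shape_models"] = {
        bone: {
            "n_components": int(m.components.shape[0]),
            "explained_var_ratio": m.explained_var_ratio,
            "n_train_oa": m.n_train_oa,
            "n_train_non_oa": m.n_train_non_oa,
        }
        for bone, m in models.items()
    }

    # ---- selection ------------------------------------------------------
    t0 = time.perf_counter()
    sel = select_case_control(cohort, rng_seed=stage_seed(config.seed, "select"))
    timings["select"] = time.perf_counter() - t0
    report["selection"] = sel.counts()

    # ---- propensity + matching -----------------------------------------
    t0 = time.perf_counter()
    ps_model = PropensityModel.from_arms(sel.cases, sel.eligible_controls)
    ps_res = ps_model.fit()
    ps_cases = ps_res.predict(sel.cases)
    ps_controls = ps_res.predict(sel.eligible_controls)
    pairs, match_report = match(
        sel.cases, sel.eligible_controls, ps_cases, ps_controls,
        exact_gender=config.exact_gender,
    )
    m_cases = sel.cases.loc[pairs["case_index"]].reset_index(drop=True)
    m_controls = sel.eligible_controls.loc[pairs["control_index"]].reset_index(drop=True)
    bal = balance(m_cases, m_controls)
    timings["match"] = time.perf_counter() - t0
    report["propensity"] = {
        "params": ps_res.params.to_dict(),
        "loglik": ps_res.llf,
        "n": ps_res.nobs,
    }
    report["matching"] = {
        "n_pairs": match_report.n_pairs,
        "n_exact": match_report.n_exact,
        "exact_pct": match_report.exact_pct,
        "max_abs_ps_diff": match_report.max_abs_diff,
        "n_contralateral": match_report.n_contralateral,
    }
    report["balance"] = bal.to_dict(orient="records")

    # ---- scoring matched knees -----------------------------------------
    t0 = time.perf_counter()
    scores_case: dict[str, np.ndarray] = {}
    scores_control: dict[str, np.ndarray] = {}
    for bi, bone in enumerate(config.bones):
        rng = np.random.default_rng((stage_seed(config.seed, "score"), bi))
        stack_case = generate_shape_stack(
            m_cases["severity"].to_numpy(), bone, config.sim, rng
        )
        stack_ctrl = generate_shape_stack(
            m_controls["severity"].to_numpy(), bone, config.sim, rng
        )
        scores_case[bone] = models[bone].score_stack(stack_case)
        scores_control[bone] = models[bone].score_stack(stack_ctrl)
    bone0 = config.bones[0]
    pooled_b = np.r_[scores_case[bone0], scores_control[bone0]]
    pooled_sev = np.r_[m_cases["severity"], m_controls["severity"]]
    report["score_validation"] = {
        "bone": bone0,
        "spearman_vs_latent_severity": float(
            spearmanr(pooled_b, pooled_sev).statistic
        ),
        "n": int(pooled_b.size),
    }
    timings["score"] = time.perf_counter() - t0

    # ---- analysis -------------------------------------------------------
    t0 = time.perf_counter()
    analysis: dict = {}

    # Paired t-tests on the bone shape vectors (case minus control)
    analysis["paired_t"] = {}
    for bone in config.bones:
        r = paired_t(scores_case[bone], scores_control[bone])
        analysis["paired_t"][bone] = {
            "mean_case": r.mean_case, "sd_case": r.sd_case,
            "mean_control": r.mean_control, "sd_control": r.sd_control,
            "mean_diff": r.mean_diff, "ci95": list(r.ci95),
            "t": r.t, "df": r.df, "p": r.p,
        }

    # Univariable conditional logistic models, all pairs
    analysis["univariable"] = {}
    univ_fits = {}
    for bone in config.bones:
        fit, note = _fit_or_note(
            scores_case[bone][:, None], scores_control[bone][:, None], [f"{bone}_vector"]
        )
        if fit is None:
            analysis["univariable"][bone] = {"error": note}
        else:
            analysis["univariable"][bone] = _clr_dict(fit)
            univ_fits[bone] = fit
    if len(univ_fits) > 1:
        analysis["univariable_aic"] = compare_aic(
            {f"{b} vector": f for b, f in univ_fits.items()}
        ).to_dict(orient="records")

    # Complete-case pair set (KL known for both members) for KL-adjusted
    # models; AIC comparison is restricted to this common sample.
    kl_case = m_cases["kl_grade"].to_numpy(dtype=float)
    kl_ctrl = m_controls["kl_grade"].to_numpy(dtype=float)
    cc = np.isfinite(kl_case) & np.isfinite(kl_ctrl)
    analysis["n_pairs_complete_kl"] = int(cc.sum())
    kd_case = kl_dummies(kl_case[cc])
    kd_ctrl = kl_dummies(kl_ctrl[cc])
    kl_names = [f"kl{g}" for g in (1, 2, 3, 4)]

    cc_fits = {}
    fit, note = _fit_or_note(kd_case, kd_ctrl, kl_names)
    analysis["kl_only"] = _clr_dict(fit) if fit else {"error": note}
    if fit:
        cc_fits["KL grade"] = fit

    analysis["adjusted"] = {}
    analysis["univariable_cc"] = {}
    for bone in config.bones:
        xc = np.column_stack([scores_case[bone][cc, None], kd_case])
        xk = np.column_stack([scores_control[bone][cc, None], kd_ctrl])
        fit, note = _fit_or_note(xc, xk, [f"{bone}_vector"] + kl_names)
        analysis["adjusted"][bone] = _clr_dict(fit) if fit else {"error": note}
        if fit:
            cc_fits[f"{bone} vector + KL"] = fit
        # univariable on the same complete-case sample, for the AIC table
        fit_u, _ = _fit_or_note(
            scores_case[bone][cc, None], scores_control[bone][cc, None],
            [f"{bone}_vector"],
        )
        if fit_u:
            cc_fits[f"{bone} vector"] = fit_u
            analysis["univariable_cc"][bone] = _clr_dict(fit_u)

    xc = np.column_stack([np.column_stack([scores_case[b][cc] for b in config.bones]), kd_case])
    xk = np.column_stack([np.column_stack([scores_control[b][cc] for b in config.bones]), kd_ctrl])
    fit, note = _fit_or_note(xc, xk, [f"{b}_vector" for b in config.bones] + kl_names)
    analysis["combined"] = _clr_dict(fit) if fit else {"error": note}
    if fit:
        cc_fits["all vectors + KL"] = fit
    if cc_fits:
        analysis["aic_table"] = compare_aic(cc_fits).to_dict(orient="records")

    # Tertile analyses: cut points from the pooled matched baseline scores
    analysis["tertiles"] = {}
    for bone in config.bones:
        pooled = np.r_[scores_case[bone], scores_control[bone]]
        tert = assign_tertiles(pooled)
        lab_case = tert.labels[: len(scores_case[bone])]
        lab_ctrl = tert.labels[len(scores_case[bone]):]
        entry = {"cut_points": list(tert.cut_points)}
        fit, note = _fit_or_note(
            tertile_dummies(lab_case), tertile_dummies(lab_ctrl),
            ["middle_tertile", "highest_tertile"],
        )
        entry["unadjusted"] = _clr_dict(fit) if fit else {"error": note}
        fit, note = _fit_or_note(
            np.column_stack([tertile_dummies(lab_case)[cc], kd_case]),
            np.column_stack([tertile_dummies(lab_ctrl)[cc], kd_ctrl]),
            ["middle_tertile", "highest_tertile"] + kl_names,
        )
        entry["adjusted"] = _clr_dict(fit) if fit else {"error": note}
        analysis["tertiles"][bone] = entry

    # Exploratory stratified models (femur vector), case-knee strata
    strat: dict = {}
    kl_int = np.where(np.isnan(kl_case), 0, kl_case).astype(int)
    kl_band = np.where(
        np.isnan(kl_case), "missing",
        np.where(kl_case <= 1, "KL 0-1", np.char.add("KL ", kl_int.astype(str))),
    )
    interval = m_cases["tkr_interval_years"].to_numpy(dtype=float)
    time_band = np.where(interval < 2, "0-2y", np.where(interval < 4, "2-4y", "4-7y"))
    bone0 = config.bones[0]
    for name, labels in (("case_kl_grade", kl_band), ("time_to_tkr_band", time_band)):
        fits, log = stratified_clr(
            scores_case[bone0][:, None], scores_control[bone0][:, None],
            labels, names=[f"{bone0}_vector"],
        )
        strat[name] = {
            str(s): {**_clr_dict(v["fit"]), "wide_ci": v["wide_ci"]}
            for s, v in fits.items()
        }
        strat[name]["skipped"] = [f"{s}: {msg}" for s, msg in log]
    analysis["stratified"] = strat
    timings["analyze"] = time.perf_counter() - t0

    report["analysis"] = analysis
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}

    # ---- artifacts ------------------------------------------------------
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_cohort(out / "cohort.csv", cohort)
        io.write_truth(out / "truth.json", truth)
        for bone, m in models.items():
            m.save(out / f"shape_model_{bone}.npz")
        sel.exclusions.to_csv(out / "exclusions.csv", index=False)
        pairs.drop(columns=["case_index", "control_index"]).to_csv(
            out / "pairs.csv", index=False
        )
        bal.to_csv(out / "balance.csv", index=False)
        scores_rows = []
        for bone in config.bones:
            for ids, arr, arm in (
                (m_cases["knee_id"], scores_case[bone], "case"),
                (m_controls["knee_id"], scores_control[bone], "control"),
            ):
                scores_rows.append(
                    pd.DataFrame({"knee_id": ids.to_numpy(), "bone": bone,
                                  "arm": arm, "b": arr})
                )
        pd.concat(scores_rows, ignore_index=True).to_csv(
            out / "scores.csv", index=False
        )
        # timings go to their own file so the analysis bundle is
        # byte-reproducible under a fixed seed
        io.dump_json(out / "timings.json", report["timings_s"])
        io.dump_json(
            out / "analysis.json",
            {k: v for k, v in report.items() if k != "timings_s"},
        )
        (out / "summary.txt").write_text(format_summary(report))
    return report


# ---------------------------------------------------------------------------
# human-readable summary
# ---------------------------------------------------------------------------


def _fmt_or(entry: dict, term: str) -> str:
    if "error" in entry:
        return f"not estimable ({entry['error']})"
    return (
        f"{entry['or'][term]:.2f} ({entry['or_ci_low'][term]:.2f}, "
        f"{entry['or_ci_high'][term]:.2f}) p={entry['p'][term]:.3g}"
    )


def format_summary(report: dict) -> str:
    a = report["analysis"]
    lines = [
        "Synthetic nested case-control run",
        f"seed = {report['config']['seed']}",
        "",
        f"Cohort: {report['cohort']['n_participants']} participants, "
        f"TKR prevalence {report['cohort']['tkr_prevalence_pct']}%",
        f"Selection: {report['selection']['cases']} cases, "
        f"{report['selection']['eligible_controls']} eligible controls, "
        f"{report['selection']['excluded']} knees excluded",
        f"Matching: {report['matching']['n_pairs']} pairs, "
        f"{report['matching']['n_exact']} exact "
        f"({report['matching']['exact_pct']:.0f}%), "
        f"max |dPS| = {report['matching']['max_abs_ps_diff']:.4f}, "
        f"{report['matching']['n_contralateral']} contralateral pairs",
        "",
        "Balance (standardized differences):",
    ]
    for row in report["balance"]:
        unit = "%" if row["type"] == "continuous" else ""
        lines.append(f"  {row['covariate']:<16} {row['std_diff']: .2f}{unit}")
    lines += ["", "Bone shape vectors, matched pairs (case vs control):",
              f"{'bone':<9}{'control':>16}{'case':>16}{'difference (95% CI)':>26}"]
    for bone, r in a["paired_t"].items():
        lines.append(
            f"{bone:<9}{r['mean_control']:>8.2f} ({r['sd_control']:.2f})"
            f"{r['mean_case']:>9.2f} ({r['sd_case']:.2f})"
            f"{r['mean_diff']:>10.2f} ({r['ci95'][0]:.2f}, {r['ci95'][1]:.2f})"
        )
    lines += ["", "Conditional logistic regression, OR (95% CI) per normalized unit:"]
    for bone, entry in a["univariable"].items():
        lines.append(f"  {bone:<9} unadjusted  {_fmt_or(entry, f'{bone}_vector')}")
    for bone, entry in a["adjusted"].items():
        lines.append(f"  {bone:<9} KL-adjusted {_fmt_or(entry, f'{bone}_vector')}")
    if "aic_table" in a:
        lines += ["", f"AIC comparison (complete-KL pairs, n={a['n_pairs_complete_kl']}):"]
        for row in a["aic_table"]:
            lines.append(f"  {row['model']:<24} k={row['k']:<3} AIC={row['aic']:.2f}")
    lines += ["", "Tertile analysis (lowest tertile = reference):"]
    for bone, entry in a["tertiles"].items():
        for arm in ("unadjusted", "adjusted"):
            sub = entry[arm]
            if "error" in sub:
                lines.append(f"  {bone} {arm}: not estimable")
                continue
            lines.append(
                f"  {bone:<9}{arm:<11} highest {_fmt_or(sub, 'highest_tertile')}; "
                f"middle {_fmt_or(sub, 'middle_tertile')}"
            )
    return "\n".join(lines) + "\n"
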