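"""Synthetic knee-OA cohort and bone-shape generator.

Everything downstream (shape-model training, case-control selection,
propensity matching, matched-pair inference) can be exercised end-to-end on
data drawn from explicit distributions under a single seed.  The generator
emulates the structure of a large observational knee-OA cohort:

* ~4,800 participants with two knees each, aged 45-79, 58% female, ~36%
  obese, and a knee-replacement (TKR) incidence near 7% of participants;
* one latent OA *severity* per knee that simultaneously drives the KL
  grade (by thresholding), knee pain, the TKR outcome, and the bone-shape
  deformation - so radiographic grade and 3D shape are correlated views of
  the same underlying process;
* knees within a participant share covariates and draw correlated
  severities (rho = 0.6), so contralateral control knees exist;
* a 96-shape labelled training set split 53 OA (KL 2-4) / 43 non-OA
  (KL 0-1), and test-retest shape replicates differing only in
  measurement noise.

Bone shapes are deterministic superellipsoid-like templates deformed by a
fixed localized "margin ridge" displacement field (scaled by severity,
mimicking osteophytic ridge growth at the cartilage-plate margins), a small
number of smooth random variation modes, and iid Gaussian point noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .datatypes import BONES, ShapeSample

__all__ = [
    "SimConfig",
    "bone_template",
    "oa_mode",
    "random_modes",
    "generate_shape",
    "generate_shape_stack",
    "generate_training_set",
    "generate_test_retest",
    "generate_cohort",
    "outcome_prevalence",
]


def _default_outcome_coefficients() -> dict:
    # intercept None => calibrated so participant-level incidence hits
    # tkr_target_rate; other terms are per-SD (age, bmi) or per-unit effects.
    return {
        "intercept": None,
        "severity": 0.5,
        "kl": 0.4,
        "age": 0.5,
        "female": 0.1,
        "bmi": 0.35,
        "pain": 0.25,
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with study-condition defaults."""

    n_participants: int = 4800
    seed: int = 0
    tkr_target_rate: float = 0.07
    outcome_coefficients: dict = field(default_factory=_default_outcome_coefficients)
    severity_noise_sd: float = 0.8
    shape_noise_sd: float = 0.5  # mm, per coordinate; ~ segmentation error
    n_points_per_bone: int = 500
    n_train: int = 96
    n_random_modes: int = 5
    kl_cut_points: tuple = (-0.4, 0.0, 0.9, 1.8)
    kl_missing_rate: float = 0.05
    knee_severity_corr: float = 0.6
    pain_intercept: float = 3.0
    pain_slope: float = 1.4
    pain_noise_sd: float = 1.2
    missing_shape_rate: float = 0.05
    non_oa_indication_rate: float = 0.0025
    indication_missing_rate: float = 0.15

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        for name in ("severity_noise_sd", "pain_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.shape_noise_sd < 0:
            raise ValueError("shape_noise_sd must be >= 0")
        for name in (
            "tkr_target_rate",
            "kl_missing_rate",
            "missing_shape_rate",
            "non_oa_indication_rate",
            "indication_missing_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if not (0.0 <= self.knee_severity_corr < 1.0):
            raise ValueError("knee_severity_corr must be in [0, 1)")
        if list(self.kl_cut_points) != sorted(self.kl_cut_points) or len(self.kl_cut_points) != 4:
            raise ValueError("kl_cut_points must be 4 increasing thresholds")


# ---------------------------------------------------------------------------
# bone geometry
# ---------------------------------------------------------------------------

_BONE_GEOMETRY = {
    # semi-axes (mm), superellipsoid exponent, fixed seed for variation modes
    "femur": ((32.0, 30.0, 26.0), 2.5, 101),
    "tibia": ((34.0, 24.0, 20.0), 3.0, 202),
    "patella": ((20.0, 19.0, 11.0), 2.2, 303),
}

_OA_MODE_RMS_MM = 1.0  # RMS point displacement per unit severity
_MODE_RMS_MM = 0.5  # RMS of the leading random variation mode
_MODE_DECAY = 0.75  # geometric decay of mode standard deviations


def _fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (golden-angle lattice)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _check_bone(bone: str) -> None:
    if bone not in _BONE_GEOMETRY:
        raise ValueError(f"unknown bone {bone!r}; expected one of {BONES}")


def bone_template(bone: str, n_points: int = 500) -> np.ndarray:
    """Deterministic template surface sampling for one bone, (N, 3) mm."""
    _check_bone(bone)
    (ax, ay, az), e, _ = _BONE_GEOMETRY[bone]
    u = _fibonacci_directions(n_points)
    denom = (
        np.abs(u[:, 0] / ax) ** e
        + np.abs(u[:, 1] / ay) ** e
        + np.abs(u[:, 2] / az) ** e
    )
    r = denom ** (-1.0 / e)
    return u * r[:, None]


def _rms_normalize(field: np.ndarray, rms: float) -> np.ndarray:
    cur = np.sqrt(np.mean(np.sum(field**2, axis=1)))
    return field * (rms / cur)


def oa_mode(bone: str, n_points: int = 500) -> np.ndarray:
    """Fixed OA deformation field: an outward ridge at the bone margin.

    Radial displacement concentrated in a band around the equator with a
    two-lobed azimuthal modulation plus a small uniform expansion term,
    normalized to 1 mm RMS point displacement per unit severity.
    """
    _check_bone(bone)
    u = _fibonacci_directions(n_points)
    z = u[:, 2]
    phi = np.arctan2(u[:, 1], u[:, 0])
    w = np.exp(-((z / 0.25) ** 2)) * (1.0 + 0.4 * np.cos(2.0 * phi)) + 0.15
    return _rms_normalize(w[:, None] * u, _OA_MODE_RMS_MM)


def random_modes(bone: str, n_points: int = 500, n_modes: int = 5) -> np.ndarray:
    """Smooth anatomical-variation displacement fields, (K, N, 3).

    Modes are fixed per bone (seeded by the bone's geometry entry, not by the
    cohort seed) and built from low-frequency functions of latitude and
    azimuth, each normalized to unit RMS; coefficients are drawn at sampling
    time with geometrically decaying standard deviations.
    """
    _check_bone(bone)
    _, _, mode_seed = _BONE_GEOMETRY[bone]
    rng = np.random.default_rng(mode_seed)
    u = _fibonacci_directions(n_points)
    z = u[:, 2]
    phi = np.arctan2(u[:, 1], u[:, 0])
    basis = np.column_stack(
        [
            np.ones_like(z),
            z,
            z**2,
            np.cos(phi),
            np.sin(phi),
            np.cos(2 * phi),
            np.sin(2 * phi),
            z * np.cos(phi),
            z * np.sin(phi),
        ]
    )
    modes = np.empty((n_modes, n_points, 3))
    for k in range(n_modes):
        coeff = rng.normal(size=(basis.shape[1], 3))
        modes[k] = _rms_normalize(basis @ coeff, 1.0)
    return modes


def mode_sds(n_modes: int) -> np.ndarray:
    """Standard deviations of the random-mode coefficients (mm RMS units)."""
    return _MODE_RMS_MM * _MODE_DECAY ** np.arange(n_modes)


def generate_shape_stack(
    severities,
    bone: str,
    config: SimConfig,
    rng: np.random.Generator,
    mode_coeffs: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized shape sampling: (n, N, 3) point sets for given severities.

    ``mode_coeffs`` may be supplied to reuse anatomy between replicates
    (test-retest pairs share severity and mode coefficients and differ only
    in the iid point noise).
    """
    sev = np.atleast_1d(np.asarray(severities, dtype=float))
    if not np.all(np.isfinite(sev)):
        raise ValueError("severities must be finite")
    n = sev.size
    npts = config.n_points_per_bone
    template = bone_template(bone, npts)
    v_oa = oa_mode(bone, npts)
    modes = random_modes(bone, npts, config.n_random_modes)
    if mode_coeffs is None:
        mode_coeffs = rng.normal(size=(n, config.n_random_modes)) * mode_sds(
            config.n_random_modes
        )
    pts = (
        template[None]
        + sev[:, None, None] * v_oa[None]
        + np.einsum("nk,kij->nij", mode_coeffs, modes)
        + rng.normal(scale=config.shape_noise_sd, size=(n, npts, 3))
    )
    return pts


def generate_shape(
    severity: float, bone: str, config: SimConfig, seed: int, knee_id: str = "",
    kl_grade: int | None = None,
) -> ShapeSample:
    """One bone shape at the given latent severity (deterministic in seed)."""
    rng = np.random.default_rng(seed)
    pts = generate_shape_stack([severity], bone, config, rng)[0]
    return ShapeSample(bone=bone, points=pts, knee_id=knee_id, kl_grade=kl_grade)


# KL-conditional severity centres used for the labelled training set; they
# sit inside the default kl_cut_points bins.
_TRAIN_SEVERITY_MU = (-0.9, -0.2, 0.45, 1.35, 2.2)
_TRAIN_SEVERITY_SD = 0.25
# 43 non-OA (KL 0-1) and 53 OA (KL 2-4) shapes
_TRAIN_COUNTS = (22, 21, 18, 18, 17)


def generate_training_set(config: SimConfig, bone: str = "femur") -> list[ShapeSample]:
    """The 96-shape labelled training set (53 OA / 43 non-OA)."""
    _check_bone(bone)
    if config.n_train != 96:
        # scale counts proportionally, preserving the 53:43 ratio roughly
        frac = config.n_train / 96.0
        counts = [max(1, round(c * frac)) for c in _TRAIN_COUNTS]
    else:
        counts = list(_TRAIN_COUNTS)
    rng = np.random.default_rng((config.seed, 1, BONES.index(bone)))
    samples: list[ShapeSample] = []
    sev_all, kl_all = [], []
    for kl, count in enumerate(counts):
        sev_all.append(rng.normal(_TRAIN_SEVERITY_MU[kl], _TRAIN_SEVERITY_SD, count))
        kl_all.extend([kl] * count)
    sev_all = np.concatenate(sev_all)
    stack = generate_shape_stack(sev_all, bone, config, rng)
    for i, (kl, pts) in enumerate(zip(kl_all, stack)):
        samples.append(
            ShapeSample(bone=bone, points=pts, knee_id=f"train_{bone}_{i:03d}", kl_grade=kl)
        )
    return samples


def generate_test_retest(
    n_knees: int, config: SimConfig, bone: str = "femur"
) -> tuple[list[ShapeSample], list[ShapeSample]]:
    """Paired shape replicates sharing severity and anatomy.

    The two scans of a pair differ only in the iid point noise, emulating
    repeat MRI of the same knee a week apart.
    """
    _check_bone(bone)
    if n_knees < 2:
        raise ValueError("need at least 2 knees")
    rng = np.random.default_rng((config.seed, 2, BONES.index(bone)))
    sev = rng.normal(1.0, 0.5, n_knees)  # OA knees
    coeffs = rng.normal(size=(n_knees, config.n_random_modes)) * mode_sds(
        config.n_random_modes
    )
    test = generate_shape_stack(sev, bone, config, rng, mode_coeffs=coeffs)
    retest = generate_shape_stack(sev, bone, config, rng, mode_coeffs=coeffs)
    mk = lambda stack, tag: [
        ShapeSample(bone=bone, points=p, knee_id=f"rt_{bone}_{i:03d}_{tag}")
        for i, p in enumerate(stack)
    ]
    return mk(test, "a"), mk(retest, "b")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _weight_category_score(bmi: np.ndarray) -> np.ndarray:
    """WHO weight category on a rough SD-like scale (0 / 0.7 / 1.4)."""
    return np.where(bmi >= 30.0, 1.4, np.where(bmi >= 25.0, 0.7, 0.0))


def _severity(config: SimConfig, z_age, bmi, rng) -> np.ndarray:
    """Per-knee latent severity, (n, 2): confounded by age and weight,
    correlated across a participant's knees.

    The weight effect acts through the WHO category, mirroring the joint
    load burden of being overweight/obese rather than marginal BMI units.
    """
    n = z_age.size
    base = 0.45 * z_age + 0.25 * _weight_category_score(bmi)
    rho = config.knee_severity_corr
    shared = rng.normal(size=n)
    own = rng.normal(size=(n, 2))
    noise = config.severity_noise_sd * (
        np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * own
    )
    return base[:, None] + noise


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Draw the full synthetic cohort: one row per knee.

    Returns the knee table and a simulation-truth sidecar (the calibrated
    outcome coefficients and the config).  The ``severity`` column is the
    hidden simulation truth and is never used by any analysis stage.
    """
    rng = np.random.default_rng((config.seed, 0))
    n = config.n_participants

    age = truncnorm.rvs(
        (45.0 - 61.0) / 9.0, (80.0 - 61.0) / 9.0, loc=61.0, scale=9.0, size=n,
        random_state=rng,
    )
    female = rng.random(n) < 0.58
    # lognormal BMI: median ~28.4, ~36% obese (>=30), ~0.2% underweight
    bmi = np.exp(rng.normal(3.3474, 0.15, n))
    z_age = (age - 61.0) / 9.0
    z_bmi = (bmi - 28.5) / 5.0

    sev = _severity(config, z_age, bmi, rng)  # (n, 2) left/right

    kl_true = np.digitize(sev, config.kl_cut_points).astype(float)
    kl = kl_true.copy()
    kl[rng.random((n, 2)) < config.kl_missing_rate] = np.nan

    pain = np.clip(
        np.rint(
            config.pain_intercept
            + config.pain_slope * sev
            + rng.normal(scale=config.pain_noise_sd, size=(n, 2))
        ),
        0,
        10,
    ).astype(int)

    coef = dict(_default_outcome_coefficients())
    coef.update(config.outcome_coefficients)
    # The direct weight effect on the decision to operate also acts through
    # the WHO weight category: the surgeon responds to obesity status, not
    # to marginal BMI units.
    wcat = _weight_category_score(bmi)
    # The radiographic grade itself enters the decision to operate (the
    # surgeon acts on the X-ray grading as well as on the underlying
    # structural severity); the true grade drives the outcome even where
    # the recorded grade is missing.
    eta = (
        coef["severity"] * sev
        + coef.get("kl", 0.0) * (kl_true - 2.0)
        + coef["age"] * z_age[:, None]
        + coef["female"] * female[:, None]
        + coef["bmi"] * wcat[:, None]
        + coef["pain"] * pain
    )
    if coef["intercept"] is None:
        if not (0.0 < config.tkr_target_rate < 1.0):
            raise ValueError("tkr_target_rate must be strictly inside (0, 1)")

        def excess(c):
            p = expit(c + eta)
            return float(np.mean(1.0 - (1.0 - p[:, 0]) * (1.0 - p[:, 1]))) - config.tkr_target_rate

        intercept = brentq(excess, -25.0, 10.0)
    else:
        intercept = float(coef["intercept"])
    coef["intercept"] = intercept
    p_tkr = expit(intercept + eta)
    tkr = rng.random((n, 2)) < p_tkr

    interval = rng.uniform(0.0, 7.0, (n, 2))
    # a fraction of bilateral replacements happen on the same day
    bilateral = tkr.all(axis=1)
    same_day = bilateral & (rng.random(n) < 0.3)
    interval[same_day, 1] = interval[same_day, 0]
    interval = np.where(tkr, interval, np.nan)

    insurance = rng.random((n, 2)) < np.where(tkr, 0.98, 0.96)
    has_shape = rng.random((n, 2)) >= config.missing_shape_rate

    # TKR indication: mostly OA, occasionally recorded as inflammatory
    # arthritis, sometimes unrecorded (analysis then falls back to
    # baseline radiographic + symptomatic evidence).
    u_ind = rng.random((n, 2))
    indication = np.full((n, 2), None, dtype=object)
    indication[tkr] = "OA"
    indication[tkr & (u_ind < config.non_oa_indication_rate)] = "RA"
    indication[
        tkr
        & (u_ind >= config.non_oa_indication_rate)
        & (u_ind < config.non_oa_indication_rate + config.indication_missing_rate)
    ] = None

    pid = np.array([f"P{i:05d}" for i in range(n)])
    rows = []
    for j, side in enumerate(("left", "right")):
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "knee_id": [f"{p}_{side[0].upper()}" for p in pid],
                    "side": side,
                    "age": age,
                    "gender": np.where(female, "female", "male"),
                    "bmi": bmi,
                    "nrs_pain": pain[:, j],
                    "kl_grade": kl[:, j],
                    "severity": sev[:, j],
                    "tkr": tkr[:, j],
                    "tkr_interval_years": interval[:, j],
                    "insurance": insurance[:, j],
                    "indication": indication[:, j],
                    "has_shape": has_shape[:, j],
                }
            )
        )
    df = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["participant_id", "side"])
        .reset_index(drop=True)
    )
    truth = {
        "outcome_coefficients": coef,
        "config": asdict(config),
        "n_participants": n,
    }
    truth["config"]["outcome_coefficients"] = coef
    return df, truth


def outcome_prevalence(cohort: pd.DataFrame, decimals: int = 0) -> float:
    """Participant-level TKR prevalence, as the percentage printed in reports."""
    per_part = cohort.groupby("participant_id")["tkr"].any()
    return round(100.0 * per_part.mean(), decimals)
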