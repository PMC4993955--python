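# Methods

This note documents the models implemented in `kneeshape`, the synthetic
data they are exercised on, and the numerical and design choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The OA shape vector

**Alignment.** Training point sets are centred and brought into a common
frame by generalized Procrustes analysis with translation and rotation only.
Scaling is deliberately *not* removed: osteoarthritic change includes
expansion of the bone surface (osteophytic ridge growth at the cartilage
margins), and similarity alignment would delete that part of the signal.
The iteration aligns each sample to the running consensus (Kabsch
superimposition, proper rotations only) and stops when the mean per-point
displacement of the samples in a pass falls below `tol` (default 1e-7 mm,
cap 100 iterations). Converged input is a fixed point, so re-alignment is
the identity; mutually random orientations converge much more slowly than
corresponded anatomies and may need a larger iteration budget.

**Shape space.** Principal components of the centred, aligned coordinate
matrix are retained up to the smallest number explaining at least
`var_frac` of total variance (default 0.98, configurable — the appropriate
truncation is an open choice; 0.98 keeps essentially all systematic shape
variation while discarding the bulk of the per-point noise dimensions).

**The vector.** The OA vector is defined in truncated component-score
space: `u` is the unit vector from the non-OA (KL 0–1) to the OA (KL 2–4)
training group mean (unweighted arithmetic means of member scores). Scores
are the orthogonal projection onto this line, affinely rescaled so the two
group means sit at −1 and +1. Training samples without a KL grade are
excluded from fitting. A model whose group means coincide is rejected as
degenerate.

**Scoring new shapes.** A raw point set is first rigidly aligned to the
model mean (`align=True`, the default). Alignment of a deformed shape to
the consensus is itself a least-squares compromise, so the exact −1/+1
normalization holds for shapes already expressed in the model frame;
scoring after alignment is rotation/translation-invariant to ≈1e-6.

**Reliability.** The smallest detectable difference is
1.96 × SD(test − retest) of paired scores (95% Bland–Altman limits of
agreement); changes smaller than the SDD are within measurement noise.

**Point-to-surface error.** Segmentation accuracy against a reference mesh
is the mean over points of the exact distance to the nearest triangle
(orthogonal plane distance where the projection lands inside the triangle
by barycentric test, otherwise the nearest edge).

## 2. Synthetic study conditions

The generator draws, under one seed, a cohort whose *structure* mirrors a
large observational knee-OA study; it does not claim to reproduce any real
dataset's joint distribution.

* 4,800 participants × 2 knees; age ~ TruncNormal(61, 9²) on [45, 80);
  58% female; BMI lognormal(3.3474, 0.15²) — ≈36% obese, ≈0.2%
  underweight (hence the underweight/normal WHO categories are merged).
* One latent **severity** per knee drives everything downstream:
  `s = 0.45·z_age + 0.25·w + e`, where `w` is the WHO weight-category
  score (0 / 0.7 / 1.4) and `e` is zero-mean Gaussian noise
  (SD 0.8) correlated ρ = 0.6 between a participant's knees (so
  contralateral case/control pairs can occur).
* KL grade = severity thresholded at (−0.4, 0.0, 0.9, 1.8), with 5% of
  grades missing at random; pain NRS = round(3 + 1.4·s + N(0, 1.2²))
  clipped to 0–10.
* TKR is Bernoulli per knee with logit
  `c + 0.5·s + 0.4·(KL−2) + 0.5·z_age + 0.1·female + 0.35·w + 0.25·pain`.
  The direct KL term reflects that the recorded radiographic grade itself
  enters the surgical decision — which is exactly why the propensity model
  omits KL. The intercept `c` is calibrated by root finding so the
  *participant-level* incidence (either knee replaced) hits the 7% target;
  an explicitly supplied intercept is used as-is. Replacement intervals are
  Uniform(0, 7] years; 30% of bilateral replacements share a surgery day to
  exercise the same-day tie rule. A small fraction of replacements carry a
  non-OA (inflammatory) indication, and some indications are unrecorded.
* **Shapes.** Each bone has a deterministic superellipsoid-like template
  (500 points via a spherical Fibonacci lattice). A shape is
  `template + s·V_OA + Σ c_k V_k + ε`: `V_OA` is a fixed margin-ridge
  displacement field (outward radial band around the equator, 1 mm RMS per
  severity unit); `V_k` are five fixed smooth random modes per bone with
  coefficients N(0, (0.5·0.75^k)²); `ε` is iid N(0, 0.5² mm²) per
  coordinate, on the order of automated-segmentation error. Test–retest
  replicates share severity and mode coefficients and differ only in `ε`.
* The labelled training set contains 22/21/18/18/17 shapes at KL 0–4
  (43 non-OA, 53 OA), with severities drawn around within-grade centres.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic femoral anatomy and its non-Gaussian
population variation; MRI artefacts and spatially correlated segmentation
error; time-varying covariates (e.g. BMI drift before surgery); informative
missingness; loss to follow-up; and any effect of unmeasured confounders.
Effect sizes on the synthetic conditions need not match any published
estimates; it is the *qualitative* behaviour (confounding removed by
matching, KL-adjustment attenuation, AIC ordering) that the conditions are
designed to exhibit.

## 3. Selection, matching, inference

* **Eligibility** requires recorded age, gender, pain and weight, plus
  shape (imaging) data. KL may be missing: KL-adjusted models drop those
  pairs (complete-case), and the AIC comparator refuses to rank models
  fitted on different pair sets. Where the TKR indication is unrecorded,
  an OA indication is taken as "highly likely" when KL ≥ 2 and pain ≥ 1
  at baseline (the criterion is verbal in the design; these thresholds are
  this package's decision).
* **Matching** is greedy nearest-neighbour without replacement on the
  propensity score, cases in descending score order with lexicographic
  knee-id tie-breaks (ties in |Δps| are detected with a 1e-12 float
  tolerance). No caliper is imposed; instead the report carries the number
  of exact matches at 2-decimal precision and the maximum |Δps|. An
  optional exact-gender constraint is off by default. Greedy matching is
  deliberately *not* optimal assignment; the test suite verifies it never
  beats a Hungarian-algorithm oracle on total |Δps|.
* **Balance**: continuous covariates (age, BMI, pain on their raw scales)
  use 100·(x̄₁−x̄₀)/√((s₁²+s₀²)/2); dichotomous ones use the prevalence
  difference over the pooled binomial SD; thresholds 10% and 0.1.
* **Conditional logistic regression** maximizes the 1:1 conditional
  likelihood Π σ(d·β), d = x_case − x_control, by Newton–Raphson from
  β = 0 (score tolerance 1e-8, cap 50 iterations, step-halving).
  Wald CIs and p-values mirror the usual OR (95% CI) presentation; a
  likelihood-ratio test is available as secondary output. Pairs with
  d = 0 contribute the constant ½ and are *kept* in the likelihood so AIC
  (= 2k − 2·logL) stays comparable across models on one pair set; they are
  separately counted as non-informative. Monotone likelihoods and
  quasi-complete separation (estimates drifting beyond |β| > 15 while the
  score vanishes) raise explicit errors — a silently huge coefficient is
  never returned. With very few KL-0 cases (as in the emulated design)
  the KL-dummy adjusted model is occasionally non-estimable for exactly
  this reason; such runs report the error, and seed-ensemble checks of the
  attenuation phenomenon are evaluated over the estimable runs.
* **Tertiles** use the pooled matched-sample 1/3 and 2/3 empirical
  quantiles at baseline (the quantile population is this package's choice),
  lower-open/upper-closed intervals, ties to the lower tertile, lowest
  tertile as reference.
* **Stratified analyses** subset existing pairs by the *case* knee's
  stratum (KL band, or time-to-TKR band 0–2/2–4/4–7 years) rather than
  re-matching within strata; strata under 10 informative pairs are flagged
  wide-CI.

## 4. Pipeline and problem sizes

A run executes generate → train → select → match → score → analyze under a
single seed; per-stage child seeds are derived deterministically (all below
2³¹) so stages can be re-run in isolation. Shapes are generated and scored
only for the knees that enter matched pairs — the nested design's own
efficiency argument — so a full default run (4,800 participants, three
bones, ≈320 pairs) completes in seconds. Wall-clock timings are written to
a separate file so the analysis bundle is byte-reproducible under a fixed
seed. Seed-ensemble properties in the test suite use fixed grids (100
cohorts for covariate balance, 40 runs for the attenuation signature,
1,000 replicates × 300 pairs for estimator calibration) — sizes chosen so
the whole suite stays desk-scale while the binomial noise on each checked
proportion remains small.

## 5. Known limitations

* The template bones are schematic closed surfaces; correspondence is by
  construction, so the package assumes (and does not solve) the
  segmentation/correspondence problem.
* Scoring aligns each shape independently to the model mean; for extreme
  deformations the alignment-then-project score is only approximately
  invariant to the deformation's rigid component.
* The propensity model is correctly specified for the synthetic outcome by
  design (weight acts through its WHO category); with real data,
  residual within-category confounding would not be removed by matching.
* Greedy matching is order-dependent by construction; determinism, not
  optimality, is the contract.
* Stratified and tertile-adjusted models on ≈300 pairs are sparse-data
  analyses; estimates there carry wide intervals and occasional
  non-estimability, which the reports surface rather than suppress.
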