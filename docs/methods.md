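# Methods

This note records the model, the numerical and design choices, and what the
synthetic data generator does and does not emulate.

## Time-slice transformation

Observations are consolidated onto nine periods [−1, 1], (1, 3], (3, 6], …,
(21, 24] months from initial diagnosis. The first period is closed on both
ends (pre-treatment workup may precede diagnosis by up to a month); later
periods are half-open `(lo, hi]` so the scheme is a partition — a time on a
printed boundary such as 3.0 belongs to the earlier period.

Within a period each variable takes its **newest** measurement. A cell is
*complete* only when every dictionary variable is present. A patient under
follow-up whose cell is incomplete is treated as lost to structured
surveillance from that slice on: the cell and every later cell are
unavailable (absorbing). Partial cells are not partially imputed — dropping
them is the conservative reading of a rule that either keeps a slice or
discards it. The single exception is a patient holding **cancer-free status**
(CFS): when an episode covers the whole missing period, the previous slice is
available, and real data re-appear at a later slice, the gap is filled by
last-observation-carried-forward and marked `imputed_locf`. LOCF never
invents values — an imputed cell is a copy of its predecessor.

Each available cell carries a **landmark**: the newest observation time in
the cell, standing in for the slice's imaging examination. (Whether the
original workflow anchored landmarks to imaging dates or slice boundaries is
an open choice; imputed cells fall back to the period's upper bound, and the
anchor is per-cell data so either convention can be emulated by the caller.)
Landmark survival at slice t contains exactly the patients with an available
cell and overall survival strictly beyond their landmark, with times re-based
to the landmark.

## Binarization

Every covariate enters the tree as a binary adverse indicator. Continuous
and ordinal variables use declared cutoffs with an adverse direction
(`ge`: value ≥ threshold is adverse, e.g. diameter ≥ 70 mm; `le`: value ≤
threshold is adverse, e.g. albumin ≤ 35 g/L); the comparison is inclusive.
Stock cutoffs ship for the eleven baseline features (age 50 y, diameter
70 mm, 4 lesions, AFP 25 IU/ml, albumin 35 g/L, total bilirubin 34 µmol/L,
prothrombin time 13 s, Child–Pugh 7 points); binary variables pass through.
The full cutoff table of the original clinical application is not public, so
cutoffs are configuration, not constants.

## Survival-path tree

Growth is breadth-first over slices 1..9 and fully deterministic:

- The root holds every patient in the slice-1 landmark risk set.
- At each slice boundary a node is screened: every candidate binary covariate
  with both levels present, ≥ 2 events and no missing values is fitted by
  **univariate Cox** on the node's landmark survival. The screen is a
  single-parameter Newton maximization of the Efron-tie partial likelihood
  with step-halving, capped at |β| = 15; monotone likelihoods (complete
  separation) and non-convergent fits mark the variable ineligible rather
  than aborting growth. Wald p-values are used throughout. (Whether the
  original implementation screened by univariate or multivariable Cox is not
  documented; univariate matches the single-bifurcation-variable semantics
  and keeps the subnode-size constraint checkable per variable. The screen
  is cross-checked against lifelines' general fitter in the test suite.)
- A split is accepted when p < α (default 0.05) and **both** resulting
  subnodes — the adverse/non-adverse subsets of the patients still available
  at the next slice — hold at least `min_split` (default 15) patients. Among
  qualifying variables the smallest p wins; ties break by larger |log HR|,
  then lexicographic name, so identical inputs always give identical trees.
- A node with no qualifying split passes its available patients forward as a
  single child, so survival paths persist across slices; patients whose
  cells become unavailable leave the tree silently.
- Node ids are assigned in creation order; every node records n and the
  Kaplan–Meier median OS from its own slice landmark (`None` = not reached).

Consequences of this construction worth noting: children always live one
slice after their parent, so the slice-1 root is never subdivided — at
prediction slice 1 the model assigns everyone the same risk and its
concordance is 0.5 by the tie convention. Discrimination appears from slice
2 onward as splits accumulate.

**Scoring.** A patient (training or held-out) is routed from the root by
applying each recorded split to their binarized value at the corresponding
slice; routing stops (no score) at any unavailable cell. Risk at prediction
slice t and horizon Δt is `1 − Ŝ_node(Δt)` with `Ŝ_node` the node's
*training* KM curve — real-valued, horizon-aware, and deliberately tied
within a node. Nodes with fewer than 3 members in the evaluated sample are
omitted (extreme-subgroup rule).

## Static comparators

Gaussian naive Bayes, random forest and an RBF support-vector classifier are
trained on the eleven slice-1 features against dead-by-horizon labels for
horizons {6, 12, 24, 36, 48} months; patients censored before a horizon
carry no label there (treating them as alive would inject noise). RF and SVC
hyperparameters come from small fixed grids (RF: trees {100, 500} × depth
{3, 5, ∞}; SVC: C {0.1, 1, 10}) selected by held-out AUC on an internal
seeded 70/30 split — AUC, not accuracy, because the models are consumed as
risk rankers. SVC features are standardized and its probabilities come from
internal cross-validated Platt calibration, so all three kinds emit a
probability of death by the horizon; a horizon whose labels collapse to one
class (or an all-constant feature matrix) yields a degenerate constant
model. Fixed seeds reproduce hyperparameters and predictions exactly.

## Evaluation

`C(t, Δt)` (truncated Harrell): over pairs where subject i dies within Δt of
the landmark and subject j survives past `T_i`, the fraction with
`risk_i > risk_j`, ties counting ½. The IPCW variant weights each pair by
`1/Ĝ(T_i⁻)²` with `Ĝ` the KM censoring-survival estimate, and reduces
exactly to the Harrell form when censoring is absent. The Harrell form is
the default for transparency; the IPCW form mirrors the behaviour of
censoring-weighted estimators in standard survival-evaluation packages whose
exact option set for the original analysis is not documented.

Uncertainty: 10 seeded subsamples of ⌊2n/3⌋ patients without replacement;
the subgroup filter applies per draw; undefined draws (no comparable pair)
are skipped and counted. SD uses the n−1 denominator. By default the draws
are shared across models within a grid cell (paired comparison, lower
comparison variance); independent draws are available.

Model comparison: `z = (m_a − m_b)/√(s_a² + s_b²)` with a two-sided normal
p-value, at a Bonferroni-corrected α (default 0.05/55 ≈ 0.0009). Treating
the two resampling SDs as independent standard errors ignores the positive
correlation induced by overlapping subsamples, so the test is approximate —
a known limitation, kept because the resampling design provides no clean
pairing across cells.

## Synthetic cohort generator

The generator emulates an intermediate-stage HCC cohort followed on the
3-month grid. What it reproduces:

- **Baseline marginals**: age ≥ 50 in 63.5%, male 89.4%, HBV 92.8%,
  AFP ≥ 25 IU/ml in 67.6%, Child–Pugh A 91.9%, tumor ≥ 5 cm in 67.2%,
  ≥ 4 lesions in 57.8%; labs drawn consistently with the intended
  Child–Pugh class.
- **Disease dynamics**: per-slice response/stable/progression moves
  (0.20/0.55/0.25) multiply tumor diameter and AFP, drift the liver labs and
  recompute the Child–Pugh score; vascular invasion and ascites can develop
  under progression. A latent **recurrence-prone subtype** (40% of patients)
  emits fresh intrahepatic lesions at 0.60 per slice (0.02 sporadically);
  the event is recorded only as the follow-up flag `new_lesion`.
- **Survival**: piecewise-constant hazard per slice,
  `λ_s = h₀ · exp(β · x_s)` on the current binarized covariates, h₀ =
  0.012/month, frozen at the slice-9 state beyond month 24. The dominant
  coefficient (log HR 1.5) sits on `new_lesion`; tumor-burden and
  liver-function coefficients are moderate (0.10–0.50). Defaults give a
  median OS of ~16 months and ~85% observed deaths under uniform(30, 84)
  administrative censoring — a plausible regime for this disease stage.
- **Follow-up realism**: visit times jittered uniformly within each period
  (so newest-value selection and landmark anchoring are non-trivial),
  occasional repeat AFP measurements, 3%/slice loss to surveillance
  (observations stop, survival follow-up continues), and CFS episodes in 5%
  of responders with interior missing slices to exercise LOCF.

The emitted cohort is a deterministic masking of the returned ground truth
(latent trajectories, linear predictors, true event/censor times, dropout
slices), and `truth_cindex` exposes the oracle concordance of the
generator's own current-slice linear predictor.

**Why the recurrence subtype.** The premise of dynamic prognostication is
that risk tracks the current state, so trajectory-aware models should beat
baseline-trained ones at late landmarks. With hazard driven only by
covariates that also sit in the baseline feature set, that advantage largely
evaporates: a baseline-trained classifier scored on *current* continuous
features (tumor diameter integrates the whole growth history) approximates
the current-state oracle. The generator therefore routes the dominant late
signal through a persistent follow-up event (`new_lesion`) that belongs to
the tree's candidate dictionary but not to the eleven baseline features —
matching the clinical situation where newly appearing lesions are a
follow-up finding, not a baseline covariate. This is the structural reason
the path model dominates the static models at late prediction slices in the
shipped configuration.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: treatment effects and treatment-stage migration,
competing risks, calendar-time effects, measurement error (emitted values
equal the latent state), correlated visit schedules (sicker patients are not
visited more often), informative censoring, and between-center heterogeneity.
Dynamics are first-order (next state depends on the current state and the
latent subtype only). Quantitative concordances from the synthetic world do
not transfer to any real cohort; the qualitative ordering of models is the
designed property.

## Numerical choices and degenerate inputs

- Cox screen: Newton from β = 0, ascent guaranteed by step-halving,
  tolerance 1e-9, ≤ 60 iterations; information ≤ 0, |β| ≈ 15 or
  non-convergence ⇒ variable ineligible.
- KM medians and survival-at-horizon via lifelines; `median_survival_time_`
  of ∞ maps to "not reached" (`None`, printed "NA").
- `C(t, Δt)` comparable-pair set requires strict `T_i < T_j`; a cell with no
  comparable pair is flagged undefined (NaN), never coerced to 0 or 0.5.
- Resampling draws with fewer than two scored patients are skipped; a cell
  where every draw is undefined is reported absent ("–" in reports).
- Z test with both SDs zero: equal means ⇒ z = 0, p = 1; unequal ⇒ ±∞,
  flagged significant.
- All randomness flows through named integer seeds (generator, split, model,
  evaluation); per-cell evaluation RNG is derived from
  `SeedSequence([seed, t, 1000·Δt])` so grid cells are independent but
  reproducible.

## Problem sizes used in the shipped checks

Unit and property tests run on cohorts of 150–400 patients; the
planted-split recovery checks use nodes of 300 patients over 10 seeds; the
late-landmark dominance check uses the full default configuration (2000
patients, 10 generator seeds, prediction slice 7, horizon 24 months); the
end-to-end determinism check runs the complete pipeline twice at n = 500.
These sizes give stable verdicts for every property while keeping a full
run on one CPU in the minutes range.

## Known limitations

- The Z test's independence approximation (above).
- Node risk is a training-set KM estimate; no shrinkage or cross-validation
  within nodes, so small terminal nodes carry noisy risks (mitigated by the
  min-subgroup filter).
- One split per node per slice boundary, binary splits only; no pruning or
  cross-validated tree selection; no multivariable or penalized Cox at
  nodes; no competing risks; no model-based imputation beyond the CFS LOCF
  rule.
- The slice-1 root is never subdivided, so the path model is uninformative
  at the first landmark by construction.
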