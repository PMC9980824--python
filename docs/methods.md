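# Methods

This note documents the models, defaults and numerical choices behind
`ecarm`, and what the passing tests do and do not establish.

## The estimand and the pipeline

The pipeline emulates the ustekinumab comparator arm of a Crohn's disease
trial from retrospective EHR-style tables. The cohort is defined in six
stages — code/order query, greedy eligibility screening, empirical baseline
window selection, informatics ascertainment of disease-activity elements,
iterative random-forest imputation, and CDAI-range finalisation — and the
endpoints are descriptive: mean CDAI reduction ± SE at weeks 12 and 24,
remission (CDAI ≤ 150), steroid use, and steroid-free remission. No
hypothesis test against a trial arm is performed, by design.

## The CDAI

Best's formula with weights 2 / 5 / 7 / 20 / 30 / 10 / 6 / 100 over the
eight components. Conventions:

* **×7 expansion.** Real diaries sum seven daily entries; clinic notes record
  single-visit assessments. A single-visit daily value is multiplied by 7 to
  stand in for the diary sum. The convention lives in one place
  (`cdai.from_daily`, `ascertainment.components_from_row`) and is switchable
  by scoring 7-day sums directly.
* **Hematocrit reference** 47% (men) / 42% (women); the hematocrit and weight
  terms may individually be negative; the total is floored at 0.
* **Abdominal mass** defaults to absent when ascertained from structured
  data: physical-exam findings are not reliably coded. This is a documented
  limitation, not an estimate.
* Scoring a matrix row clips imputed continuous values back into their
  declared ordinal ranges (pain 0–3, wellbeing 0–4, stools ≥ 0) and rounds
  imputed flags to {0, 1}.

Eligibility is 220 ≤ CDAI ≤ 450 inclusive; remission CDAI ≤ 150 inclusive.
Percentages print as count/denominator with the percent rounded half away
from zero (12.5% → 13%). Note 37.5% → 38% under this rule.

## Screening

* Week-based windows use unambiguous day arithmetic: 3 weeks = 21 days,
  12 weeks = 84 days, 6 months = 183 days.
* Window convention `(anchor − lookback, anchor]`: the induction day counts
  as prior exposure for non-ustekinumab orders, since the infusion's time of
  day is unknowable — a conservative choice.
* **Dose change** of a drug class = two orders with different doses whose
  later start falls in the window, or any start/stop of the class inside it.
  A patient stably on a drug since before the window passes.
* "Approved route and dose" = first ustekinumab order IV, later orders SC at
  90 mg.
* Biologic-washout criteria are deliberately absent, mirroring the emulated
  protocol's deviation (washouts removed nearly all real-world candidates).
* Screening is greedy (stop at first failure, fixed printed criterion
  order). The final eligible set is provably order-invariant — the tests
  check greedy against exhaustive evaluation — only the attribution of
  exclusions depends on order.

## Baseline-window selection

The published analysis chose 12 weeks "by visual review" of availability
curves; a reproducible surrogate is needed. We quantify "no substantial
increase in missing data" as a **5% plateau rule**: the smallest lookback w
such that every PRO element's availability at w is at least 95% of its
availability at the maximum lookback (16 weeks). The joint (worst-element)
rule is a declared choice; the per-element curves are forced non-decreasing
by construction. Snapshots take the observation closest to the anchor day
inside the window, ties to the earlier date (prefer pre-anchor data,
deterministic). Follow-up windows are fixed a priori: week 12 = days 70–98,
week 24 = days 140–196.

## Imputation

A missForest-style imputer authored here, with scikit-learn random forests
as base learners:

* initialise with column mean / mode (mode ties to the lexicographically
  smallest value, for determinism);
* visit columns in increasing-missingness order; per column, fit a forest on
  the rows where it is observed and predict its missing cells;
* convergence statistics per sweep: Δ_cont = Σ(new−old)²/Σnew² over imputed
  continuous cells, Δ_cat = disagreement fraction over imputed categorical
  cells; stop when either increases (or at `max_iter` = 10) and return the
  matrix from the sweep before the increase;
* observed cells are never altered; a fixed seed gives a bit-identical
  result.

Defaults: 100 trees, `max_features="sqrt"`. The "two routines" of the
emulated study are realised as two variants of this one implementation
(different seed, `max_features`, `min_samples_leaf`), because the point of
the sensitivity analysis is robustness to variant choice, not package
identity. The cohort matrix is **wide** — one row per patient, columns
element@period (≈ 48 variables) — so the forests can borrow information
across timepoints, which is what makes post-baseline imputation work when
most week-12 PRO values are missing. Single imputation only; no pooling, no
MNAR modelling.

## The synthetic generator

`synthetic_ehr.generate_bundle` emits linked tables from a known latent
state; defaults are the study conditions and are not tuned per experiment.

* **Baseline CDAI**: Normal(location, 120), floored at 30. The location
  defaults to the value solved (truncated-normal mean, root find) so that
  the *eligible-range* (220–450) mean is 305. The population scale of 120
  makes roughly 40% of screened patients fall in range — most real-world
  candidates are too mild for trial eligibility.
* **Response**: responders (80%) decline by Δ(t) = A·(1 − e^(−t/τ)) with A
  and τ solved so the *cohort-mean* decline is exactly the configured 95 /
  133 points at days 84 / 168; non-responders decline by 0. The configured
  effects are cohort means, so the recovery target is the config value
  itself. The saturating-rise form requires effect₂₄/effect₁₂ ∈ (1, 2).
* **Decomposition**: the non-PRO contribution (EIM count, antidiarrheal use,
  hematocrit deficit, weight deviation) is constant per patient; the PRO
  remainder is split by per-patient Dirichlet shares (pain/wellbeing/stools
  ≈ 18/30/52%), capped at the pain and wellbeing scale maxima with the
  excess spilt into the unbounded stool count, then rounded to daily
  ordinals. Treatment response therefore flows entirely through the PROs,
  matching the observation that informatics accuracy is driven by PRO
  dominance and EIM class imbalance (prevalence 3% per category).
* **Visits**: renewal process with exponential gaps (mean 30 days) over days
  −150..+210, with all visits inside an exponential authorization gap (mean
  30 days) before day 0 removed. All three PRO elements are documented
  together at a visit with probability 0.75, labs with probability 0.4 —
  reproducing both the availability rise with lookback and baseline /
  follow-up PRO missingness of roughly 25% / 50–60%.
* **Steroids**: 38% start as users; tapers stop geometrically (10%/week), so
  ~13% remain on steroids in the week-12 window. A pure taper cannot
  reproduce a late *rise* in steroid use (restarts); week-24 steroid use is
  therefore lower than in the emulated study. Known limitation.
* **Ineligibility injections**: each non-CDAI criterion independently
  disqualifies 13.1% of patients via a detectable artifact (an IV-steroid
  order 10 days before induction, a dose change inside the window, a recent
  ileocecectomy, …), so ~25% of candidates survive screening.
* **Manual-abstraction view**: element values are ground truth; an element
  is present when the structured view observed it or with 50% recovery
  probability otherwise, so manual completeness dominates structured
  completeness. With zero noise, daily visits and full documentation the two
  views coincide — that configuration is what the perfect-concordance tests
  use.

What the generator does **not** emulate: visit-level correlation of symptom
noise, informative (MNAR) missingness, steroid restarts, coding errors or
code-set drift, free text. Passing recovery tests therefore show the
pipeline is consistent under MCAR-like documentation gaps and the stated
trajectory model — not that it is unbiased on real clinical data.

## Recovery experiments and problem sizes

`experiments.run_parameter_recovery` simulates 5500 candidate records
(≈ 1350 screened-eligible, cohort ≈ 600), runs the full pipeline and
compares estimates with configured truth. At this scale the week-12/24
reductions recover within two standard errors. The pipeline-reported cohort
mean baseline CDAI sits 0–5 points below the calibrated 305 because
membership is decided on *imputed* scores: imputed values are shrunk toward
their conditional mean, and selecting the 220–450 band on shrunken scores
admits slightly milder patients. The generator-level calibration itself is
verified separately on the true scores of screened-eligible patients. Unit
and property tests run at much smaller scales (tens to a few hundred
patients) chosen to exercise the contracts, not to minimise runtime noise.

## Degenerate inputs and tie-breaks

* Zero patients: every stage reports an explicit empty-cohort status.
* Missing CDAI components raise with a pointer to imputation; they are never
  silently defaulted.
* Concordance drops pairs with either side missing; zero comparable pairs is
  an error for accuracy, a flagged NaN for MAE; r² is refused below 3 pairs
  or at zero variance.
* n = 1 endpoint summaries report SE = 0 with a warning.
* Snapshot ties break earlier; mode ties break lexicographically; the
  attrition report validates that first-failure counts sum to the eligible
  count.
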