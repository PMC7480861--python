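# Methods

This note records the modelling assumptions, parameter conventions and
numerical choices behind `readmit_rx`, and what the synthetic-data tests
do and do not establish about behaviour on real registry data.

## Cohort model and preprocessing

A cohort is a patient × variable table with a binary 30-day readmission
outcome, a pre-operative/post-operative class per variable, and three
special roles: the hematocrit HCT (volume %, the actionable variable), the
pre-operative transfusion indicator TRANSFUS, and any bounded-probability
variables (values in [0,1], e.g. estimated mortality/morbidity
probabilities).  Missing entries are `NaN` and never enter computation.

* **Death filter.**  Patients who died within 30 days without readmission
  are removed (their outcome is unobservable, not negative); row order is
  preserved and the filter is idempotent.
* **Sparse variables.**  Variables missing in *strictly more than* 80% of
  rows are dropped; exactly 80% is retained.  The cut-off is a parameter.
* **Imputation.**  Cluster-restricted k-nearest-neighbour: k-means
  (default 10 clusters, seeded) on the fully observed variables after
  min-max scaling, then for each missing cell the mean of the k = 5
  nearest same-cluster donors observing that variable.  Equidistant donors
  at the k-th distance are all averaged (a deterministic tie-break);
  clusters without a donor fall back to the whole cohort.  Consequences
  proved in tests: observed cells are never altered, imputed values stay
  inside each variable's observed range, and the procedure is
  deterministic given the seed.  Rows that are entirely missing are an
  error, not a guess.
* **Scaling.**  Min-max to [0,1] using *training-split* statistics only.
  Zero-range variables map to the constant 0.  Test-set values outside the
  training range are deliberately not clipped: the transform stays affine,
  so linear-model scores remain monotone in the raw values.  Trees are
  trained on unscaled values (axis-aligned splits are invariant to
  monotone rescaling, and raw thresholds read clinically).
* **Comparison table.**  Welch's two-sample t-test (no equal-variance
  assumption, Welch–Satterthwaite df) per variable on *unnormalized*
  values, readmitted vs not, sorted by ascending two-tailed p.  Raw
  p-values are reported without multiple-testing correction — the table
  ranks candidate discriminators rather than testing hypotheses.  For
  indicator variables the group mean is the fraction satisfying the
  condition.  A variable with zero variance in both groups and equal
  means is reported as t = 0, p = 1.

## Predictive models

Scores always follow one sign convention: larger = riskier.

* **L2 logistic regression** minimizes mean class-weighted logistic loss
  plus λ₂‖w‖² (intercept unpenalized) with L-BFGS and an analytic
  gradient; the objective is strictly convex so the optimum is
  start-independent (verified by a gradient-norm < 1e-4 check).
* **SLSVM** minimizes mean class-weighted hinge loss plus λ₁‖w‖₁, solved
  *exactly* as a linear program (HiGHS), then hard-thresholds to the κ
  largest |w| and refits the hinge loss on that support (with a vanishing
  λ₁ = 1e-8 so separable refits stay bounded).  κ and λ₁ are exposed; the
  refit provably never increases the support-restricted hinge loss.
* **Class weighting.**  At ~5.5% prevalence an unweighted fit collapses
  toward the majority class, so both linear models default to
  inverse-prevalence class weights (mean weight 1); `class_weight=None`
  restores the unweighted objective.
* **Ensemble/NN baselines** are adapters around scikit-learn estimators
  (random forest defaults to 500 trees; the MLP is a small fixed
  architecture), all seeded.  Their internals are out of scope.
* **Threshold calibration.**  τ is the (1−p)-quantile of training scores,
  p the training prevalence; the rule predicts positive iff score > τ
  (strictly), so ties at τ go negative and round(p·n) patients are
  predicted positive up to ties.  At rare-outcome prevalence this forces
  specificity near 1 − p.

## Treatments and baseline factuals

One bag of blood ≈ +3 HCT percentage points; the domain is b ∈ {0,1,2,3}
bags (+0/3/6/9 points; 9 is the safe ceiling).  Registries record whether
a pre-operative transfusion occurred but not the volume, so factual doses
are reconstructed from (HCT, TRANSFUS): 0 bags if untransfused; otherwise
1, 2 or 3 bags for HCT > 30, 27 < HCT < 30, HCT < 27 — the dose that
plausibly lifted the patient toward the common transfusion trigger of 30.
Boundary values (exactly 30 or 27) get the fewer-bags arm: when the rule
is ambiguous we assume the conservative transfusion.

## Counterfactual covariate model

Fitted on unscaled training rows so slopes keep physical units.  Screening
uses Pearson correlation (|r| > 0.1) of each pre-operative variable with
HCT, pairwise-complete over missingness; the adjusted list is derived from
the data, never hard-coded.  Each selected variable gets a univariate
regression on HCT — ordinary least squares, or least squares on the logit
scale for bounded-probability variables (values clamped to
[1e-6, 1−1e-6] with a warning before the transform), which keeps adjusted
values strictly inside (0,1) for any dose.  Applying a dose shifts HCT by
3b and each adjusted variable by slope·Δ on its link scale; identity-link
shifts are additive in Δ.  The TRANSFUS indicator is toggled to 1 for
treated patients by default (`toggle_transfus=False` disables this).
HCT itself and TRANSFUS are never in the adjusted set.

## Prescriptive SVM

Stage 2 treats only candidates (HCT < 30; everyone else gets 0 bags) and
minimizes, per patient, `loss(score after dose) + λ_rx·3b` by enumerating
the four doses — exact because the objective separates across patients.
Ties break toward fewer bags.  Two losses are implemented:

* **indicator** (default): the hard 0/1 predicted-readmission indicator
  after threshold τ.  Doses go only to candidates whose prediction a shift
  can actually flip; on cohorts of a few thousand patients this caps the
  average dose among candidates well below one bag.
* **hinge**: max(0, 1 + s − τ).  Every in-margin candidate benefits from
  any score reduction, so prescriptions are nearly bang-bang in λ_rx: for
  λ_rx below |w_HCT|/range(HCT) almost all in-margin candidates get their
  full useful dose, above it nobody does.

By default stage 2 moves only the HCT coordinate of the score; the
correlated-covariate shifts enter at evaluation time
(`include_covariate_shifts=True` folds them into stage 2 as well).  The
dose penalty λ_rx is selected by `tune_lambda_rx`, which scans a grid and
returns the value whose average dose among training candidates is closest
to a target of one bag — the operating point at which the method is meant
to run.  Because of the dose-response shapes above, the achievable average
on a small synthetic cohort may sit below that target; the tuner then
returns the closest attainable point rather than forcing doses.

## Optimal prescriptive trees

Leaves estimate the readmission rate per treatment arm from their factual
members; the leaf prescribes the arm with the smallest estimate (ties →
fewest bags) and predicts that arm's rate.  The training objective is

    α · (1/n) Σᵢ (ŷ_{ℓ(i), bᵢ} − yᵢ)²  +  (1−α) · (1/n) Σᵢ ŷ_{ℓ(i), b*_{ℓ(i)}}

— a squared-error term against each patient's own factual arm estimate
plus the mean estimated rate under the prescribed arms; both terms are
rates in [0,1] and α (default 0.5) trades predictive faithfulness against
prescriptive aggressiveness.

* **Arm fallback.**  Observational data rarely populate four arms per
  leaf.  Arms with fewer than `n_arm_min` factual members inherit the
  parent node's arm estimate, recursively up to cohort-wide arm means.
  The default `n_arm_min=10` suits common outcomes; **for rare outcomes it
  should grow** (the examples use 50–75 at 5% prevalence), because a thin
  arm with zero observed events otherwise wins every argmin — a winner's-
  curse artifact of comparing noisy minima, visible in the package's own
  demos and called out here deliberately.
* **Search.**  Greedy top-down induction over midpoint split candidates
  (at most `max_bins=32` quantile-spaced candidates for high-cardinality
  variables; exact midpoints below that, so small-instance behaviour is
  exact), followed by a seeded local-search sweep: collapse a node to a
  leaf, exactly re-split twig nodes, and — for nodes with at most
  `rebuild_max_rows` rows — try every candidate split with greedily
  rebuilt children.  Each accepted move strictly decreases the objective,
  so the search terminates; on fixtures small enough for enumeration it
  attains the exhaustive depth-≤2 optimum (tested).
* Split candidates need `min_leaf` rows on both sides; a node with no
  admissible improving split becomes a leaf.

## Evaluation protocol

Three independent 80/20 train/test splits (seeded).  Everything —
scalers, predictive ground truths, prescribers, the counterfactual model,
thresholds — is refit on each split's training side.  On the test side:

    prevented % = 100 · #(candidates predicted readmitted untreated whose
                  post-treatment prediction is negative)
                / #(candidates predicted readmitted untreated)

with the treated record shifted by the counterfactual model before
re-scoring.  Only positive flips count; a clearly-labelled `net=True`
variant subtracts reverse flips but is not the headline metric.  An empty
denominator yields NaN with a warning rather than a fabricated zero.
Alongside: the average dose among candidates (treated or not) and the
constant one-bag baseline.  Split-level values aggregate as mean and
sample (n−1) standard deviation, computed in full precision and reported
to 2 decimals.

On cohorts of a few thousand patients the denominator is a handful of
patients (5% prevalence × 5% candidates), so per-split prevented
percentages are coarse (multiples of 1/den) and vary strongly across
ground-truth models; this is a property of the desk-scale cohort, not of
the estimator, and the generator's true counterfactual probabilities
(`true_effect`) provide the smooth oracle the real world lacks.

## Synthetic cohort generator

The generator emulates the published cohort facts a registry extract would
provide: 5.49% target readmission prevalence (intercept solved by root
finding so the mean factual-treatment probability hits the target), HCT ~
Normal(39.67, 6) clipped to (12, 58) with a protective logistic
coefficient (−0.05 per point, so readmitted patients run ~2 points lower),
creatinine/INR/prothrombin-time/albumin-like labs linear in HCT,
mortality/morbidity probabilities generated through a logit link on HCT,
a TRANSFUS indicator hitting low-HCT patients with configurable adherence
(default 0.85) and a small background rate above the trigger, factual
doses from the baseline rule, outcome-informative post-operative
complication variables (so post-operative models dominate pre-operative
ones), MCAR missingness at 5% (an age-dependent MAR switch exists), one
~90%-missing lab to exercise the sparse filter, and ~1% deaths without
readmission to exercise the cohort filter.

The true treatment effect acts causally through HCT (and through the
morbidity probability's logit link), optionally strengthened inside a
treatment-responsive subgroup (`subgroup_gamma`) and weakened or reversed
outside it (`complement_gamma`, default 0 — by default every candidate
genuinely benefits).  `GroundTruth` carries the coefficients and each
patient's true P(readmission | dose) for all four doses.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real data: procedure-code feature structure
(CPT/ICD9), the full ~200-variable correlation fabric, informative
missingness tied to clinical workflows, unmeasured confounding between
transfusion practice and outcome beyond the encoded HCT pathway, and
registry scale (7×10⁵ patients), where prevented-percentage denominators
are three orders of magnitude larger and arm estimates correspondingly
stable.

## Problem sizes and determinism

Unit and property tests run on cohorts of 16–2,500 rows; parameter-
recovery checks use n = 10,000 (counterfactual slopes within 10%
relative error), support recovery n = 2,000 (4+ of 5 seeds), subgroup
recovery n = 5,000 (majority of 5 seeds under the responsive-subgroup
stress configuration with 20% prevalence), and the end-to-end
reproducibility check runs the full pipeline twice at n = 1,000 and
compares artifacts byte-for-byte.  All randomness flows through explicit
integer seeds (NumPy `default_rng` / `SeedSequence`); reruns with the
same configuration are bit-identical, including CSV artifacts.

## Known limitations

* Prevented percentages are estimates against predictive models, not
  causal measurements; without a randomized trial the package can only
  show consistency across several ground truths (and, on synthetic data,
  against the generator's oracle).
* The two-stage P-SVM moves one actionable variable; joint interventions
  and continuous dosing are out of scope.
* The tree trainer is a heuristic for an NP-hard objective; optimality is
  guaranteed (and tested) only at enumeration scale.
* The imputation scheme is one concrete instantiation of kNN-plus-
  clustering; it is deliberately simple and deterministic rather than
  state of the art.
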