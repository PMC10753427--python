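# Methods

## Study design being emulated

The package implements a nested (density-sampled) case-control analysis of
medication dispensing and early-onset colorectal cancer inside a dynamic
health-provider cohort. Cases are first CRC diagnoses in 2001–2019 at age
≤ 50 with ≥ 3 years of continuous prior enrollment and no IBD or
hereditary-syndrome indication; each case is matched to 10 controls sampled
from its risk set at the index date (exact match on sex, residential
district, sociodemographic band, population subgroup and periphery band;
birth year within ±2). Exposure is "ever dispensed" per ATC level-5 class,
assessed strictly before index minus a 2-year lag; classes used by < 0.1%
of the matched cohort are dropped. A repeated gradient-boosted screen
nominates classes; a matched conditional-logistic model estimates adjusted
odds ratios.

## Synthetic-data generator

**What it emulates.** Demographics are drawn independently from categorical
margins (defaults reproduce the matched cohort's sex / district / subgroup
splits; the sociodemographic band is a discretized normal with mean 6.5, SD
1.9 on a 1–10 scale). Enrollment starts are uniform over 1995–2005; 90% of
subjects stay enrolled through the study end and 10% disenroll early, so
the 3-year enrollment filter and risk-set eligibility genuinely bind.
Physician visits are a homogeneous per-subject Poisson stream with
Gamma-distributed monthly rates (mean 7.2/yr, SD ≈ 6/yr). Each of the (by
default 800) medication classes gets a log-uniform baseline prevalence on
[0.0005, 0.35], reproducing the long right tail of real dispensing data.
Ever-exposure is Bernoulli on the logit scale, optionally shifted by
comorbidities (confounding by indication: one condition can raise both the
odds of dispensing selected classes and the outcome hazard; the mechanism
is off by default so the null generator is clean). Exposed subjects receive
one dispensing uniform over enrollment plus, with probability 0.3, an extra
dispensing in their final 2 enrolled years — events the lag filter must
discard.

**Outcome model.** A discrete annual hazard: in each calendar year a
currently enrolled, undiagnosed subject is diagnosed with probability
`baseline_annual_hazard × exp(Σ log OR_j · exposed_j(t−2y) + Σ γ_c ·
comorbid_c(t))`. The default baseline hazard is 1e-4/yr — a deliberate
rare-disease regime in which conditional odds ratios approximate the
planted hazard ratios. A consequence is that a default-sized population
(120,000) yields on the order of 150 ascertained cases, far fewer than the
~941 of the emulated study; experiments that need exact case counts plant a
registry (`plant_case_registry`), which also guarantees ample risk sets via
a matching-cell pool threshold. The generator makes no attempt to model
dose, adherence, drug switching, seasonality, or age-dependent incidence;
calendar time enters only through enrollment and the hazard loop.
Consequently, passing tests demonstrate correctness of the *pipeline
mechanics and estimators* under the assumed generating process, not
real-world validity of any medication signal.

**Retrospective matched-set generator.** For estimator calibration and
screening power studies, `simulate_matched_cohort` draws exposure directly
within 1:M sets: controls are Bernoulli(p₀ⱼ) and the case is
Bernoulli(p₁ⱼ) with odds(p₁ⱼ) = ORⱼ · odds(p₀ⱼ). The conditional-logistic
estimator is consistent for log ORⱼ under this mechanism, so planted values
are recoverable without the (much slower) forward simulation. The forward
annual-hazard generator remains the instrument for cohort-construction
tests, where risk sets must change over calendar time.

## Conditional logistic regression

The conditional likelihood for one case per set,
`L(β) = Πₛ exp(x_case·β) / Σ_{j∈s} exp(x_j·β)`, is maximized by
Newton–Raphson with analytic score and observed information, β initialized
at 0 and steps halved whenever the likelihood decreases. Convergence is
declared at max |score| < 1e-8; because the score of a ~10⁴-row problem
carries ~1e-8 of float64 summation noise, iteration also stops when the
Newton step falls below 1e-12, and step-halving tolerates likelihood
decreases under 1e-10. A coefficient exceeding 15 in magnitude while the
likelihood still improves raises a separation error naming the feature.
Standard errors come from the pseudo-inverse of the observed information —
pseudo, so that a covariate constant within every set (which the
conditional likelihood cannot identify) degrades to a zero estimate without
contaminating the others. Inference is Wald (95% CIs, two-sided p); the
default model is joint (all selected medications plus the four adjustment
covariates — visit rate, diabetes, cardiovascular disease, excess weight —
in one fit), with a per-medication mode available. Hypertension is computed
upstream but not adjusted for by default.

Verification is three-way: the closed-form discordant-pair odds ratio
n₁₀/n₀₁ on 1:1 designs (agreement to 1e-6), a brute-force likelihood grid
on tiny fixtures (1e-4), and statsmodels' `ConditionalLogit` on random
mixed-covariate designs (1e-5); statsmodels is a test-only cross-check,
never a runtime dependency.

## Screening

Each of the `n_runs` (default 50) runs holds out a random 20% of rows,
tunes XGBoost hyperparameters by sequential model-based optimization
(Matern-5/2 GP over the unit-cube-encoded space, expected improvement over
random candidates; `medscreen.bayesopt`) of the 5-fold cross-validated
log-loss, refits on the 80% at the cross-validated round count, and scores
global SHAP (mean |TreeSHAP contribution|, via XGBoost's native
`pred_contribs`) on the held-out rows. Out-of-sample scoring is a
deliberate choice: the holdout exists to make importances reproducible, and
out-of-sample SHAP resists overfit artifacts. The default search space:
learning rate [0.01, 0.3] (log), depth 1–8, row/column subsample
[0.5, 1], min child weight [1, 20], L1/L2 [1e-3, 10] (log), ≤ 2000 rounds
with 50-round early stopping.

Consensus: a class is selected when its global SHAP is strictly positive in
≥ 50% of runs, or lands in the top 2.5% of at least one run's importance
distribution. The top-2.5% threshold is the ⌈0.025·k⌉-th largest score
within the run (ties included), so 800 distinct scores flag exactly 20
classes; a strict-positivity guard keeps an all-zero run from selecting
anything. Matched-set structure is ignored at this stage (matching keys are
balanced by design and are not features); direction and magnitude come only
from the regression stage.

**Interactions.** The final model is refit on the full data restricted to
the selected classes; non-depth hyperparameters are tuned once, then depth
is profiled over 1–6. Interactions are called informative iff the best
depth exceeds 1 *and* its mean paired per-fold improvement over depth 1
exceeds one standard error of those paired fold differences — a
one-standard-error operationalization of "did deeper trees help". Column
subsampling is pinned to 1 for this stage: with only a handful of selected
features, per-tree column sampling can show a tree one member of an
interacting pair, making the interaction structurally invisible at any
depth (a planted XOR pair is the regression test for this).

## Problem sizes and numerical choices

Reference experiments run at the study's scale where that is cheap (941
sets × 1:10; 800 classes; 25 estimator replicates) and at a reduced
screening scale where it is not: 20 runs with optimization budget 10 (and,
for null calibration, 10 runs with budget 5), a learning-rate floor of
0.05, depth ≤ 6, ≤ 200 boosting rounds with 20-round early stopping. Because every screen
feature is a binary ever-exposure indicator, the boosted trees use 4
histogram bins (`max_bin=4`) — lossless for 0/1 features and roughly half
the per-round cost of the 256-bin default — and cross-validation folds are
materialized once per search and reused across all candidate
configurations. The null-coverage check uses 400 replicates so its Monte
Carlo standard error (~1.1%) sits well inside the ±3% acceptance band. The planted signal panel
for screening power is fixed once: conditional ORs 1.94, 1.61, 0.33, 1.70,
0.60 at control prevalences 3.1%, 5%, 4%, 7.7%, 10% — magnitudes all ≥ 1.6
and prevalences all ≥ 3%, echoing the strongest signals the design is meant
to detect. Quantile and threshold conventions: the rarity filter drops
classes with users < ⌈0.001·N⌉; dates are ISO-8601 with half-open
intervals; ages are index year minus birth year (matching operates on birth
years, not birth dates).

## Known limitations

* The exclusion arithmetic of the emulated study (1461 → 1174 → "941")
  does not reconcile (1174 − 237 = 937); the pipeline reports whatever its
  own ledger produces and makes no attempt to force a particular count.
* The generator's incidence model is a stand-in: absolute case counts at
  default settings are not calibrated to any registry.
* Confounding by indication can be generated and adjusted for, but the
  screen itself is marginal: a strongly confounded class will be nominated,
  as in the emulated design, and only the adjusted regression can shrink it.
* Wald intervals slightly undercover (~94.5% at the reference size) as is
  typical for matched designs of this sparsity; no exact conditional
  inference is provided.
* The screen treats rows as exchangeable; no attempt is made to respect
  matched sets during holdout splitting.
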