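# medscreen

Medication-wide screening for early-onset colorectal cancer (EOCRC) risk
signals in matched case-control dispensing data.

EOCRC — colorectal cancer diagnosed at age 50 or younger — has risen sharply
since the 1990s, and most cases carry neither a hereditary cancer syndrome
nor inflammatory bowel disease. One candidate class of environmental
exposures is prior medication use. `medscreen` implements, end to end, the
analysis design used to screen for such signals in health-provider EMR data:

1. **Synthetic EMR generator** (`medscreen.synthetic`) — a dynamic cohort
   with configurable demographic margins, enrollment spans, ~800 ATC
   level-5 medication classes with a long-tailed prevalence spread,
   physician-visit streams, optional confounding by indication
   (comorbidity → exposure *and* outcome), and a discrete annual-hazard
   outcome model with planted conditional odds ratios. Because the source
   data for this design are proprietary EMRs, the generator is a
   first-class, tested component: every downstream stage is exercised
   against data whose truth is known.
2. **Cohort builder** (`medscreen.cohort`) — case ascertainment (first CRC
   diagnosis 2001–2019, age ≤ 50), exclusions (≥3 years of continuous
   pre-index enrollment; no IBD / hereditary-syndrome flag), and 1:10
   **density (risk-set) matching**: controls are drawn uniformly without
   replacement from the subjects at risk on the case's index date that
   exactly match on sex, district, sociodemographic band, population
   subgroup and periphery, with birth year ±2. A future case may serve as a
   control before its own diagnosis; each subject serves as a control at
   most once.
3. **Exposure builder** (`medscreen.exposure`) — binary "ever dispensed
   strictly before index − 2 years" indicators per ATC level-5 class (the
   2-year lag guards against reverse causation), a <0.1%-of-cohort rarity
   filter, comorbidity indicators, and the lag-truncated physician-visit
   rate (a surveillance-bias proxy).
4. **Screening** (`medscreen.screening`) — 50 independent XGBoost
   classifiers, each setting aside a random 20% of rows, with
   hyperparameters tuned per run by Bayesian optimization (GP + expected
   improvement, `medscreen.bayesopt`) of the 5-fold cross-validated
   log-loss. Per run, the **global SHAP** importance of each class (mean
   |TreeSHAP contribution| on the held-out rows) is recorded. A class is
   selected when it is associated (global SHAP > 0) in **≥50% of runs**, or
   reaches the **top 2.5%** of at least one run's importance distribution.
   A final full-data model profiles the tree-depth hyperparameter to judge
   whether interactions between medications are informative.
5. **Effect estimation** (`medscreen.conditional_logit`) — a from-scratch
   **conditional logistic regression** for 1:M matched sets, maximizing

   L(β) = ∏ₛ exp(x_case(s)·β) / Σ_{j∈s} exp(x_j·β)

   by Newton–Raphson with analytic score and observed information; Wald
   95% CIs and p-values. On 1:1 binary designs it reduces exactly to the
   discordant-pair estimator n₁₀/n₀₁. Odds ratios are adjusted for
   physician-visit frequency, diabetes, cardiovascular disease and excess
   weight.
6. **Reporting / CLI** (`medscreen.reporting`, `medscreen.cli`) — pipeline
   orchestration, a reproduction manifest, and the three standard tables
   (matched demographics; per-class prevalence of use with consensus rates;
   adjusted ORs sorted descending).

## Worked example

Recover a planted conditional odds ratio of 1.94 for an exposure with 2.4%
control prevalence, in 941 matched 1:10 sets:

```python
import numpy as np
from medscreen.synthetic import simulate_matched_cohort
from medscreen.conditional_logit import fit_conditional_logistic

coh = simulate_matched_cohort(
    n_sets=941, ratio=10, prevalences=np.array([0.024]),
    planted={0: 1.94}, seed=1,
)
fit = fit_conditional_logistic(coh.X, coh.y, coh.set_id)
print(fit.summary().round(4))
```

```
  feature    beta      se      or  ci_low  ci_high       p
0      x0  0.6752  0.1837  1.9644  1.3705   2.8158  0.0002
```

The single-seed estimate (OR 1.96, 95% CI 1.37–2.82, p = 0.0002) scatters
around the planted 1.94; averaging over 25 seeds recovers it to within a
few percent (see below). The full pipeline runs from a shell:

```bash
medscreen simulate --out data/ --seed 7
medscreen build-cohort --data data/ --ratio 10 --seed 7 --out matched_sets.csv
medscreen build-exposure --cohort matched_sets.csv --data data/ --out stage/
medscreen screen --exposure stage/exposure_matrix.parquet --runs 50 --out stage/
medscreen estimate --exposure stage/exposure_matrix.parquet \
    --covariates stage/covariates.csv --consensus stage/consensus.csv
# or everything at once, with a manifest:
medscreen run --out medscreen_out --seed 7
```

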