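"""Scaled replication experiments: planted-effect recovery and screening
power/calibration under the study's matched 1:10 design.

These are the package's reference experiments: 941 matched sets of 1 case
and 10 controls, 800 ATC level-5 classes with a long-tailed prevalence
spread, and a small panel of planted conditional effects whose magnitudes
echo the strongest reported medication signals (odds ratios near 1.9 and
1.6 for harmful classes and 0.33 for a protective one). Screens run in the
reduced configuration (20 runs, optimization budget 10, 5-fold CV) so a
full experiment fits on one CPU in minutes; estimator experiments average
25 seeded replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from medscreen.config import reduced_screening_config
from medscreen.conditional_logit import fit_conditional_logistic
from medscreen.exposure import exposure_features, filter_rare_drugs
from medscreen.screening import RunResult, consensus_select, run_screening
from medscreen.synthetic import MatchedCohort, simulate_matched_cohort

#: Planted signal panel for screening-power experiments: class index ->
#: (conditional odds ratio, control prevalence). All magnitudes are at least
#: 1.6 and all prevalences at least 3%.
SIGNAL_PANEL: dict[int, tuple[float, float]] = {
    3: (1.94, 0.031),
    97: (1.61, 0.05),
    211: (0.33, 0.04),
    405: (1.70, 0.077),
    633: (0.60, 0.10),
}


def planted_or_recovery(
    odds_ratio: float,
    control_prevalence: float,
    n_replicates: int = 25,
    n_sets: int = 941,
    ratio: int = 10,
    base_seed: int = 1,
) -> dict:
    """Mean conditional-logistic OR over seeded replicates of a single
    planted exposure in 941 matched 1:10 sets."""
    estimates = []
    for rep in range(n_replicates):
        coh = simulate_matched_cohort(
            n_sets=n_sets,
            ratio=ratio,
            prevalences=np.array([control_prevalence]),
            planted={0: odds_ratio},
            seed=base_seed + rep,
        )
        fit = fit_conditional_logistic(coh.X, coh.y, coh.set_id)
        estimates.append(float(fit.odds_ratio[0]))
    return {
        "mean_or": float(np.mean(estimates)),
        "estimates": estimates,
        "n_rows": n_sets * (ratio + 1),
        "n_replicates": n_replicates,
    }


def build_signal_cohort(
    seed: int,
    panel: dict[int, tuple[float, float]] | None = None,
    n_classes: int = 800,
    n_sets: int = 941,
    ratio: int = 10,
) -> MatchedCohort:
    """Full-width matched cohort with the planted signal panel (or a null
    cohort when ``panel`` is empty)."""
    panel = SIGNAL_PANEL if panel is None else panel
    rng = np.random.default_rng([seed, 8])
    prevalences = np.exp(rng.uniform(np.log(0.0005), np.log(0.35), n_classes))
    planted = {}
    for cid, (orr, prev) in panel.items():
        prevalences[cid] = prev
        planted[cid] = orr
    return simulate_matched_cohort(
        n_sets=n_sets,
        ratio=ratio,
        prevalences=prevalences,
        planted=planted,
        seed=seed,
    )


def _screen_cohort(
    coh: MatchedCohort, n_runs: int, bo_budget: int, base_seed: int
) -> tuple[list[RunResult], pd.DataFrame, list[str]]:
    """Rarity-filter the cohort's matrix, screen it, and return the run
    results, the consensus table, and the retained feature names."""
    frame = coh.frame()
    frame.insert(1, "subject_id", np.arange(len(frame)))
    filtered = filter_rare_drugs(frame, min_frac=0.001)
    feats = exposure_features(filtered)
    cfg = reduced_screening_config(
        n_runs=n_runs, bo_budget=bo_budget, base_seed=base_seed
    )
    results = run_screening(
        filtered[feats].to_numpy(np.float32),
        filtered["is_case"].to_numpy(),
        cfg,
        feature_names=feats,
    )
    return results, consensus_select(results), feats


def signal_screen_experiment(
    seed: int = 1, n_runs: int = 20, bo_budget: int = 10
) -> dict:
    """Screen the planted-panel cohort; count planted classes passing the
    at-least-50%-of-runs consistency clause."""
    coh = build_signal_cohort(seed)
    results, consensus, feats = _screen_cohort(coh, n_runs, bo_budget, seed)
    planted_codes = [coh.feature_names[cid] for cid in SIGNAL_PANEL]
    rates = consensus.set_index("feature")["association_rate"]
    planted_rates = {code: float(rates.get(code, 0.0)) for code in planted_codes}
    return {
        "n_planted_passing_rate_clause": sum(
            r >= 0.5 for r in planted_rates.values()
        ),
        "planted_association_rates": planted_rates,
        "n_features_screened": len(feats),
        "n_rows": len(coh.y),
        "consensus": consensus,
    }


def null_screen_experiment(
    seed: int = 1, n_runs: int = 10, bo_budget: int = 5, n_classes: int = 800
) -> dict:
    """Screen an all-null cohort; report the fraction of classes passing the
    rate clause (the screen's per-class type-I selection rate)."""
    coh = build_signal_cohort(seed, panel={}, n_classes=n_classes)
    results, consensus, feats = _screen_cohort(coh, n_runs, bo_budget, seed)
    n_pass = int((consensus["association_rate"] >= 0.5).sum())
    return {
        "n_passing_rate_clause": n_pass,
        "frac_of_catalog": n_pass / n_classes,
        "n_features_screened": len(feats),
        "consensus": consensus,
    }


def null_ci_coverage(
    n_replicates: int = 100,
    n_sets: int = 941,
    ratio: int = 10,
    prevalence: float = 0.1,
    base_seed: int = 1,
) -> dict:
    """Coverage of the 95% Wald CI for a null single-feature model."""
    covered = 0
    for rep in range(n_replicates):
        coh = simulate_matched_cohort(
            n_sets=n_sets,
            ratio=ratio,
            prevalences=np.array([prevalence]),
            seed=base_seed + 1000 + rep,
        )
        fit = fit_conditional_logistic(coh.X, coh.y, coh.set_id)
        lo, hi = fit.ci95[0]
        covered += lo <= 1.0 <= hi
    return {"coverage": covered / n_replicates, "n_replicates": n_replicates}


def xor_cohort(
    n_rows: int = 10351, seed: int = 1, base_rate: float = -2.2, effect: float = 2.5
) -> tuple[np.ndarray, np.ndarray]:
    """Two co-acting exposures whose risk lives purely in their XOR; no
    depth-1 tree can express it."""
    rng = np.random.default_rng([seed, 9])
    X = (rng.random((n_rows, 2)) < 0.5).astype(np.float32)
    xor = np.logical_xor(X[:, 0], X[:, 1])
    p = 1 / (1 + np.exp(-(base_rate + effect * xor)))
    y = (rng.random(n_rows) < p).astype(int)
    return X, y
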