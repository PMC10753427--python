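"""Configuration objects for the simulation and screening stages.

All stage parameters default to the study design they emulate: a 2001-2019
dynamic cohort of a large Israeli health provider, 1:10 density matching,
a 2-year exposure lag, ~800 ATC level-5 medication classes, 50 repeated
gradient-boosted screening runs with 5-fold cross-validated Bayesian
hyperparameter optimization.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

STUDY_START = np.datetime64("2001-01-01")
STUDY_END = np.datetime64("2020-01-01")  # half-open [start, end)

#: Conditions tracked as chronic comorbidities (adjustment candidates).
COMORBIDITIES = ("diabetes", "hypertension", "cardiovascular", "excess_weight")
#: Conditions that trigger case exclusion.
EXCLUSION_CONDITIONS = ("ibd", "hereditary_syndrome")


def _ses_margin(mean: float = 6.5, sd: float = 1.9) -> dict[int, float]:
    """Discretized-normal margin over the 1-10 sociodemographic scale."""
    from scipy.stats import norm

    edges = np.arange(0.5, 11.5)
    cdf = norm.cdf(edges, loc=mean, scale=sd)
    p = np.diff(cdf)
    p /= p.sum()
    return {band: float(pi) for band, pi in zip(range(1, 11), p)}


def default_demographic_margins() -> dict[str, dict]:
    """Categorical margins matching the matched-cohort demographics.

    Sex, residential district and population subgroup use the cohort
    percentages; sociodemographic status is a discretized normal with
    mean 6.5 and SD 1.9 on the 1-10 band scale; the periphery margin and
    birth-year range are the generator's own choices (not reported for
    the source population).
    """
    birth_years = list(range(1951, 1990))
    return {
        "sex": {"male": 0.488, "female": 0.512},
        "district": {
            "north": 0.187,
            "center": 0.194,
            "jerusalem": 0.224,
            "sharon": 0.225,
            "south": 0.170,
        },
        "subpopulation": {
            "secular": 0.881,
            "ultra_orthodox": 0.068,
            "arab": 0.051,
        },
        "ses": _ses_margin(),
        "periphery": {"central": 0.65, "peripheral": 0.35},
        "birth_year": {y: 1.0 / len(birth_years) for y in birth_years},
    }


@dataclass(frozen=True)
class PlantedEffect:
    """A medication class with a known conditional odds ratio on the outcome."""

    class_id: int
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError(f"odds_ratio must be > 0, got {self.odds_ratio}")


@dataclass(frozen=True)
class ConfounderEffect:
    """Confounding by indication: a comorbidity that shifts both the odds of
    being dispensed certain medication classes and the outcome hazard."""

    condition: str
    exposure_log_odds: float
    outcome_log_odds: float
    affected_classes: tuple[int, ...] = ()


@dataclass
class SimConfig:
    """Parameters of the synthetic EMR dispensing-data generator.

    Parameters
    ----------
    seed
        Master seed; every draw derives from it.
    n_population
        Number of subjects in the dynamic cohort.
    study_window
        Half-open [start, end) calendar window for case ascertainment.
    n_drug_classes
        Size of the ATC level-5 catalog.
    prevalence_range
        Per-class baseline ever-exposure probability is drawn log-uniformly
        from this interval, reproducing the long-tailed prevalence spread of
        real dispensing data.
    planted_effects
        Medication classes with non-null conditional odds ratios on the
        outcome hazard.
    confounder_effects
        Comorbidity-driven dual effects on exposure and outcome; empty by
        default so the null generator is clean.
    baseline_annual_hazard
        Outcome probability per enrolled person-year for an unexposed,
        comorbidity-free subject. Kept in the rare-disease regime so
        conditional odds ratios approximate the planted hazard ratios.
    comorbidity_rates
        Lifetime probability of each chronic condition / exclusion flag.
    visit_rate_gamma
        (shape, scale) of the Gamma distribution of per-month physician
        visit rates; defaults give mean 0.6/month (7.2/yr), SD ~0.5/month.
    extra_recent_event_prob
        Probability that an exposed subject receives an additional dispensing
        inside the final 2 years of enrollment (exercises the lag filter).
    """

    seed: int = 0
    n_population: int = 120_000
    study_window: tuple[np.datetime64, np.datetime64] = (STUDY_START, STUDY_END)
    n_drug_classes: int = 800
    prevalence_range: tuple[float, float] = (0.0005, 0.35)
    planted_effects: Sequence[PlantedEffect] = ()
    confounder_effects: Sequence[ConfounderEffect] = ()
    baseline_annual_hazard: float = 1e-4
    demographic_margins: Mapping[str, Mapping] = field(
        default_factory=default_demographic_margins
    )
    comorbidity_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "diabetes": 0.05,
            "hypertension": 0.08,
            "cardiovascular": 0.03,
            "excess_weight": 0.12,
            "ibd": 0.005,
            "hereditary_syndrome": 0.003,
        }
    )
    visit_rate_gamma: tuple[float, float] = (1.44, 0.4167)
    extra_recent_event_prob: float = 0.3
    margin_tol: float = 1e-6

    def __post_init__(self) -> None:
        start, end = (np.datetime64(d) for d in self.study_window)
        if end <= start:
            raise ValueError("study_window end must be after start")
        self.study_window = (start, end)
        lo, hi = self.prevalence_range
        if not (0 <= lo <= hi < 1):
            raise ValueError(f"invalid prevalence_range {self.prevalence_range}")
        if not (0 < self.baseline_annual_hazard < 1):
            raise ValueError("baseline_annual_hazard must be in (0,1)")
        if self.n_drug_classes < len(self.planted_effects):
            raise ValueError("more planted effects than drug classes")
        self.planted_effects = tuple(
            e if isinstance(e, PlantedEffect) else PlantedEffect(**e)
            for e in self.planted_effects
        )
        self.confounder_effects = tuple(
            e if isinstance(e, ConfounderEffect) else ConfounderEffect(**e)
            for e in self.confounder_effects
        )
        for eff in self.planted_effects:
            if not 0 <= eff.class_id < self.n_drug_classes:
                raise ValueError(f"planted class_id {eff.class_id} not in catalog")
        for name, margin in self.demographic_margins.items():
            total = sum(margin.values())
            if not math.isclose(total, 1.0, abs_tol=max(self.margin_tol, 1e-6)):
                raise ValueError(f"margin '{name}' sums to {total}, expected 1")
            if any(p < 0 for p in margin.values()):
                raise ValueError(f"margin '{name}' has negative probabilities")

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "study_window" in raw:
            raw["study_window"] = tuple(np.datetime64(d) for d in raw["study_window"])
        if "planted_effects" in raw:
            raw["planted_effects"] = [PlantedEffect(**e) for e in raw["planted_effects"]]
        if "confounder_effects" in raw:
            raw["confounder_effects"] = [
                ConfounderEffect(
                    condition=e["condition"],
                    exposure_log_odds=e["exposure_log_odds"],
                    outcome_log_odds=e["outcome_log_odds"],
                    affected_classes=tuple(e.get("affected_classes", ())),
                )
                for e in raw["confounder_effects"]
            ]
        if "demographic_margins" in raw:
            margins = raw["demographic_margins"]
            for key in ("ses", "birth_year"):
                if key in margins:
                    margins[key] = {int(k): v for k, v in margins[key].items()}
        return cls(**raw)

    def to_json(self, path) -> None:
        raw = asdict(self)
        raw["study_window"] = [str(d) for d in self.study_window]
        raw["planted_effects"] = [asdict(e) for e in self.planted_effects]
        raw["confounder_effects"] = [
            {**asdict(e), "affected_classes": list(e.affected_classes)}
            for e in self.confounder_effects
        ]
        raw["demographic_margins"] = {
            k: {str(c): p for c, p in m.items()}
            for k, m in self.demographic_margins.items()
        }
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2)


#: Hyperparameter search space of the screening stage (log-scale where noted).
DEFAULT_SPACE: dict[str, tuple] = {
    "learning_rate": (0.01, 0.3, "log"),
    "max_depth": (1, 8, "int"),
    "subsample": (0.5, 1.0, "linear"),
    "colsample_bytree": (0.5, 1.0, "linear"),
    "min_child_weight": (1.0, 20.0, "linear"),
    "reg_alpha": (1e-3, 10.0, "log"),
    "reg_lambda": (1e-3, 10.0, "log"),
}

#: Reduced space for scaled-down screens (fewer boosting rounds, shallower
#: trees, faster learning-rate floor); identical structure, cheaper to
#: cross-validate on one CPU.
REDUCED_SPACE: dict[str, tuple] = {
    "learning_rate": (0.05, 0.3, "log"),
    "max_depth": (1, 6, "int"),
    "subsample": (0.5, 1.0, "linear"),
    "colsample_bytree": (0.5, 1.0, "linear"),
    "min_child_weight": (1.0, 20.0, "linear"),
    "reg_alpha": (1e-3, 10.0, "log"),
    "reg_lambda": (1e-3, 10.0, "log"),
}


@dataclass
class ScreeningConfig:
    """Repeated gradient-boosted screening parameters.

    Defaults follow the study design: 50 independent runs, each holding out a
    random 20% of rows, hyperparameters tuned by 5-fold cross-validated
    Bayesian optimization; global Shapley importances are evaluated on each
    run's held-out rows.
    """

    n_runs: int = 50
    holdout_frac: float = 0.2
    cv_folds: int = 5
    bo_budget: int = 30
    space: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_SPACE))
    base_seed: int = 0
    max_rounds: int = 2000
    early_stopping_rounds: int = 50
    #: screen features are binary ever-exposure indicators, so a handful of
    #: histogram bins loses nothing and roughly halves the per-round cost
    max_bin: int = 4
    nthread: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.holdout_frac < 1:
            raise ValueError("holdout_frac must be in (0,1)")
        if self.n_runs < 1 or self.cv_folds < 2 or self.bo_budget < 1:
            raise ValueError("n_runs >= 1, cv_folds >= 2, bo_budget >= 1 required")
        for name, spec in self.space.items():
            lo, hi = spec[0], spec[1]
            if hi < lo:
                raise ValueError(f"space bound for '{name}' is not ordered")


def reduced_screening_config(
    n_runs: int = 20, bo_budget: int = 10, base_seed: int = 0
) -> ScreeningConfig:
    """Scaled-down screen: reduced run count / optimization budget and a
    cheaper boosting budget, for single-CPU replication runs."""
    return ScreeningConfig(
        n_runs=n_runs,
        bo_budget=bo_budget,
        space=dict(REDUCED_SPACE),
        base_seed=base_seed,
        max_rounds=200,
        early_stopping_rounds=20,
    )
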