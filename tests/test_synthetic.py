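"""Generator contracts: determinism, marginal calibration, confounding
closed forms, and the annual-hazard outcome model."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy.stats import norm

from medscreen.config import ConfounderEffect, PlantedEffect, SimConfig
from medscreen.synthetic import (
    assign_outcomes,
    drug_catalog,
    generate_dispensing,
    generate_population,
    simulate_matched_cohort,
)
from tests.conftest import coarse_margins


def test_empty_population_is_allowed():
    cfg = SimConfig(seed=1, n_population=0, n_drug_classes=3)
    pop = generate_population(cfg)
    assert len(pop.subjects) == 0
    events = generate_dispensing(pop, cfg)
    assert len(events) == 0
    diagnoses = assign_outcomes(pop, events, cfg)
    assert len(diagnoses) == 0


def test_same_seed_reproduces_tables_exactly():
    cfg = SimConfig(seed=42, n_population=500, n_drug_classes=10,
                    baseline_annual_hazard=0.01)
    runs = []
    for _ in range(2):
        pop = generate_population(cfg)
        events = generate_dispensing(pop, cfg)
        diagnoses = assign_outcomes(pop, events, cfg)
        runs.append((pop.subjects, pop.comorbidities, pop.visits, events, diagnoses))
    for a, b in zip(*runs):
        assert_frame_equal(a, b)


def test_invalid_margin_rejected():
    margins = coarse_margins()
    margins["sex"] = {"male": 0.7, "female": 0.7}
    with pytest.raises(ValueError, match="sums to"):
        SimConfig(n_population=10, demographic_margins=margins)


def test_sex_margin_calibrated_at_cohort_scale():
    """Male fraction lands within 1% of the configured 48.8% at n=120k."""
    cfg = SimConfig(seed=5, n_population=120_000)
    pop = generate_population(cfg, include_visits=False)
    male = (pop.subjects["sex"] == "male").mean()
    assert abs(male - 0.488) < 0.01


def test_dispensing_prevalence_matches_configuration():
    """A 3.1% baseline class shows 3.1% +/- 0.5% empirical prevalence."""
    cfg = SimConfig(
        seed=7,
        n_population=120_000,
        n_drug_classes=1,
        prevalence_range=(0.031, 0.031),
        demographic_margins=coarse_margins(),
    )
    pop = generate_population(cfg, include_visits=False)
    events = generate_dispensing(pop, cfg)
    prevalence = events["subject_id"].nunique() / cfg.n_population
    assert abs(prevalence - 0.031) < 0.005


def test_zero_prevalence_class_never_dispensed():
    cfg = SimConfig(seed=3, n_population=300, n_drug_classes=4,
                    prevalence_range=(0.0, 0.0),
                    demographic_margins=coarse_margins())
    pop = generate_population(cfg, include_visits=False)
    events = generate_dispensing(pop, cfg)
    assert len(events) == 0


def test_confounded_exposure_matches_logistic_closed_form():
    """Exposure among comorbid subjects equals expit(logit(p0) + 1.0)."""
    p0 = 0.05
    cfg = SimConfig(
        seed=9,
        n_population=60_000,
        n_drug_classes=1,
        prevalence_range=(p0, p0),
        comorbidity_rates={"diabetes": 0.5},
        confounder_effects=[
            ConfounderEffect("diabetes", exposure_log_odds=1.0,
                             outcome_log_odds=0.0, affected_classes=(0,))
        ],
        demographic_margins=coarse_margins(),
    )
    pop = generate_population(cfg, include_visits=False)
    events = generate_dispensing(pop, cfg)
    comorbid = set(
        pop.comorbidities.loc[
            pop.comorbidities["condition"] == "diabetes", "subject_id"
        ]
    )
    exposed = set(events["subject_id"])
    n_com = len(comorbid)
    obs = len(comorbid & exposed) / n_com
    expected = 1 / (1 + np.exp(-(np.log(p0 / (1 - p0)) + 1.0)))
    tol = 3 * np.sqrt(expected * (1 - expected) / n_com)
    assert abs(obs - expected) < tol


def _case_noncase_prevalence(cfg):
    pop = generate_population(cfg, include_visits=False)
    events = generate_dispensing(pop, cfg)
    diagnoses = assign_outcomes(pop, events, cfg)
    cases = set(diagnoses.loc[diagnoses["condition"] == "crc", "subject_id"])
    catalog = drug_catalog(cfg)
    code = catalog["atc5"].iloc[0]
    exposed = set(events.loc[events["atc5"] == code, "subject_id"])
    n = cfg.n_population
    case_ids = np.array(sorted(cases))
    is_exposed = np.isin(np.arange(n), np.array(sorted(exposed)))
    is_case = np.isin(np.arange(n), case_ids)
    return is_exposed, is_case


def test_null_outcome_model_has_no_exposure_imbalance():
    """All ORs = 1: exposure prevalence equal among cases and non-cases
    (two-proportion z at alpha=0.01)."""
    cfg = SimConfig(
        seed=13,
        n_population=120_000,
        n_drug_classes=1,
        prevalence_range=(0.1, 0.1),
        baseline_annual_hazard=5e-3,
        demographic_margins=coarse_margins(),
    )
    is_exposed, is_case = _case_noncase_prevalence(cfg)
    p1 = is_exposed[is_case].mean()
    p0 = is_exposed[~is_case].mean()
    p = is_exposed.mean()
    se = np.sqrt(p * (1 - p) * (1 / is_case.sum() + 1 / (~is_case).sum()))
    assert abs(p1 - p0) / se < norm.ppf(1 - 0.01 / 2)


def test_doubling_hazard_doubles_case_count():
    base = dict(
        seed=17,
        n_population=60_000,
        n_drug_classes=1,
        prevalence_range=(0.05, 0.05),
        demographic_margins=coarse_margins(),
    )
    counts = []
    for hz in (2e-3, 4e-3):
        cfg = SimConfig(baseline_annual_hazard=hz, **base)
        pop = generate_population(cfg, include_visits=False)
        events = generate_dispensing(pop, cfg)
        diagnoses = assign_outcomes(pop, events, cfg)
        counts.append((diagnoses["condition"] == "crc").sum())
    ratio = counts[1] / counts[0]
    # Poisson tolerance: 3 SD of the ratio around 2
    tol = 3 * 2 * np.sqrt(1 / counts[0] + 1 / counts[1])
    assert abs(ratio - 2) < tol


def test_hazard_overflow_rejected():
    cfg = SimConfig(
        seed=1,
        n_population=50,
        n_drug_classes=2,
        baseline_annual_hazard=0.5,
        planted_effects=[PlantedEffect(0, 20.0)],
        demographic_margins=coarse_margins(),
    )
    pop = generate_population(cfg, include_visits=False)
    events = generate_dispensing(pop, cfg)
    with pytest.raises(ValueError, match="hazard"):
        assign_outcomes(pop, events, cfg)


def test_matched_cohort_case_exposure_odds():
    """Case exposure probability follows odds(p1) = OR * odds(p0)."""
    p0, orr = 0.2, 3.0
    coh = simulate_matched_cohort(
        n_sets=5000, ratio=1, prevalences=np.array([p0]), planted={0: orr}, seed=2
    )
    p1_expected = orr * p0 / (1 - p0) / (1 + orr * p0 / (1 - p0))
    p1 = coh.X[coh.y == 1, 0].mean()
    p0_obs = coh.X[coh.y == 0, 0].mean()
    assert abs(p1 - p1_expected) < 3 * np.sqrt(p1_expected * (1 - p1_expected) / 5000)
    assert abs(p0_obs - p0) < 3 * np.sqrt(p0 * (1 - p0) / 5000)


def test_matched_cohort_structure():
    coh = simulate_matched_cohort(n_sets=7, ratio=10, n_classes=5, seed=1)
    assert coh.X.shape == (77, 5)
    assert coh.y.sum() == 7
    df = coh.frame()
    assert df.groupby("set_id")["is_case"].sum().eq(1).all()
    assert len(coh.feature_names) == 5
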