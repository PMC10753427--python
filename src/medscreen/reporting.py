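"""End-to-end pipeline orchestration and the three standard report tables.

Table 1: demographics of matched cases vs controls (matched keys must show
identical percentage columns). Table 2: per-selected-class prevalence of use
among cases and controls with the screening consensus rates. Table 3:
adjusted odds ratios from the matched conditional-logistic model, sorted
descending. Percentages print to one decimal, ORs and CI bounds to two,
following the conventional case-control table layout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import medscreen
from medscreen import io as msio
from medscreen.cohort import apply_exclusions, ascertain_cases, density_match
from medscreen.conditional_logit import build_design, estimate_effects
from medscreen.config import ScreeningConfig, SimConfig
from medscreen.exposure import (
    build_covariates,
    build_exposure_matrix,
    exposure_features,
    filter_rare_drugs,
)
from medscreen.screening import (
    assess_interactions,
    consensus_select,
    results_frame,
    run_screening,
)
from medscreen.synthetic import (
    assign_outcomes,
    drug_catalog,
    generate_dispensing,
    generate_population,
)

logger = logging.getLogger(__name__)

DAY = np.timedelta64(1, "D")


@dataclass
class PipelineConfig:
    """Every stage parameter of the end-to-end run, with study defaults:
    1:10 matching with birth year +/-2, a 730-day exposure lag, the 0.1%
    rarity filter, and the 50-run screening configuration."""

    out_dir: str = "medscreen_out"
    data_dir: str | None = None  # None -> simulate into out_dir/data
    sim: SimConfig = field(default_factory=SimConfig)
    ratio: int = 10
    birth_tol: int = 2
    min_years: int = 3
    lag_days: int = 730
    min_frac: float = 0.001
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    joint_regression: bool = True
    allow_short_sets: bool = False
    seed: int = 0


def _pct(n: int, total: int) -> str:
    return f"{n} ({100 * n / total:.1f})" if total else "0 (0.0)"


def make_table1(
    subjects: pd.DataFrame,
    matched_sets: pd.DataFrame,
    visits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Demographic margins of matched cases and controls.

    Categorical rows give n (%) per role; continuous rows give mean (SD) of
    the sociodemographic band, follow-up weeks before index, age at index
    and (when visits are supplied) yearly physician-visit frequency.
    """
    members = matched_sets.merge(subjects, on="subject_id", how="left")
    rows = []
    groups = {r: members[members["role"] == r] for r in ("case", "control")}
    totals = {r: len(g) for r, g in groups.items()}
    for var in ("sex", "subpopulation", "district"):
        for level in sorted(members[var].dropna().unique()):
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "cases": _pct(
                        int((groups["case"][var] == level).sum()), totals["case"]
                    ),
                    "controls": _pct(
                        int((groups["control"][var] == level).sum()),
                        totals["control"],
                    ),
                }
            )

    def _mean_sd(series: pd.Series) -> str:
        return f"{series.mean():.1f} ({series.std(ddof=1):.1f})"

    for role, g in groups.items():
        g = g.copy()
        g["age_at_index"] = (
            pd.to_datetime(g["index_date"]).dt.year - g["birth_year"]
        )
        g["followup_weeks"] = (
            pd.to_datetime(g["index_date"]) - pd.to_datetime(g["enrollment_start"])
        ).dt.days / 7
        groups[role] = g
    for var in ("ses", "age_at_index", "followup_weeks"):
        rows.append(
            {
                "variable": var,
                "level": "mean_sd",
                "cases": _mean_sd(groups["case"][var]),
                "controls": _mean_sd(groups["control"][var]),
            }
        )
    if visits is not None and len(visits):
        counts = visits.groupby("subject_id").size()
        for role, g in groups.items():
            per_year = (
                counts.reindex(g["subject_id"], fill_value=0).to_numpy()
                / np.maximum(g["followup_weeks"].to_numpy() / 52.18, 1e-9)
            )
            g["visits_per_year"] = per_year
        rows.append(
            {
                "variable": "visits_per_year",
                "level": "mean_sd",
                "cases": _mean_sd(groups["case"]["visits_per_year"]),
                "controls": _mean_sd(groups["control"]["visits_per_year"]),
            }
        )
    return pd.DataFrame(rows)


def make_table2(matrix: pd.DataFrame, consensus: pd.DataFrame) -> pd.DataFrame:
    """Prevalence of use among cases/controls for consensus-examined classes,
    with the rate of runs associated and the rate of top-2.5% hits."""
    sel = consensus[consensus["selected"]].copy()
    if sel.empty:
        return pd.DataFrame(
            columns=[
                "atc5",
                "cases_n_pct",
                "controls_n_pct",
                "runs_associated_pct",
                "runs_top_2.5_pct",
            ]
        )
    cases = matrix[matrix["is_case"] == 1]
    controls = matrix[matrix["is_case"] == 0]
    rows = []
    for _, rec in sel.sort_values("association_rate", ascending=False).iterrows():
        feat = rec["feature"]
        rows.append(
            {
                "atc5": feat,
                "cases_n_pct": _pct(int(cases[feat].sum()), len(cases)),
                "controls_n_pct": _pct(int(controls[feat].sum()), len(controls)),
                "runs_associated_pct": round(100 * rec["association_rate"], 1),
                "runs_top_2.5_pct": round(100 * rec["top_q_rate"], 1),
            }
        )
    return pd.DataFrame(rows)


def make_table3(effects: pd.DataFrame) -> pd.DataFrame:
    """Adjusted odds ratios sorted descending, formatted OR (95% CI) and p."""
    out = effects.sort_values("or", ascending=False).reset_index(drop=True)
    return pd.DataFrame(
        {
            "atc5": out["feature"],
            "or_95ci": [
                f"{o:.2f} ({lo:.2f}-{hi:.2f})"
                for o, lo, hi in zip(out["or"], out["ci_low"], out["ci_high"])
            ],
            "p": [f"{p:.3f}" if p >= 0.001 else "<.001" for p in out["p"]],
        }
    )


def make_tables(
    subjects: pd.DataFrame,
    matched_sets: pd.DataFrame,
    matrix: pd.DataFrame,
    consensus: pd.DataFrame,
    effects: pd.DataFrame,
    visits: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    return {
        "table1": make_table1(subjects, matched_sets, visits),
        "table2": make_table2(matrix, consensus),
        "table3": make_table3(effects),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """simulate -> build-cohort -> build-exposure -> screen -> estimate ->
    report; writes every stage artifact plus a manifest that reproduces the
    run exactly."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if cfg.data_dir is None:
            pop = generate_population(cfg.sim)
            catalog = drug_catalog(cfg.sim)
            dispensing = generate_dispensing(pop, cfg.sim, catalog)
            diagnoses = assign_outcomes(pop, dispensing, cfg.sim, catalog)
            data_dir = msio.write_dataset(out / "data", pop, dispensing, diagnoses,
                                          catalog)
            tables = msio.read_dataset(data_dir)
        else:
            tables = msio.read_dataset(cfg.data_dir)

        stage = "build-cohort"
        cases = ascertain_cases(
            tables["diagnoses"], tables["subjects"], window=cfg.sim.study_window
        )
        eligible, ledger = apply_exclusions(
            cases, tables["diagnoses"], tables["enrollment"], min_years=cfg.min_years
        )
        matched = density_match(
            eligible,
            tables["subjects"],
            tables["enrollment"],
            tables["diagnoses"],
            ratio=cfg.ratio,
            birth_tol=cfg.birth_tol,
            min_years=cfg.min_years,
            seed=cfg.seed,
            allow_short_sets=cfg.allow_short_sets,
        )
        matched.to_csv(out / "matched_sets.csv", index=False)

        stage = "build-exposure"
        catalog_codes = (
            tables["catalog"]["atc5"].tolist() if "catalog" in tables else None
        )
        matrix = build_exposure_matrix(
            matched, tables["dispensing"], lag_days=cfg.lag_days,
            catalog=catalog_codes
        )
        matrix = filter_rare_drugs(matrix, min_frac=cfg.min_frac)
        covariates = build_covariates(
            matched,
            tables.get("comorbidities", pd.DataFrame(
                columns=["subject_id", "condition", "onset_date"])),
            tables.get("visits", pd.DataFrame(columns=["subject_id", "visit_date"])),
            tables["enrollment"],
            lag_days=cfg.lag_days,
        )
        msio.write_matrix(matrix, out / "exposure_matrix.parquet")
        covariates.to_csv(out / "covariates.csv", index=False)

        stage = "screen"
        feats = exposure_features(matrix)
        results = run_screening(
            matrix[feats].to_numpy(np.float32),
            matrix["is_case"].to_numpy(),
            cfg.screening,
            feature_names=feats,
        )
        results_frame(results).to_parquet(out / "run_results.parquet", index=False)
        consensus = consensus_select(results)
        consensus.to_csv(out / "consensus.csv", index=False)
        selected = consensus.loc[consensus["selected"], "feature"].tolist()
        if selected:
            report = assess_interactions(
                matrix[selected].to_numpy(np.float32),
                matrix["is_case"].to_numpy(),
                cfg.screening,
                feature_names=selected,
            )
        else:
            report = {"best_depth": None, "informative": None,
                      "note": "empty consensus"}
        with open(out / "interaction_report.json", "w") as fh:
            json.dump(report, fh, indent=2)

        stage = "estimate"
        if selected:
            design = build_design(matrix, covariates, selected)
            effects = estimate_effects(design, selected, joint=cfg.joint_regression)
        else:
            effects = pd.DataFrame(
                columns=["feature", "beta", "se", "or", "ci_low", "ci_high", "p"]
            )
        effects.to_csv(out / "effects.csv", index=False)

        stage = "report"
        tabs = make_tables(
            tables["subjects"], matched, matrix, consensus, effects,
            visits=tables.get("visits"),
        )
        for name, tab in tabs.items():
            tab.to_csv(out / f"{name}.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    manifest = {
        "package_version": medscreen.__version__,
        "seed": cfg.seed,
        "exclusion_ledger": ledger,
        "n_sets": int(matched["set_id"].nunique()),
        "n_selected": len(selected),
        "parameters": {
            "ratio": cfg.ratio,
            "birth_tol": cfg.birth_tol,
            "min_years": cfg.min_years,
            "lag_days": cfg.lag_days,
            "min_frac": cfg.min_frac,
            "screening": {
                "n_runs": cfg.screening.n_runs,
                "holdout_frac": cfg.screening.holdout_frac,
                "cv_folds": cfg.screening.cv_folds,
                "bo_budget": cfg.screening.bo_budget,
                "base_seed": cfg.screening.base_seed,
                "max_rounds": cfg.screening.max_rounds,
                "early_stopping_rounds": cfg.screening.early_stopping_rounds,
                "space": {k: list(v) for k, v in cfg.screening.space.items()},
            },
            "sim_seed": cfg.sim.seed,
            "n_population": cfg.sim.n_population,
            "n_drug_classes": cfg.sim.n_drug_classes,
            "joint_regression": cfg.joint_regression,
        },
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "out_dir": str(out),
        "ledger": ledger,
        "consensus": consensus,
        "effects": effects,
        "interaction_report": report,
        "tables": tabs,
        "manifest": manifest,
    }
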