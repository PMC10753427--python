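"""Case ascertainment, exclusions, and 1:10 density (risk-set) matching.

Cases are first colorectal-cancer diagnoses inside the study window at age
50 or younger; eligibility requires 3 years of continuous enrollment before
the index date and no IBD / hereditary-syndrome flag. Controls are sampled
uniformly without replacement from each case's risk set at the case's index
date: subjects enrolled for 3+ years, cancer-free on the index date, and
exactly matching on sex, residential district, sociodemographic band,
population subgroup and periphery band, with birth year within +/-2 years.
Risk-set semantics: a subject who later becomes a case is eligible as a
control before their own diagnosis. Each subject serves as a control in at
most one set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from medscreen.config import EXCLUSION_CONDITIONS, STUDY_END, STUDY_START

logger = logging.getLogger(__name__)

MATCH_KEYS = ("sex", "district", "subpopulation", "ses", "periphery")
DAY = np.timedelta64(1, "D")


class DataIntegrityError(ValueError):
    """A record references a subject absent from the subject table."""


class ShortRiskSetError(RuntimeError):
    """A case's risk set holds fewer candidates than the matching ratio."""


def _years_offset(dates: pd.Series | np.ndarray, years: int) -> np.ndarray:
    """Calendar-exact subtraction of whole years from dates."""
    s = pd.Series(pd.to_datetime(np.asarray(dates)))
    return (s - pd.offsets.DateOffset(years=years)).to_numpy()


def first_crc(diagnoses: pd.DataFrame) -> pd.DataFrame:
    crc = diagnoses[diagnoses["condition"] == "crc"]
    return (
        crc.sort_values("diagnosis_date", kind="stable")
        .groupby("subject_id", as_index=False)
        .first()
    )


def ascertain_cases(
    diagnoses: pd.DataFrame,
    subjects: pd.DataFrame,
    window: tuple = (STUDY_START, STUDY_END),
    max_age: int = 50,
) -> pd.DataFrame:
    """First in-window CRC diagnoses at age ``max_age`` or younger.

    Age at index is computed as index year minus birth year (matching, like
    the ascertainment itself, operates on birth years). Returns a frame with
    subject_id, index_date and age_at_index.
    """
    crc = first_crc(diagnoses)
    missing = set(crc["subject_id"]) - set(subjects["subject_id"])
    if missing:
        raise DataIntegrityError(
            f"{len(missing)} diagnosed subjects missing from subject table "
            f"(e.g. {sorted(missing)[:5]})"
        )
    lo, hi = (np.datetime64(d) for d in window)
    cases = crc.merge(
        subjects[["subject_id", "birth_year"]], on="subject_id", how="left"
    )
    idx = cases["diagnosis_date"].to_numpy().astype("datetime64[D]")
    in_window = (idx >= lo) & (idx < hi)
    age = pd.to_datetime(cases["diagnosis_date"]).dt.year - cases["birth_year"]
    keep = in_window & (age <= max_age)
    out = cases.loc[keep, ["subject_id", "diagnosis_date"]].rename(
        columns={"diagnosis_date": "index_date"}
    )
    out["age_at_index"] = age[keep].to_numpy()
    return out.sort_values(["index_date", "subject_id"], kind="stable").reset_index(
        drop=True
    )


def apply_exclusions(
    cases: pd.DataFrame,
    diagnoses: pd.DataFrame,
    enrollment: pd.DataFrame,
    min_years: int = 3,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop cases without continuous pre-index enrollment, then flagged cases.

    Rule order (each count recorded in the returned ledger):

    1. ``enrollment``: enrollment must start at least ``min_years`` calendar
       years before the index date and still cover it.
    2. ``flagged``: any IBD or hereditary-syndrome record for the subject.
    """
    ledger: dict[str, int] = {"ascertained": len(cases)}
    merged = cases.merge(enrollment, on="subject_id", how="left")
    cutoff = _years_offset(merged["index_date"], min_years)
    enrolled = (merged["enrollment_start"].to_numpy() <= cutoff) & (
        merged["enrollment_end"].to_numpy() >= merged["index_date"].to_numpy()
    )
    ledger["excluded_enrollment"] = int((~enrolled).sum())
    survivors = merged.loc[enrolled, cases.columns.tolist()]
    ledger["after_enrollment"] = len(survivors)

    flagged_ids = set(
        diagnoses.loc[
            diagnoses["condition"].isin(EXCLUSION_CONDITIONS), "subject_id"
        ]
    )
    is_flagged = survivors["subject_id"].isin(flagged_ids)
    ledger["excluded_flagged"] = int(is_flagged.sum())
    final = survivors.loc[~is_flagged].reset_index(drop=True)
    ledger["final"] = len(final)
    logger.info("case exclusion ledger: %s", ledger)
    return final, ledger


def risk_set(
    case: pd.Series,
    subjects: pd.DataFrame,
    enrollment: pd.DataFrame,
    diagnoses: pd.DataFrame,
    birth_tol: int = 2,
    min_years: int = 3,
) -> np.ndarray:
    """Exhaustively enumerate one case's eligible controls (reference path;
    `density_match` uses an indexed equivalent)."""
    idx = np.datetime64(case["index_date"], "D")
    merged = subjects.merge(enrollment, on="subject_id", how="left", suffixes=("", "_e"))
    crc = first_crc(diagnoses).set_index("subject_id")["diagnosis_date"]
    ok = np.ones(len(merged), dtype=bool)
    for key in MATCH_KEYS:
        ok &= (merged[key] == case[key]).to_numpy()
    ok &= (merged["birth_year"] - case["birth_year"]).abs().to_numpy() <= birth_tol
    cutoff = np.datetime64(
        pd.Timestamp(idx) - pd.offsets.DateOffset(years=min_years), "D"
    )
    ok &= merged["enrollment_start"].to_numpy().astype("datetime64[D]") <= cutoff
    ok &= merged["enrollment_end"].to_numpy().astype("datetime64[D]") >= idx
    crc_dates = crc.reindex(merged["subject_id"]).to_numpy().astype("datetime64[D]")
    ok &= np.isnat(crc_dates) | (crc_dates > idx)
    ok &= (merged["subject_id"] != case["subject_id"]).to_numpy()
    return merged.loc[ok, "subject_id"].to_numpy()


@dataclass
class MatchingReport:
    n_sets: int
    n_controls: int
    short_sets: list[int]


def density_match(
    cases: pd.DataFrame,
    subjects: pd.DataFrame,
    enrollment: pd.DataFrame,
    diagnoses: pd.DataFrame,
    ratio: int = 10,
    birth_tol: int = 2,
    min_years: int = 3,
    seed: int = 0,
    allow_short_sets: bool = False,
) -> pd.DataFrame:
    """Sample ``ratio`` controls per case from its risk set at the index date.

    Cases are processed in index-date order; sampling is uniform without
    replacement and reproducible from ``seed``. A control is used in at most
    one set. A risk set smaller than ``ratio`` raises ShortRiskSetError
    unless ``allow_short_sets`` is set, in which case the set is emitted
    short with a warning.

    Returns a long frame: set_id, subject_id, role ('case'/'control'),
    index_date.
    """
    rng = np.random.default_rng(seed)
    merged = subjects.merge(enrollment, on="subject_id", how="left", suffixes=("", "_e"))
    crc = first_crc(diagnoses).set_index("subject_id")["diagnosis_date"]
    crc_dates = (
        crc.reindex(merged["subject_id"]).to_numpy().astype("datetime64[D]")
    )

    sid = merged["subject_id"].to_numpy()
    by = merged["birth_year"].to_numpy()
    e_start = merged["enrollment_start"].to_numpy().astype("datetime64[D]")
    e_end = merged["enrollment_end"].to_numpy().astype("datetime64[D]")

    cells: dict[tuple, np.ndarray] = {
        key: grp.to_numpy()
        for key, grp in pd.Series(np.arange(len(merged))).groupby(
            [merged[k] for k in MATCH_KEYS]
        )
    }

    used = np.zeros(len(merged), dtype=bool)
    pos_of = pd.Series(np.arange(len(merged)), index=sid)
    keyed = cases.merge(
        subjects[["subject_id", "birth_year", *MATCH_KEYS]],
        on="subject_id",
        how="left",
    )
    ordered = keyed.sort_values(["index_date", "subject_id"], kind="stable")
    rows: list[pd.DataFrame] = []
    short_sets: list[int] = []
    for set_id, (_, case) in enumerate(ordered.iterrows()):
        idx = np.datetime64(case["index_date"], "D")
        cutoff = np.datetime64(
            pd.Timestamp(idx) - pd.offsets.DateOffset(years=min_years), "D"
        )
        key = tuple(case[k] for k in MATCH_KEYS)
        pool = cells.get(key, np.empty(0, dtype=np.int64))
        if len(pool):
            ok = (
                (np.abs(by[pool] - case["birth_year"]) <= birth_tol)
                & (e_start[pool] <= cutoff)
                & (e_end[pool] >= idx)
                & (np.isnat(crc_dates[pool]) | (crc_dates[pool] > idx))
                & (sid[pool] != case["subject_id"])
                & ~used[pool]
            )
            pool = pool[ok]
        if len(pool) < ratio:
            if not allow_short_sets:
                raise ShortRiskSetError(
                    f"case {case['subject_id']} at {idx}: risk set has "
                    f"{len(pool)} candidates, need {ratio}"
                )
            logger.warning(
                "case %s: short risk set (%d < %d)",
                case["subject_id"],
                len(pool),
                ratio,
            )
            short_sets.append(set_id)
            chosen = pool
        else:
            chosen = pool[rng.choice(len(pool), size=ratio, replace=False)]
        used[chosen] = True
        used[pos_of[case["subject_id"]]] = True  # a case never re-enters as control
        rows.append(
            pd.DataFrame(
                {
                    "set_id": set_id,
                    "subject_id": np.concatenate(
                        [[case["subject_id"]], sid[chosen]]
                    ),
                    "role": ["case"] + ["control"] * len(chosen),
                    "index_date": idx,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["set_id", "subject_id", "role", "index_date"])
    out = pd.concat(rows, ignore_index=True)
    logger.info(
        "matched %d sets, %d controls (%d short sets)",
        out["set_id"].nunique(),
        int((out["role"] == "control").sum()),
        len(short_sets),
    )
    return out
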