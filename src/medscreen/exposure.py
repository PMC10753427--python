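"""Lagged binary exposure matrix and adjustment covariates.

Exposure to a medication class is "ever dispensed strictly before the index
date minus a 2-year lag"; events inside the lag window are discarded to
limit reverse causation (prodromal prescribing). Controls inherit their
set's shared index date. Classes used by fewer than 0.1% of the matched
cohort are dropped. Covariates: chronic-comorbidity indicators (onset before
index) and the physician-visit rate, with both the visit count and the
follow-up time truncated 2 years before index.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from medscreen.cohort import DataIntegrityError

logger = logging.getLogger(__name__)

DAY = np.timedelta64(1, "D")
DAYS_PER_MONTH = 365.25 / 12

META_COLS = ["set_id", "subject_id", "is_case"]


def _member_frame(matched_sets: pd.DataFrame) -> pd.DataFrame:
    members = matched_sets[["set_id", "subject_id", "role", "index_date"]].copy()
    members["is_case"] = (members["role"] == "case").astype(np.int8)
    return members.drop(columns="role")


def build_exposure_matrix(
    matched_sets: pd.DataFrame,
    dispensing: pd.DataFrame,
    lag_days: int = 730,
    catalog: list[str] | None = None,
    known_subjects: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Binary members x classes matrix of lagged ever-exposure.

    A cell is 1 iff the member has at least one dispensing of the class dated
    strictly before ``index_date - lag_days``. Row order follows
    ``matched_sets`` (set_id, case first); the leading columns are set_id,
    subject_id and is_case, the rest one column per ATC level-5 code. With
    ``catalog`` given, all listed codes appear as columns (zero-filled when
    unused); otherwise columns are the codes observed in ``dispensing``.
    ``known_subjects`` (the full subject universe, not just matched members)
    enables an integrity check on the dispensing table.
    """
    members = _member_frame(matched_sets)
    if known_subjects is not None:
        unknown = set(dispensing["subject_id"]) - set(np.asarray(known_subjects))
        if unknown:
            raise DataIntegrityError(
                f"{len(unknown)} dispensing records reference unknown subjects "
                f"(e.g. {sorted(unknown)[:5]})"
            )
    events = dispensing.merge(
        members[["set_id", "subject_id", "index_date"]], on="subject_id", how="inner"
    )
    cutoff = events["index_date"].to_numpy().astype(
        "datetime64[D]"
    ) - lag_days * DAY
    events = events[events["dispense_date"].to_numpy().astype("datetime64[D]") < cutoff]

    codes = (
        list(catalog)
        if catalog is not None
        else sorted(dispensing["atc5"].unique().tolist())
    )
    code_pos = {c: j for j, c in enumerate(codes)}
    row_key = members.set_index(["set_id", "subject_id"]).index
    row_pos = {k: i for i, k in enumerate(row_key)}
    mat = np.zeros((len(members), len(codes)), dtype=np.uint8)
    if len(events):
        ridx = [
            row_pos[k]
            for k in zip(events["set_id"].to_numpy(), events["subject_id"].to_numpy())
        ]
        cidx = events["atc5"].map(code_pos)
        if cidx.isna().any():
            bad = events.loc[cidx.isna(), "atc5"].unique()
            raise DataIntegrityError(f"dispensing codes outside catalog: {bad[:5]}")
        mat[ridx, cidx.to_numpy(dtype=np.int64)] = 1
    out = pd.DataFrame(mat, columns=codes)
    for col in reversed(META_COLS):
        out.insert(0, col, members[col].to_numpy())
    return out


def exposure_features(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in META_COLS]


def filter_rare_drugs(matrix: pd.DataFrame, min_frac: float = 0.001) -> pd.DataFrame:
    """Drop classes used by fewer than ``ceil(min_frac * N)`` cohort members.

    N counts all matched-set members (cases plus controls). The threshold and
    the dropped classes are logged; ``min_frac=0`` is the identity.
    """
    n = len(matrix)
    threshold = math.ceil(min_frac * n)
    codes = exposure_features(matrix)
    users = matrix[codes].sum(axis=0)
    keep = [c for c in codes if users[c] >= threshold]
    dropped = [c for c in codes if users[c] < threshold]
    logger.info(
        "rarity filter: threshold %d users of N=%d; dropped %d of %d classes",
        threshold,
        n,
        len(dropped),
        len(codes),
    )
    if dropped:
        logger.debug("dropped classes: %s", dropped)
    return matrix[META_COLS + keep]


def build_covariates(
    matched_sets: pd.DataFrame,
    comorbidities: pd.DataFrame,
    visits: pd.DataFrame,
    enrollment: pd.DataFrame,
    lag_days: int = 730,
    conditions: tuple[str, ...] = (
        "diabetes",
        "hypertension",
        "cardiovascular",
        "excess_weight",
    ),
) -> pd.DataFrame:
    """Per-member comorbidity indicators and lag-truncated visit rate.

    Comorbidity indicators are 1 iff onset is strictly before the member's
    index date. The visit rate divides visits dated strictly before
    ``index_date - lag_days`` by the months from enrollment start to that
    cutoff. Members whose enrollment starts on/after the cutoff get a missing
    visit_rate and are flagged (column ``flagged``); downstream stages must
    drop or impute them.
    """
    members = _member_frame(matched_sets)
    cutoff = (
        members["index_date"].to_numpy().astype("datetime64[D]") - lag_days * DAY
    )
    out = members[META_COLS].copy()

    onset_lookup = {
        cond: grp.set_index("subject_id")["onset_date"]
        for cond, grp in comorbidities.groupby("condition")
    }
    index_dates = members["index_date"].to_numpy().astype("datetime64[D]")
    for cond in conditions:
        onsets = (
            onset_lookup[cond].reindex(members["subject_id"]).to_numpy()
            if cond in onset_lookup
            else np.full(len(members), np.datetime64("NaT"))
        ).astype("datetime64[D]")
        out[cond] = ((~np.isnat(onsets)) & (onsets < index_dates)).astype(np.int8)

    enr = enrollment.set_index("subject_id")["enrollment_start"]
    start = enr.reindex(members["subject_id"]).to_numpy().astype("datetime64[D]")
    if np.isnat(start).any():
        raise DataIntegrityError("matched member missing from enrollment table")
    followup_months = ((cutoff - start) / DAY).astype(float) / DAYS_PER_MONTH

    v = visits.merge(
        members[["set_id", "subject_id"]].assign(cutoff=cutoff),
        on="subject_id",
        how="inner",
    )
    v = v[v["visit_date"].to_numpy().astype("datetime64[D]") < v["cutoff"].to_numpy()]
    counts = (
        v.groupby(["set_id", "subject_id"]).size()
        if len(v)
        else pd.Series(dtype=np.int64)
    )
    key = pd.MultiIndex.from_frame(members[["set_id", "subject_id"]])
    n_visits = counts.reindex(key, fill_value=0).to_numpy(dtype=float)

    valid = followup_months > 0
    rate = np.full(len(members), np.nan)
    rate[valid] = n_visits[valid] / followup_months[valid]
    out["visit_rate"] = rate
    out["flagged"] = (~valid).astype(np.int8)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning(
            "%d members have non-positive lagged follow-up; visit_rate set missing",
            n_bad,
        )
    return out
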