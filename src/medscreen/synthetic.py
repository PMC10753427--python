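"""Synthetic EMR dispensing-data generator.

Emulates the statistical structure of a dynamic health-provider cohort used
for matched case-control medication screening: demographics drawn from
configurable margins, per-subject enrollment spans, a long-tailed catalog of
ATC level-5 medication classes, time-stamped pharmacy dispensing with
optional comorbidity-driven confounding by indication, physician-visit
streams (a surveillance proxy), and a discrete annual-hazard outcome model
with planted conditional effects.

Two generators are provided:

* the forward cohort generator (`generate_population` -> `generate_dispensing`
  -> `assign_outcomes`), which produces raw tables for the full pipeline and
  genuinely exercises risk-set matching (risk sets change over calendar
  time); and
* `simulate_matched_cohort`, a retrospective generator that draws exposure
  directly within 1:M matched sets at a prescribed conditional odds ratio —
  the standard device for calibration studies of the conditional-logistic
  estimator and the screening stage.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from medscreen.config import COMORBIDITIES, SimConfig

DAY = np.timedelta64(1, "D")
LAG_DAYS = 730
_STAGE = {"population": 1, "catalog": 2, "dispensing": 3, "outcomes": 4, "visits": 5}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STAGE[stage]])


def _uniform_dates(
    rng: np.random.Generator, start: np.ndarray, end: np.ndarray
) -> np.ndarray:
    """One uniform date per row in the half-open span [start, end)."""
    span = np.maximum((end - start) / DAY, 1).astype(np.int64)
    offs = (rng.random(len(span)) * span).astype(np.int64)
    return start + offs * DAY


@dataclass
class Population:
    """Output of `generate_population`: flat subject table plus long-format
    comorbidity-onset and physician-visit tables."""

    subjects: pd.DataFrame
    comorbidities: pd.DataFrame
    visits: pd.DataFrame

    @property
    def enrollment(self) -> pd.DataFrame:
        return self.subjects[["subject_id", "enrollment_start", "enrollment_end"]]


def generate_population(cfg: SimConfig, include_visits: bool = True) -> Population:
    """Draw the dynamic cohort: demographics, enrollment spans, chronic
    comorbidity onsets and (optionally) physician-visit events.

    Subject attributes are drawn independently from ``cfg.demographic_margins``.
    Enrollment starts are uniform over 1995-2005; 90% of subjects remain
    enrolled through the study end, the rest disenroll early (so the 3-year
    continuous-enrollment filter and risk-set eligibility have bite).
    Visits form a homogeneous per-subject Poisson stream at the subject's
    Gamma-distributed monthly rate.
    """
    rng = _rng(cfg.seed, "population")
    n = cfg.n_population
    cols: dict[str, np.ndarray] = {"subject_id": np.arange(n, dtype=np.int64)}
    for key, margin in cfg.demographic_margins.items():
        cats = np.asarray(list(margin.keys()))
        probs = np.asarray(list(margin.values()), dtype=float)
        cols[key] = cats[rng.choice(len(cats), size=n, p=probs / probs.sum())]
    cols["ses"] = cols.pop("ses").astype(np.int64)
    cols["birth_year"] = cols.pop("birth_year").astype(np.int64)

    start_lo, start_hi = np.datetime64("1995-01-01"), np.datetime64("2006-01-01")
    starts = _uniform_dates(
        rng, np.full(n, start_lo), np.full(n, start_hi)
    )
    ends = np.full(n, cfg.study_window[1])
    early = rng.random(n) < 0.10
    span_days = (rng.uniform(0.5, 10.0, size=n) * 365.25).astype(np.int64)
    ends[early] = np.minimum(ends[early], starts[early] + span_days[early] * DAY)
    cols["enrollment_start"] = starts
    cols["enrollment_end"] = ends

    shape, scale = cfg.visit_rate_gamma
    cols["visit_rate"] = rng.gamma(shape, scale, size=n)
    subjects = pd.DataFrame(cols)

    como_frames = []
    for cond in COMORBIDITIES:
        rate = cfg.comorbidity_rates.get(cond, 0.0)
        hit = np.flatnonzero(rng.random(n) < rate)
        if len(hit) == 0:
            continue
        onsets = _uniform_dates(rng, starts[hit], ends[hit])
        como_frames.append(
            pd.DataFrame(
                {"subject_id": hit, "condition": cond, "onset_date": onsets}
            )
        )
    comorbidities = (
        pd.concat(como_frames, ignore_index=True)
        if como_frames
        else pd.DataFrame(columns=["subject_id", "condition", "onset_date"])
    )

    if include_visits:
        vrng = _rng(cfg.seed, "visits")
        months = ((ends - starts) / DAY).astype(float) / 30.4375
        counts = vrng.poisson(subjects["visit_rate"].to_numpy() * months)
        sid = np.repeat(subjects["subject_id"].to_numpy(), counts)
        vdates = _uniform_dates(vrng, np.repeat(starts, counts), np.repeat(ends, counts))
        visits = pd.DataFrame({"subject_id": sid, "visit_date": vdates})
    else:
        visits = pd.DataFrame(columns=["subject_id", "visit_date"])
    return Population(subjects=subjects, comorbidities=comorbidities, visits=visits)


def drug_catalog(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic ATC level-5 catalog: 7-character lower-case codes
    (anatomical letter, 2-digit group, 2-letter subgroup, 2-digit substance)
    with log-uniform baseline ever-exposure prevalences."""
    rng = _rng(cfg.seed, "catalog")
    n = cfg.n_drug_classes
    letters = np.asarray(list(string.ascii_lowercase))
    seen: set[str] = set()
    codes: list[str] = []
    while len(codes) < n:
        code = (
            rng.choice(letters)
            + f"{rng.integers(1, 17):02d}"
            + rng.choice(letters)
            + rng.choice(letters)
            + f"{rng.integers(1, 100):02d}"
        )
        if code not in seen:
            seen.add(code)
            codes.append(code)
    lo, hi = cfg.prevalence_range
    if hi <= 0:
        prev = np.zeros(n)
    else:
        prev = np.exp(rng.uniform(np.log(max(lo, 1e-12)), np.log(hi), size=n))
    return pd.DataFrame(
        {"class_id": np.arange(n), "atc5": codes, "baseline_prevalence": prev}
    )


def generate_dispensing(
    population: Population, cfg: SimConfig, catalog: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Draw per-subject ever-exposure for every medication class and stamp
    dispensing dates.

    Ever-exposure for class j is Bernoulli with
    ``logit = logit(baseline_prevalence_j) + sum of comorbidity exposure
    log-odds`` over configured confounders affecting j that the subject
    carries. Exposed subjects receive one dispensing uniform over their
    enrollment and, with probability ``cfg.extra_recent_event_prob``, an
    additional dispensing inside the final 2 years of enrollment — events the
    downstream lag filter must discard.
    """
    if catalog is None:
        catalog = drug_catalog(cfg)
    for eff in cfg.planted_effects:
        if eff.class_id not in set(catalog["class_id"]):
            raise ValueError(f"planted class_id {eff.class_id} not in catalog")

    rng = _rng(cfg.seed, "dispensing")
    subj = population.subjects
    n = len(subj)
    starts = subj["enrollment_start"].to_numpy()
    ends = subj["enrollment_end"].to_numpy()

    has_cond: dict[str, np.ndarray] = {}
    if len(population.comorbidities):
        for cond, grp in population.comorbidities.groupby("condition"):
            mask = np.zeros(n, dtype=bool)
            mask[grp["subject_id"].to_numpy()] = True
            has_cond[cond] = mask

    shift = {int(c): np.zeros(n) for c in catalog["class_id"]}
    for eff in cfg.confounder_effects:
        mask = has_cond.get(eff.condition)
        if mask is None:
            continue
        for cid in eff.affected_classes:
            shift[int(cid)] = shift[int(cid)] + eff.exposure_log_odds * mask

    frames = []
    codes = catalog["atc5"].to_numpy()
    prevs = catalog["baseline_prevalence"].to_numpy()
    for cid, code, p0 in zip(catalog["class_id"], codes, prevs):
        if p0 <= 0:
            continue
        logit = np.log(p0 / (1 - p0)) + shift[int(cid)]
        p = 1.0 / (1.0 + np.exp(-logit))
        exposed = np.flatnonzero(rng.random(n) < p)
        if len(exposed) == 0:
            continue
        d1 = _uniform_dates(rng, starts[exposed], ends[exposed])
        extra = exposed[rng.random(len(exposed)) < cfg.extra_recent_event_prob]
        parts = [pd.DataFrame({"subject_id": exposed, "atc5": code, "dispense_date": d1})]
        if len(extra):
            lag_lo = np.maximum(starts[extra], ends[extra] - LAG_DAYS * DAY)
            d2 = _uniform_dates(rng, lag_lo, ends[extra])
            parts.append(
                pd.DataFrame({"subject_id": extra, "atc5": code, "dispense_date": d2})
            )
        frames.append(pd.concat(parts, ignore_index=True))
    if not frames:
        return pd.DataFrame(columns=["subject_id", "atc5", "dispense_date"])
    events = pd.concat(frames, ignore_index=True)
    return events.sort_values(
        ["subject_id", "atc5", "dispense_date"], kind="stable"
    ).reset_index(drop=True)


def assign_outcomes(
    population: Population,
    events: pd.DataFrame,
    cfg: SimConfig,
    catalog: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the discrete annual-hazard outcome model over the study window.

    For each enrolled, not-yet-diagnosed subject and calendar year starting
    at t, the diagnosis probability is

        baseline_annual_hazard * exp( sum_j log(OR_j) * [exposed before t-2y]
                                      + sum_c gamma_c * [onset_c before t] )

    with j over planted classes and c over configured outcome confounders.
    The 2-year lag in the hazard matches the downstream exposure lag, so
    planted conditional odds ratios are recoverable. First diagnoses only.
    IBD and hereditary-syndrome flags are drawn independently at the
    configured lifetime rates (they drive exclusions, not the hazard).
    """
    if catalog is None:
        catalog = drug_catalog(cfg)
    rng = _rng(cfg.seed, "outcomes")
    subj = population.subjects
    n = len(subj)
    starts = subj["enrollment_start"].to_numpy()
    ends = subj["enrollment_end"].to_numpy()

    code_of = dict(zip(catalog["class_id"], catalog["atc5"]))
    first_event: dict[int, np.ndarray] = {}
    for eff in cfg.planted_effects:
        code = code_of[eff.class_id]
        sub = events[events["atc5"] == code]
        arr = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
        if len(sub):
            firsts = sub.groupby("subject_id")["dispense_date"].min()
            arr[firsts.index.to_numpy()] = firsts.to_numpy().astype("datetime64[D]")
        first_event[eff.class_id] = arr

    onset_of: dict[str, np.ndarray] = {}
    for eff in cfg.confounder_effects:
        sub = population.comorbidities[
            population.comorbidities["condition"] == eff.condition
        ]
        arr = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
        if len(sub):
            arr[sub["subject_id"].to_numpy()] = (
                sub["onset_date"].to_numpy().astype("datetime64[D]")
            )
        onset_of[eff.condition] = arr

    max_lhr = sum(abs(np.log(e.odds_ratio)) for e in cfg.planted_effects) + sum(
        max(e.outcome_log_odds, 0.0) for e in cfg.confounder_effects
    )
    if cfg.baseline_annual_hazard * np.exp(max_lhr) >= 1.0:
        raise ValueError(
            "annual hazard can exceed 1 under the configured effects; "
            "reduce baseline_annual_hazard or effect sizes"
        )

    win_start, win_end = cfg.study_window
    years = np.arange(
        win_start.astype("datetime64[Y]").astype(int) + 1970,
        win_end.astype("datetime64[Y]").astype(int) + 1970,
    )
    diagnosed = np.zeros(n, dtype=bool)
    diag_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    for year in years:
        t = np.datetime64(f"{year}-01-01")
        t_next = np.datetime64(f"{year + 1}-01-01")
        at_risk = (~diagnosed) & (starts <= t) & (ends > t)
        if not at_risk.any():
            continue
        log_hr = np.zeros(n)
        cutoff = t - LAG_DAYS * DAY
        for eff in cfg.planted_effects:
            fe = first_event[eff.class_id]
            log_hr += np.log(eff.odds_ratio) * (
                (~np.isnat(fe)) & (fe < cutoff)
            )
        for eff in cfg.confounder_effects:
            on = onset_of[eff.condition]
            log_hr += eff.outcome_log_odds * ((~np.isnat(on)) & (on < t))
        hazard = cfg.baseline_annual_hazard * np.exp(log_hr)
        hit = at_risk & (rng.random(n) < hazard)
        idx = np.flatnonzero(hit)
        if len(idx):
            diag_date[idx] = _uniform_dates(
                rng, np.full(len(idx), t), np.full(len(idx), t_next)
            )
            diagnosed[idx] = True

    frames = []
    crc = np.flatnonzero(diagnosed)
    if len(crc):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": crc,
                    "condition": "crc",
                    "diagnosis_date": diag_date[crc],
                }
            )
        )
    for cond in ("ibd", "hereditary_syndrome"):
        rate = cfg.comorbidity_rates.get(cond, 0.0)
        hit = np.flatnonzero(rng.random(n) < rate)
        if len(hit):
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": hit,
                        "condition": cond,
                        "diagnosis_date": _uniform_dates(rng, starts[hit], ends[hit]),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["subject_id", "condition", "diagnosis_date"])
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["subject_id", "condition"], kind="stable")
        .reset_index(drop=True)
    )


@dataclass
class MatchedCohort:
    """Exposure matrix of a simulated matched case-control sample.

    Rows are grouped by matched set (case first, then its controls); ``X`` is
    the binary subjects x classes ever-exposure matrix, ``y`` the case
    indicator, ``set_id`` the matched-set label.
    """

    X: np.ndarray
    y: np.ndarray
    set_id: np.ndarray
    feature_names: list[str]
    prevalences: np.ndarray
    planted: dict[int, float] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "is_case", self.y)
        df.insert(0, "set_id", self.set_id)
        return df


def simulate_matched_cohort(
    n_sets: int = 941,
    ratio: int = 10,
    n_classes: int = 800,
    prevalences: np.ndarray | None = None,
    planted: dict[int, float] | None = None,
    seed: int = 0,
    prevalence_range: tuple[float, float] = (0.0005, 0.35),
) -> MatchedCohort:
    """Draw binary exposure directly within 1:`ratio` matched sets at
    prescribed conditional odds ratios.

    Within every set, each control's exposure to class j is Bernoulli(p0_j)
    (the control prevalence) and the case's exposure is Bernoulli(p1_j) with
    odds(p1_j) = OR_j * odds(p0_j); OR_j = 1 for unplanted classes. The
    conditional-logistic estimator is consistent for log(OR_j) under this
    mechanism, which makes the generator the reference instrument for
    estimator-calibration and screening-power studies.
    """
    rng = np.random.default_rng([seed, 6])
    if prevalences is None:
        lo, hi = prevalence_range
        prevalences = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_classes))
    else:
        prevalences = np.asarray(prevalences, dtype=float)
        n_classes = len(prevalences)
    planted = dict(planted or {})
    for cid in planted:
        if not 0 <= cid < n_classes:
            raise ValueError(f"planted class_id {cid} out of range")

    p_case = prevalences.copy()
    for cid, orr in planted.items():
        odds = orr * prevalences[cid] / (1 - prevalences[cid])
        p_case[cid] = odds / (1 + odds)

    m = ratio + 1
    n_rows = n_sets * m
    y = np.zeros(n_rows, dtype=np.int8)
    y[::m] = 1
    set_id = np.repeat(np.arange(n_sets), m)
    p_row = np.where(y[:, None] == 1, p_case[None, :], prevalences[None, :])
    X = (rng.random((n_rows, n_classes)) < p_row).astype(np.uint8)

    cat_cfg = SimConfig(seed=seed, n_drug_classes=n_classes,
                        prevalence_range=prevalence_range)
    names = drug_catalog(cat_cfg)["atc5"].tolist()
    return MatchedCohort(
        X=X,
        y=y,
        set_id=set_id,
        feature_names=names,
        prevalences=prevalences,
        planted=planted,
    )


def plant_case_registry(
    population: Population,
    n_cases: int,
    seed: int = 0,
    n_short_enrollment: int = 0,
    n_flagged: int = 0,
    index_window: tuple[str, str] = ("2008-01-01", "2016-01-01"),
    max_age: int = 50,
    min_years: int = 3,
    min_pool: int = 0,
) -> pd.DataFrame:
    """Plant a CRC registry with known composition into a generated population.

    Produces exactly ``n_cases`` first-CRC diagnoses inside ``index_window``
    at ages <= ``max_age``, of which ``n_short_enrollment`` have less than
    ``min_years`` of enrollment before their index date (so the
    continuous-enrollment filter removes exactly that many) and ``n_flagged``
    of the remainder carry an IBD flag. With ``min_pool`` > 0, fully-enrolled
    case subjects are restricted to matching-key cells that hold at least
    that many exactly-matching candidate controls, guaranteeing an ample risk
    set for 1:10 matching.

    Returns a diagnoses table (crc + ibd rows) ready for case ascertainment.
    """
    rng = np.random.default_rng([seed, 7])
    subj = population.subjects
    win_lo, win_hi = (np.datetime64(d) for d in index_window)
    starts = subj["enrollment_start"].to_numpy()
    ends = subj["enrollment_end"].to_numpy()
    by = subj["birth_year"].to_numpy()
    # age at index uses index year - birth year; being under the cap at the
    # window's last year keeps any planted date valid
    young = by >= (win_hi.astype("datetime64[Y]").astype(int) + 1970) - max_age

    three_y = np.timedelta64(int(round(min_years * 365.25)), "D")
    margin = np.timedelta64(40, "D")
    long_ok = young & (starts + three_y + margin <= win_lo) & (ends >= win_hi)

    if min_pool > 0:
        keys = ["sex", "district", "subpopulation", "ses", "periphery"]
        cand = subj.loc[long_ok | ((starts + three_y <= win_lo) & (ends >= win_hi))]
        counts = cand.groupby(keys + ["birth_year"]).size()
        pool = np.zeros(len(subj), dtype=np.int64)
        cell = pd.MultiIndex.from_frame(subj[keys + ["birth_year"]])
        for dy in range(-2, 3):
            shifted = pd.MultiIndex.from_arrays(
                [subj[k] for k in keys] + [subj["birth_year"] + dy]
            )
            pool += counts.reindex(shifted, fill_value=0).to_numpy()
        del cell
        long_ok &= pool - 1 >= min_pool

    # a "short" case's index sits inside its first min_years of enrollment
    short_hi = np.minimum.reduce(
        [starts + three_y - margin, np.full(len(subj), win_hi), ends]
    )
    short_lo = np.maximum(starts + margin, win_lo)
    short_ok = young & (short_hi > short_lo) & ~long_ok

    n_long = n_cases - n_short_enrollment
    long_ids = np.flatnonzero(long_ok)
    short_ids = np.flatnonzero(short_ok)
    if len(long_ids) < n_long or len(short_ids) < n_short_enrollment:
        raise ValueError(
            f"population too small to plant {n_cases} cases "
            f"({len(long_ids)} long-enrolled / {len(short_ids)} short-enrolled "
            "candidates available)"
        )
    long_pick = rng.choice(long_ids, size=n_long, replace=False)
    short_pick = rng.choice(short_ids, size=n_short_enrollment, replace=False)

    long_dates = _uniform_dates(
        rng, np.full(n_long, win_lo), np.full(n_long, win_hi)
    )
    sl = short_lo[short_pick]
    sh = short_hi[short_pick]
    short_dates = _uniform_dates(rng, sl, sh)

    frames = [
        pd.DataFrame(
            {
                "subject_id": np.concatenate([long_pick, short_pick]),
                "condition": "crc",
                "diagnosis_date": np.concatenate([long_dates, short_dates]),
            }
        )
    ]
    if n_flagged:
        if n_flagged > n_long:
            raise ValueError("n_flagged exceeds the fully-enrolled case count")
        flagged = rng.choice(long_pick, size=n_flagged, replace=False)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": flagged,
                    "condition": "ibd",
                    "diagnosis_date": starts[flagged] + np.timedelta64(30, "D"),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
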