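"""Shared fixtures: compact populations with coarse demographic margins so
risk sets stay ample at small n, and hand-sized matched-set frames."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from medscreen.config import SimConfig


def coarse_margins() -> dict:
    """Low-cardinality margins: ~8 matching cells, so a few thousand
    subjects give every case an ample risk set."""
    years = list(range(1962, 1983))
    return {
        "sex": {"male": 0.5, "female": 0.5},
        "district": {"north": 0.5, "south": 0.5},
        "subpopulation": {"secular": 1.0},
        "ses": {5: 0.5, 6: 0.5},
        "periphery": {"central": 1.0},
        "birth_year": {y: 1.0 / len(years) for y in years},
    }


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    return SimConfig(
        seed=11,
        n_population=4000,
        n_drug_classes=20,
        demographic_margins=coarse_margins(),
    )


@pytest.fixture(scope="session")
def small_population(small_sim_config):
    from medscreen.synthetic import generate_population

    return generate_population(small_sim_config)


def toy_subjects(rows: list[dict]) -> pd.DataFrame:
    """Build a subject table from terse dicts, filling constant match keys."""
    defaults = dict(
        sex="female",
        district="north",
        subpopulation="secular",
        ses=5,
        periphery="central",
        birth_year=1970,
        enrollment_start=np.datetime64("1998-01-01"),
        enrollment_end=np.datetime64("2020-01-01"),
        visit_rate=0.5,
    )
    out = []
    for i, row in enumerate(rows):
        rec = {"subject_id": i, **defaults, **row}
        out.append(rec)
    df = pd.DataFrame(out)
    for col in ("enrollment_start", "enrollment_end"):
        df[col] = pd.to_datetime(df[col])
    return df


def matched_frame(n_sets: int, ratio: int, index_date="2012-06-01") -> pd.DataFrame:
    """Matched-set long frame with synthetic subject ids (case first)."""
    rows = []
    sid = 0
    for s in range(n_sets):
        for j in range(ratio + 1):
            rows.append(
                {
                    "set_id": s,
                    "subject_id": sid,
                    "role": "case" if j == 0 else "control",
                    "index_date": np.datetime64(index_date),
                }
            )
            sid += 1
    df = pd.DataFrame(rows)
    df["index_date"] = pd.to_datetime(df["index_date"])
    return df
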