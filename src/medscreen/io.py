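"""Reading and writing of the pipeline's tabular artifacts.

The raw dataset is a directory of flat CSVs mirroring EMR extracts:
subjects.csv, enrollment.csv, dispensing.csv (subject_id, atc5, date),
diagnoses.csv, comorbidities.csv, visits.csv and catalog.csv. Dates are
ISO-8601; intervals are half-open [start, end). Exposure matrices may also
be written as Parquet to keep the 800-column table compact.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from medscreen.synthetic import Population

DATE_COLS = {
    "subjects": ["enrollment_start", "enrollment_end"],
    "enrollment": ["enrollment_start", "enrollment_end"],
    "dispensing": ["dispense_date"],
    "diagnoses": ["diagnosis_date"],
    "comorbidities": ["onset_date"],
    "visits": ["visit_date"],
    "matched_sets": ["index_date"],
}


def write_dataset(
    out_dir,
    population: Population,
    dispensing: pd.DataFrame,
    diagnoses: pd.DataFrame,
    catalog: pd.DataFrame,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    population.subjects.to_csv(out / "subjects.csv", index=False)
    population.enrollment.to_csv(out / "enrollment.csv", index=False)
    population.comorbidities.to_csv(out / "comorbidities.csv", index=False)
    population.visits.to_csv(out / "visits.csv", index=False)
    dispensing.to_csv(out / "dispensing.csv", index=False)
    diagnoses.to_csv(out / "diagnoses.csv", index=False)
    catalog.to_csv(out / "catalog.csv", index=False)
    return out


def read_table(path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in DATE_COLS.get(name, []):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def read_dataset(data_dir) -> dict[str, pd.DataFrame]:
    data = Path(data_dir)
    tables = {}
    for name in (
        "subjects",
        "enrollment",
        "dispensing",
        "diagnoses",
        "comorbidities",
        "visits",
        "catalog",
    ):
        path = data / f"{name}.csv"
        if path.exists():
            tables[name] = read_table(path, name)
    missing = {"subjects", "enrollment", "dispensing", "diagnoses"} - set(tables)
    if missing:
        raise FileNotFoundError(f"dataset at {data} is missing tables: {missing}")
    return tables


def write_matrix(matrix: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        matrix.to_parquet(path, index=False)
    else:
        matrix.to_csv(path, index=False)


def read_matrix(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)
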