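"""Shared in-memory containers and tab-separated I/O.

Two objects travel through every stage of the analysis:

* a *cohort table* — one row per subject with demographics, diagnosis and
  sleep-disordered-breathing (SDB) status — kept as a plain
  :class:`pandas.DataFrame` with a fixed column schema, and
* a :class:`ParcelMatrix` — a subjects x parcels matrix of gray-matter
  parcel volumes, row-aligned with its cohort table.

All tables are serialized as tab-separated text with a one-line header;
missing entries are written as the explicit token ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NA_TOKEN = "NA"

DIAGNOSES = ("HC", "MCI", "AD")
SEXES = ("female", "male")
SDB_LEVELS = ("negative", "positive")

#: Column schema of a cohort table.  ``sdb_status`` is NA for reference
#: (training) cohorts, which carry no SDB phenotype.
COHORT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "diagnosis",
    "sdb_status",
    "bmi",
    "education_years",
    "apoe4_count",
    "site",
    "protocol",
    "field_strength",
    "treatment_flag",
]

_NUMERIC_COHORT_COLUMNS = ["age", "bmi", "education_years", "apoe4_count"]


def validate_cohort(cohort: pd.DataFrame, require_sdb: bool = False) -> None:
    """Check a cohort table against the expected schema.

    Raises ``ValueError`` on missing columns, duplicate subject ids, or —
    when ``require_sdb`` — undefined SDB status.
    """
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    if cohort["subject_id"].duplicated().any():
        dup = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id in cohort table: {dup!r}")
    if require_sdb and cohort["sdb_status"].isna().any():
        raise ValueError("sdb_status must be defined for every subject in a study cohort")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    if "treatment_flag" in df.columns:
        df["treatment_flag"] = df["treatment_flag"].astype(bool)
    return df


@dataclass
class ParcelMatrix:
    """Subjects x parcels matrix of gray-matter parcel volumes.

    Rows are aligned with the paired cohort table; ``parcel_ids`` follow the
    atlas label-table order.
    """

    values: np.ndarray
    parcel_ids: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.parcel_ids = [str(p) for p in self.parcel_ids]
        self.subject_ids = [str(s) for s in self.subject_ids]
        if self.values.ndim != 2:
            raise ValueError("parcel values must be a 2-D subjects x parcels array")
        n, p = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError(f"{len(self.subject_ids)} subject ids for {n} rows")
        if len(self.parcel_ids) != p:
            raise ValueError(f"{len(self.parcel_ids)} parcel ids for {p} columns")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("parcel matrix contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]

    def subset(self, subject_ids) -> "ParcelMatrix":
        """Row-subset (and reorder) by subject id."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            rows = [index[str(s)] for s in subject_ids]
        except KeyError as e:
            raise KeyError(f"subject {e.args[0]!r} not in parcel matrix") from None
        return ParcelMatrix(self.values[rows], self.parcel_ids, [str(s) for s in subject_ids])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.parcel_ids)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)

    @classmethod
    def from_tsv(cls, path) -> "ParcelMatrix":
        df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
        if df.columns[0] != "subject_id":
            raise ValueError("parcel matrix TSV must have 'subject_id' as its first column")
        return cls(
            df.iloc[:, 1:].to_numpy(dtype=float),
            list(df.columns[1:]),
            [str(s) for s in df["subject_id"]],
        )
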