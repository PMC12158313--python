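"""Subject records, cohorts, and the published population-table structure.

The study population is 49 adults, stratified by sex and age, characterized
by a bioimpedance body-composition scale (body fat, visceral fat, skeletal
protein, BMI) plus self-reported binary health flags: smoker, history of
reflux/gastritis/chronic stomach pain, and other digestive issues.  The
published summary table reports, per sex, bin counts for each anthropometric
parameter and the mean with [min–max] range; those bins and ranges are kept
here as module constants so that both the deterministic fixture cohort and
cohort summaries are driven by a single definition.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterator

import pandas as pd

#: total participants in the reference population
N_PARTICIPANTS = 49
N_MEN = 23
N_WOMEN = 26

#: flag totals: (men, women)
FLAG_COUNTS = {
    "smoker": (2, 4),        # 6 of 49
    "gastric_issue": (3, 4),  # 7 of 49
    "reflux": (2, 4),         # 6 of 49
}

#: anthropometric parameter → bin edges (first/last bin open-ended),
#: per-sex bin counts, per-sex printed [min, max] range and mean.
TABLE1 = {
    "age": {
        "edges": [18.0, 30.0, 50.0, 70.0],
        "counts": {"M": [17, 5, 1], "W": [12, 11, 3]},
        "range": {"M": (18.0, 53.0), "W": (20.0, 56.0)},
        "mean": {"M": 28.1, "W": 35.4},
    },
    "height": {
        "edges": [0.0, 160.0, 170.0, 185.0, 220.0],
        "counts": {"M": [0, 3, 15, 5], "W": [8, 16, 2, 0]},
        "range": {"M": (164.0, 190.0), "W": (151.0, 176.0)},
        "mean": {"M": 178.4, "W": 163.0},
    },
    "weight": {
        "edges": [0.0, 50.0, 65.0, 90.0, 150.0],
        "counts": {"M": [0, 3, 14, 6], "W": [6, 11, 8, 1]},
        "range": {"M": (54.0, 119.0), "W": (43.0, 85.0)},
        "mean": {"M": 80.3, "W": 58.2},
    },
    "body_fat": {
        "edges": [0.0, 18.5, 26.9, 40.0, 60.0],
        "counts": {"M": [9, 10, 4, 0], "W": [1, 13, 8, 4]},
        "range": {"M": (0.7, 38.0), "W": (18.0, 45.0)},
        "mean": {"M": 19.5, "W": 26.0},
    },
    "visceral_fat": {
        "edges": [0.0, 3.0, 5.0, 9.0, 24.0],
        "counts": {"M": [2, 5, 10, 6], "W": [6, 12, 7, 1]},
        "range": {"M": (2.0, 23.0), "W": (2.0, 9.0)},
        "mean": {"M": 7.3, "W": 4.1},
    },
    "skeletal_protein": {
        "edges": [0.0, 25.0, 30.0, 40.0, 55.0],
        "counts": {"M": [0, 1, 11, 11], "W": [3, 13, 10, 0]},
        "range": {"M": (28.0, 47.0), "W": (23.0, 34.0)},
        "mean": {"M": 40.1, "W": 29.3},
    },
    "bmi": {
        "edges": [0.0, 20.0, 22.0, 25.0, 40.0],
        "counts": {"M": [1, 3, 12, 7], "W": [12, 6, 1, 7]},
        "range": {"M": (19.0, 37.0), "W": (17.0, 34.0)},
        "mean": {"M": 25.3, "W": 21.8},
    },
}

ANTHROPOMETRIC_FIELDS = tuple(TABLE1)
FLAG_FIELDS = ("smoker", "reflux", "gastric_issue")

#: CSV column names for cohort I/O, in order
COHORT_COLUMNS = (
    "subject_id",
    "sex",
    "age_years",
    "height_cm",
    "weight_kg",
    "body_fat_pct",
    "visceral_fat_pct",
    "skeletal_protein_pct",
    "bmi",
    "smoker",
    "reflux",
    "gastric_issue",
    "electrode_distance_m",
)

_FIELD_TO_COLUMN = {
    "age": "age_years",
    "height": "height_cm",
    "weight": "weight_kg",
    "body_fat": "body_fat_pct",
    "visceral_fat": "visceral_fat_pct",
    "skeletal_protein": "skeletal_protein_pct",
    "bmi": "bmi",
}


class CohortError(ValueError):
    """Invalid subject record or cohort."""


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: demographics, body composition, health flags.

    Units: age in years, height cm, weight kg, fat/protein fractions in
    g/100 g, BMI kg/m², electrode separation in m.  Flags are 0/1 integers
    (1 = condition present).
    """

    subject_id: str
    sex: str                 # "M" or "W"
    age: float
    height: float
    weight: float
    body_fat: float
    visceral_fat: float
    skeletal_protein: float
    bmi: float
    smoker: int
    reflux: int
    gastric_issue: int
    electrode_distance: float

    def __post_init__(self) -> None:
        if self.sex not in ("M", "W"):
            raise CohortError(f"sex must be 'M' or 'W', got {self.sex!r}")
        for name in FLAG_FIELDS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise CohortError(f"{name} flag must be 0 or 1, got {v!r}")
        for name in ("age", "height", "weight", "body_fat", "visceral_fat",
                     "skeletal_protein", "bmi", "electrode_distance"):
            if not getattr(self, name) > 0:
                raise CohortError(f"{name} must be positive")


@dataclass
class Cohort:
    """An ordered collection of subject records."""

    subjects: tuple[SubjectRecord, ...]

    def __post_init__(self) -> None:
        self.subjects = tuple(self.subjects)
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate subject ids in cohort")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def __getitem__(self, i: int) -> SubjectRecord:
        return self.subjects[i]

    def flag_total(self, flag: str) -> int:
        if flag not in FLAG_FIELDS:
            raise CohortError(f"unknown flag {flag!r}")
        return sum(getattr(s, flag) for s in self.subjects)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            d = asdict(s)
            rows.append({
                "subject_id": d["subject_id"],
                "sex": d["sex"],
                "age_years": d["age"],
                "height_cm": d["height"],
                "weight_kg": d["weight"],
                "body_fat_pct": d["body_fat"],
                "visceral_fat_pct": d["visceral_fat"],
                "skeletal_protein_pct": d["skeletal_protein"],
                "bmi": d["bmi"],
                "smoker": d["smoker"],
                "reflux": d["reflux"],
                "gastric_issue": d["gastric_issue"],
                "electrode_distance_m": d["electrode_distance"],
            })
        return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Cohort":
        missing = set(COHORT_COLUMNS) - set(df.columns)
        if missing:
            raise CohortError(f"cohort table missing columns: {sorted(missing)}")
        subjects = tuple(
            SubjectRecord(
                subject_id=str(r.subject_id),
                sex=str(r.sex),
                age=float(r.age_years),
                height=float(r.height_cm),
                weight=float(r.weight_kg),
                body_fat=float(r.body_fat_pct),
                visceral_fat=float(r.visceral_fat_pct),
                skeletal_protein=float(r.skeletal_protein_pct),
                bmi=float(r.bmi),
                smoker=int(r.smoker),
                reflux=int(r.reflux),
                gastric_issue=int(r.gastric_issue),
                electrode_distance=float(r.electrode_distance_m),
            )
            for r in df.itertuples(index=False)
        )
        return cls(subjects=subjects)


def parameter_column(param: str) -> str:
    """Map an anthropometric parameter name to its cohort CSV column."""
    try:
        return _FIELD_TO_COLUMN[param]
    except KeyError:
        raise CohortError(f"unknown anthropometric parameter {param!r}") from None


def bin_counts(cohort: Cohort, param: str, sex: str) -> list[int]:
    """Count this cohort's *sex* subjects falling in each published bin of *param*."""
    spec = TABLE1[param]
    values = [getattr(s, param) for s in cohort if s.sex == sex]
    edges = spec["edges"]
    counts = [0] * (len(edges) - 1)
    for v in values:
        for i in range(len(edges) - 1):
            lo, hi = edges[i], edges[i + 1]
            # first bin closed on the left, all bins closed on the right
            if (v >= lo if i == 0 else v > lo) and v <= hi:
                counts[i] += 1
                break
    return counts
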