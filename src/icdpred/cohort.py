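"""Longitudinal cohort data model and CSV round-trip.

A cohort is a collection of Parkinson's disease subjects followed over
irregularly spaced visits.  Each subject carries static covariates (age at
baseline, sex, SNP dosages), an ordered list of time-stamped visits with
clinical scale values and a binary impulse-control-disorder (ICD) status,
and a list of medication exposure intervals expressed in levodopa
equivalent daily dose (LEDD).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: clinical scales that may be missing and are subject to imputation
SCALE_COLUMNS = ("anxiety", "depression", "rem", "updrs3")

#: binary treatment-class flags recorded at each visit
TREATMENT_FLAGS = ("on_levodopa", "on_dopamine_agonist", "on_other")

DRUG_CLASSES = ("levodopa", "dopamine_agonist", "other")


@dataclass
class Visit:
    """One clinical visit: scale values (NaN = missing) plus ICD status."""

    time_years: float
    anxiety: float
    depression: float
    rem: float
    updrs3: float
    icd: int
    on_levodopa: int = 0
    on_dopamine_agonist: int = 0
    on_other: int = 0
    da_daily_dose: float = 0.0

    def __post_init__(self) -> None:
        if self.time_years < 0:
            raise ValueError("visit time must be non-negative")
        if self.icd not in (0, 1):
            raise ValueError("icd status must be binary, never missing")
        if self.da_daily_dose > 0 and not self.on_dopamine_agonist:
            raise ValueError("positive DA dose requires on_dopamine_agonist=1")

    def scale_value(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class MedicationInterval:
    """Piecewise-constant drug exposure: [start, end) years at a daily dose."""

    drug_class: str
    start_years: float
    end_years: float
    daily_dose_ledd: float = 0.0

    def __post_init__(self) -> None:
        if self.drug_class not in DRUG_CLASSES:
            raise ValueError(f"unknown drug class {self.drug_class!r}")
        if not self.start_years < self.end_years:
            raise ValueError("interval start must precede end")
        if self.daily_dose_ledd < 0:
            raise ValueError("daily dose must be non-negative")


@dataclass
class SubjectRecord:
    """All data for one subject.

    Invariants: at least two visits (a baseline visit and at least one
    follow-up), strictly increasing visit times with the first at 0.
    """

    subject_id: str
    age_baseline: float
    sex: int
    genotype: np.ndarray
    visits: list[Visit]
    medication: list[MedicationInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.visits) < 2:
            raise ValueError(
                f"subject {self.subject_id}: needs a baseline visit and at "
                "least another visit"
            )
        times = [v.time_years for v in self.visits]
        if times[0] != 0:
            raise ValueError(f"subject {self.subject_id}: first visit not at 0")
        if not all(a < b for a, b in zip(times, times[1:])):
            raise ValueError(
                f"subject {self.subject_id}: visit times not strictly increasing"
            )
        self.genotype = np.asarray(self.genotype, dtype=float)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def visit_times(self) -> np.ndarray:
        return np.array([v.time_years for v in self.visits])


@dataclass
class Cohort:
    """An ordered collection of subjects plus the dialect it was drawn from."""

    subjects: list[SubjectRecord]
    dialect: str = "drugnaive_baseline"

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def n_snps(self) -> int:
        return int(self.subjects[0].genotype.shape[0]) if self.subjects else 0

    def n_visits_total(self) -> int:
        return sum(s.n_visits for s in self.subjects)

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        wanted = set(subject_ids)
        return Cohort(
            [s for s in self.subjects if s.subject_id in wanted], self.dialect
        )

    def copy(self) -> "Cohort":
        return Cohort(
            [
                SubjectRecord(
                    s.subject_id,
                    s.age_baseline,
                    s.sex,
                    s.genotype.copy(),
                    [replace(v) for v in s.visits],
                    list(s.medication),
                )
                for s in self.subjects
            ],
            self.dialect,
        )

    # ------------------------------------------------------------------ I/O

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Long-format visit table and wide-format static table."""
        visit_rows = []
        static_rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "age": s.age_baseline, "sex": s.sex}
            for j, d in enumerate(s.genotype):
                row[f"snp_{j + 1}"] = d
            static_rows.append(row)
            for v in s.visits:
                visit_rows.append(
                    {
                        "subject_id": s.subject_id,
                        "time_years": v.time_years,
                        **{c: v.scale_value(c) for c in SCALE_COLUMNS},
                        "icd": v.icd,
                        **{f: getattr(v, f) for f in TREATMENT_FLAGS},
                        "da_daily_dose": v.da_daily_dose,
                    }
                )
        return pd.DataFrame(visit_rows), pd.DataFrame(static_rows)

    def medication_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.subject_id,
                "drug_class": m.drug_class,
                "start_years": m.start_years,
                "end_years": m.end_years,
                "daily_dose_ledd": m.daily_dose_ledd,
            }
            for s in self.subjects
            for m in s.medication
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "subject_id",
                "drug_class",
                "start_years",
                "end_years",
                "daily_dose_ledd",
            ],
        )

    def write_csv(self, visits_path, static_path, medication_path=None) -> None:
        visits, static = self.to_frames()
        visits.to_csv(visits_path, index=False)
        static.to_csv(static_path, index=False)
        if medication_path is not None:
            self.medication_frame().to_csv(medication_path, index=False)

    @classmethod
    def from_frames(
        cls,
        visits: pd.DataFrame,
        static: pd.DataFrame,
        medication: pd.DataFrame | None = None,
        dialect: str = "drugnaive_baseline",
    ) -> "Cohort":
        snp_cols = sorted(
            (c for c in static.columns if c.startswith("snp_")),
            key=lambda c: int(c.split("_")[1]),
        )
        med_by_subject: dict[str, list[MedicationInterval]] = {}
        if medication is not None and len(medication):
            for _, r in medication.iterrows():
                med_by_subject.setdefault(str(r["subject_id"]), []).append(
                    MedicationInterval(
                        r["drug_class"],
                        float(r["start_years"]),
                        float(r["end_years"]),
                        float(r["daily_dose_ledd"]),
                    )
                )
        subjects = []
        for _, srow in static.iterrows():
            sid = str(srow["subject_id"])
            sub_visits = visits[visits["subject_id"].astype(str) == sid].sort_values(
                "time_years"
            )
            vlist = [
                Visit(
                    time_years=float(r["time_years"]),
                    **{c: float(r[c]) for c in SCALE_COLUMNS},
                    icd=int(r["icd"]),
                    **{f: int(r[f]) for f in TREATMENT_FLAGS},
                    da_daily_dose=float(r["da_daily_dose"]),
                )
                for _, r in sub_visits.iterrows()
            ]
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    age_baseline=float(srow["age"]),
                    sex=int(srow["sex"]),
                    genotype=srow[snp_cols].to_numpy(dtype=float),
                    visits=vlist,
                    medication=med_by_subject.get(sid, []),
                )
            )
        return cls(subjects, dialect)

    @classmethod
    def read_csv(
        cls,
        visits_path,
        static_path,
        medication_path=None,
        dialect: str = "drugnaive_baseline",
    ) -> "Cohort":
        med = pd.read_csv(medication_path) if medication_path is not None else None
        return cls.from_frames(
            pd.read_csv(visits_path), pd.read_csv(static_path), med, dialect
        )


def read_dosage_matrix(path) -> tuple[list[str], np.ndarray]:
    """Read a plain additive-coding dosage CSV (subject_id, snp columns).

    Accepts the wide layout PLINK's ``--recode A`` produces once exported to
    CSV: one row per subject, one 0/1/2 column per variant.
    """
    df = pd.read_csv(path)
    ids = df["subject_id"].astype(str).tolist()
    snp_cols = [c for c in df.columns if c != "subject_id"]
    return ids, df[snp_cols].to_numpy(dtype=float)
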