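"""Clinical cohort table: parsing, validation, group filters and summaries.

The cohort table describes patients with disorders of consciousness (DOC):
diagnosis (MCS = minimally conscious state, UWS = unresponsive wakefulness
syndrome, historically labelled VS), aetiology, demographics, and the six
CRS-R sub-scores (auditory, visual, motor, verbal, communication, arousal)
with their total.  Aetiology maps deterministically onto the
traumatic/nontraumatic split used by every downstream group contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import SchemaError, ValidationError

DIAGNOSES = ("MCS", "UWS")
AETIOLOGIES = ("trauma", "hemorrhage", "anoxia")
TRAUMATIC_GROUPS = ("traumatic", "nontraumatic")

#: per-subscale maxima of the CRS-R (auditory, visual, motor, verbal,
#: communication, arousal)
CRS_SUBSCALE_MAX = (4, 5, 6, 3, 2, 3)

_SUB_COLS = ("crs_a", "crs_v", "crs_m", "crs_verbal", "crs_comm", "crs_arousal")
_REQUIRED = ("patient_id", "diagnosis", "etiology", "months_since_injury") + _SUB_COLS + ("crs_total",)


def aetiology_to_group(aetiology: str) -> str:
    """Map aetiology to the traumatic/nontraumatic dichotomy.

    ``trauma`` -> traumatic; ``hemorrhage`` and ``anoxia`` -> nontraumatic.
    """
    a = aetiology.strip().lower()
    if a == "trauma":
        return "traumatic"
    if a in ("hemorrhage", "anoxia"):
        return "nontraumatic"
    raise ValidationError(f"unknown aetiology {aetiology!r}")


def _normalize_diagnosis(label: str) -> str:
    d = label.strip().upper()
    if d == "VS":  # vegetative state == unresponsive wakefulness syndrome
        return "UWS"
    if d in DIAGNOSES:
        return d
    raise ValidationError(f"unknown diagnosis label {label!r}")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    diagnosis: str                 # MCS | UWS
    sex: str                       # M | F
    age: int                       # years
    aetiology: str                 # trauma | hemorrhage | anoxia
    lesion_text: str
    months_since_injury: float
    crs_r_sub: tuple               # six ints: auditory, visual, motor, verbal, comm, arousal
    crs_r_total: int

    def __post_init__(self):
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(f"{self.patient_id}: diagnosis {self.diagnosis!r}")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"{self.patient_id}: sex {self.sex!r}")
        if self.age <= 0:
            raise ValidationError(f"{self.patient_id}: age must be > 0")
        if self.months_since_injury <= 0:
            raise ValidationError(f"{self.patient_id}: months_since_injury must be > 0")
        if len(self.crs_r_sub) != 6 or any(s < 0 for s in self.crs_r_sub):
            raise ValidationError(f"{self.patient_id}: six nonnegative sub-scores required")

    @property
    def traumatic_group(self) -> str:
        return aetiology_to_group(self.aetiology)

    def validate_total(self) -> None:
        s = sum(self.crs_r_sub)
        if s != self.crs_r_total:
            raise ValidationError(
                f"patient {self.patient_id}: CRS-R sub-scores sum to {s} "
                f"but total is {self.crs_r_total}"
            )


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean_age: float          # unrounded; NaN when n == 0
    mean_age_rounded: Optional[int]
    age_min: Optional[int]
    age_max: Optional[int]
    n_male: int
    n_traumatic: int


@dataclass
class CohortTable:
    records: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter(self, diagnosis: Optional[str] = None,
               traumatic_group: Optional[str] = None) -> "CohortTable":
        rows = self.records
        if diagnosis is not None:
            d = _normalize_diagnosis(diagnosis)
            rows = [r for r in rows if r.diagnosis == d]
        if traumatic_group is not None:
            if traumatic_group not in TRAUMATIC_GROUPS:
                raise ValidationError(f"unknown traumatic_group {traumatic_group!r}")
            rows = [r for r in rows if r.traumatic_group == traumatic_group]
        return CohortTable(list(rows))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "patient_id": r.patient_id,
                "diagnosis": r.diagnosis,
                "sex": r.sex,
                "age": r.age,
                "etiology": r.aetiology,
                "lesion": r.lesion_text,
                "months_since_injury": r.months_since_injury,
            }
            row.update(dict(zip(_SUB_COLS, r.crs_r_sub)))
            row["crs_total"] = r.crs_r_total
            rows.append(row)
        cols = ["patient_id", "diagnosis", "sex", "age", "etiology", "lesion",
                "months_since_injury", *_SUB_COLS, "crs_total"]
        return pd.DataFrame(rows, columns=cols)

    @property
    def crs_totals(self):
        return [r.crs_r_total for r in self.records]


def parse_cohort_table(path, validate_totals: bool = True) -> CohortTable:
    """Parse a tab-delimited cohort table into a :class:`CohortTable`.

    The header must carry ``patient_id, diagnosis, etiology, lesion,
    months_since_injury``, the six sub-score columns and ``crs_total``, plus
    either separate ``sex``/``age`` columns or a packed ``sex_age`` column
    ("M/60").  Diagnosis strings MCS/UWS/VS are accepted (VS normalizes to
    UWS).  Unless ``validate_totals`` is disabled, each row's total must
    equal the sum of its six sub-scores.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = set(df.columns)
    missing = [c for c in _REQUIRED if c not in cols]
    if "sex_age" in cols:
        pass
    elif not {"sex", "age"} <= cols:
        missing.append("sex_age (or sex + age)")
    if "lesion" not in cols:
        missing.append("lesion")
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")

    records = []
    for _, row in df.iterrows():
        if "sex_age" in cols and row.get("sex_age", ""):
            sex, _, age_s = row["sex_age"].partition("/")
        else:
            sex, age_s = row["sex"], row["age"]
        rec = PatientRecord(
            patient_id=row["patient_id"],
            diagnosis=_normalize_diagnosis(row["diagnosis"]),
            sex=sex.strip().upper(),
            age=int(age_s),
            aetiology=row["etiology"].strip().lower(),
            lesion_text=row["lesion"],
            months_since_injury=float(row["months_since_injury"]),
            crs_r_sub=tuple(int(row[c]) for c in _SUB_COLS),
            crs_r_total=int(row["crs_total"]),
        )
        if rec.aetiology not in AETIOLOGIES:
            raise ValidationError(f"{rec.patient_id}: unknown aetiology {rec.aetiology!r}")
        if validate_totals:
            rec.validate_total()
        records.append(rec)
    return CohortTable(records)


def write_cohort_table(table: CohortTable, path) -> Path:
    """Write the canonical TSV form (separate sex/age columns)."""
    path = Path(path)
    table.to_frame().to_csv(path, sep="\t", index=False)
    return path


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_group(table: CohortTable, diagnosis: Optional[str] = None,
                    traumatic_group: Optional[str] = None) -> GroupSummary:
    """Summarize the rows passing all supplied filters.

    Mean age is reported unrounded and, for comparison against integer
    reports, rounded half-up.  An empty selection yields n=0 with the
    undefined aggregates flagged as None/NaN.
    """
    sel = table.filter(diagnosis=diagnosis, traumatic_group=traumatic_group)
    n = len(sel)
    if n == 0:
        return GroupSummary(0, float("nan"), None, None, None, 0, 0)
    ages = [r.age for r in sel]
    mean_age = sum(ages) / n
    return GroupSummary(
        n=n,
        mean_age=mean_age,
        mean_age_rounded=_round_half_up(mean_age),
        age_min=min(ages),
        age_max=max(ages),
        n_male=sum(r.sex == "M" for r in sel),
        n_traumatic=sum(r.traumatic_group == "traumatic" for r in sel),
    )


def reference_cohort_path() -> Path:
    """Path of the packaged DOC reference cohort table (32 patients)."""
    return Path(resources.files("dynconn") / "data" / "doc_cohort_table1.tsv")


def load_reference_cohort() -> CohortTable:
    return parse_cohort_table(reference_cohort_path())
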