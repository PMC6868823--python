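"""Domain vocabulary for SCOFF/BMI eating-disorder screening.

The SCOFF questionnaire is a five-item binary screen (Sick, Control,
One stone, Fat, Food); two or more positive answers constitute a
positive screen.  Screen-positive adults are classed by body-mass index
into the four WHO classes and, downstream, mapped by a rule table to one
of four broad eating-disorder categories:

* RD  -- restrictive disorders (anorexia nervosa and relatives)
* BD  -- bulimic disorders (bulimia nervosa and low-frequency variants)
* HD  -- hyperphagic disorders (binge-eating disorder and variants)
* OED -- other eating disorders (purging disorder, night eating, residual)

This module holds the types and elementary operations: SCOFF scoring and
the screen-positive rule, BMI classing, the DSM-5 diagnosis to broad
category mapping, patient records and their CSV round-trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ValidationError",
    "ScoffResponse",
    "BmiClass",
    "BroadCategory",
    "Dsm5Diagnosis",
    "Sex",
    "PatientRecord",
    "SCOFF_ITEMS",
    "DSM5_TO_BROAD",
    "score_scoff",
    "is_screen_positive",
    "classify_bmi",
    "map_dsm5_to_broad",
    "read_patient_csv",
    "write_patient_csv",
    "records_to_frame",
    "frame_to_records",
]


class ValidationError(ValueError):
    """Raised when domain inputs violate their invariants."""


#: Fixed item order of the questionnaire: Sick, Control, One stone, Fat, Food.
SCOFF_ITEMS = ("sick", "control", "one_stone", "fat", "food")

#: CSV column names for the five answers, in item order.
SCOFF_COLUMNS = tuple(f"scoff_{item}" for item in SCOFF_ITEMS)

_TRUTHY = {"1", "yes", "y", "true"}
_FALSY = {"0", "no", "n", "false"}


def _coerce_binary(value: object, item: str) -> bool:
    """Normalize a questionnaire answer to a bool; accept 1/0, yes/no, Y/N."""
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValidationError(f"missing answer for SCOFF item {item!r}")
    if isinstance(value, (int,)) and value in (0, 1):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValidationError(
        f"answer for SCOFF item {item!r} must be binary (yes/no, 1/0), got {value!r}"
    )


@dataclass(frozen=True)
class ScoffResponse:
    """One completed SCOFF questionnaire.

    Fields follow the fixed item order Sick, Control, One stone, Fat,
    Food.  Every answer must be present and binary; construction fails
    otherwise, naming the offending item.
    """

    sick: bool
    control: bool
    one_stone: bool
    fat: bool
    food: bool

    def __post_init__(self) -> None:
        for item in SCOFF_ITEMS:
            object.__setattr__(self, item, _coerce_binary(getattr(self, item), item))

    @property
    def score(self) -> int:
        """Number of positive answers, 0..5."""
        return sum(int(getattr(self, item)) for item in SCOFF_ITEMS)

    @property
    def pattern(self) -> tuple[int, int, int, int, int]:
        """The answer bits as an ordered (sick, control, one_stone, fat, food) tuple."""
        return tuple(int(getattr(self, item)) for item in SCOFF_ITEMS)  # type: ignore[return-value]

    @classmethod
    def from_pattern(cls, bits: Sequence[int]) -> "ScoffResponse":
        if len(bits) != 5:
            raise ValidationError(f"SCOFF pattern needs 5 bits, got {len(bits)}")
        return cls(*(bool(b) for b in bits))


class BmiClass(IntEnum):
    """WHO BMI class; ordered underweight < normal < overweight < obese."""

    UNDERWEIGHT = 0
    NORMAL = 1
    OVERWEIGHT = 2
    OBESE = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "BmiClass":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise ValidationError(
                f"unknown BMI class {label!r}; expected one of "
                f"{[c.label for c in cls]}"
            ) from None


class BroadCategory(str, Enum):
    """The four broad eating-disorder categories, in canonical order."""

    RD = "RD"
    BD = "BD"
    HD = "HD"
    OED = "OED"

    @property
    def index(self) -> int:
        return list(BroadCategory).index(self)

    @classmethod
    def from_label(cls, label: str) -> "BroadCategory":
        try:
            return cls(str(label).strip().upper())
        except ValueError:
            raise ValidationError(
                f"unknown category {label!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


class Dsm5Diagnosis(str, Enum):
    """Closed vocabulary of DSM-5 eating-disorder labels handled here."""

    ANOREXIA_NERVOSA = "anorexia_nervosa"
    BULIMIA_NERVOSA = "bulimia_nervosa"
    BINGE_EATING_DISORDER = "binge_eating_disorder"
    RESTRICTIVE_FOOD_INTAKE_DISORDER = "restrictive_food_intake_disorder"
    ATYPICAL_ANOREXIA_NERVOSA = "atypical_anorexia_nervosa"
    BULIMIA_NERVOSA_LOW_FREQ = "bulimia_nervosa_low_freq"
    BINGE_EATING_DISORDER_LOW_FREQ = "binge_eating_disorder_low_freq"
    PURGING_DISORDER = "purging_disorder"
    NIGHT_EATING_SYNDROME = "night_eating_syndrome"
    OTHER_ED = "other_ed"

    @classmethod
    def from_label(cls, label: str) -> "Dsm5Diagnosis":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown DSM-5 label {label!r}; expected one of "
                f"{[d.value for d in cls]}"
            ) from None


#: Grouping of DSM-5 diagnoses into the four broad categories:
#: AN, ARFID and atypical AN are restrictive; BN and its low-frequency
#: variant bulimic; BED and its variant hyperphagic; purging disorder,
#: night eating syndrome and the residual label fall to OED.
DSM5_TO_BROAD: dict[Dsm5Diagnosis, BroadCategory] = {
    Dsm5Diagnosis.ANOREXIA_NERVOSA: BroadCategory.RD,
    Dsm5Diagnosis.RESTRICTIVE_FOOD_INTAKE_DISORDER: BroadCategory.RD,
    Dsm5Diagnosis.ATYPICAL_ANOREXIA_NERVOSA: BroadCategory.RD,
    Dsm5Diagnosis.BULIMIA_NERVOSA: BroadCategory.BD,
    Dsm5Diagnosis.BULIMIA_NERVOSA_LOW_FREQ: BroadCategory.BD,
    Dsm5Diagnosis.BINGE_EATING_DISORDER: BroadCategory.HD,
    Dsm5Diagnosis.BINGE_EATING_DISORDER_LOW_FREQ: BroadCategory.HD,
    Dsm5Diagnosis.PURGING_DISORDER: BroadCategory.OED,
    Dsm5Diagnosis.NIGHT_EATING_SYNDROME: BroadCategory.OED,
    Dsm5Diagnosis.OTHER_ED: BroadCategory.OED,
}


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"

    @classmethod
    def from_label(cls, label: str) -> "Sex":
        text = str(label).strip().lower()
        aliases = {"f": "female", "m": "male"}
        try:
            return cls(aliases.get(text, text))
        except ValueError:
            raise ValidationError(
                f"unknown sex {label!r}; expected female/male"
            ) from None


@dataclass
class PatientRecord:
    """One screened individual: demographics, BMI, answers, optional diagnosis."""

    id: str
    sex: Sex
    age: float
    bmi: float
    scoff: ScoffResponse
    dsm5: Dsm5Diagnosis | None = None
    extra: dict = field(default_factory=dict)

    def validate(self, permissive: bool = False) -> None:
        """Check study-inclusion invariants; ``permissive`` skips the age floor."""
        if not math.isfinite(self.bmi) or self.bmi <= 0:
            raise ValidationError(f"record {self.id!r}: BMI must be finite and > 0")
        if self.bmi > 100:
            raise ValidationError(
                f"record {self.id!r}: BMI {self.bmi} is implausible (> 100 kg/m²)"
            )
        if not permissive and self.age < 18:
            raise ValidationError(
                f"record {self.id!r}: age {self.age} below the adult inclusion "
                "criterion (use permissive=True to accept)"
            )


def score_scoff(resp: ScoffResponse) -> int:
    """Count of positive SCOFF answers (0..5)."""
    return resp.score


def is_screen_positive(resp: ScoffResponse) -> bool:
    """Positive screen: at least 2 of the 5 answers positive."""
    return resp.score >= 2


def classify_bmi(bmi: float) -> BmiClass:
    """Class a BMI value (kg/m²) into the four WHO classes.

    Intervals are half-open and exhaustive on (0, 100]:
    [0, 18.5) underweight, [18.5, 25) normal, [25, 30) overweight,
    [30, inf) obese — so 18.5 is normal, 25.0 overweight, 30.0 obese.
    """
    if not isinstance(bmi, (int, float)) or isinstance(bmi, bool):
        raise ValidationError(f"BMI must be numeric, got {bmi!r}")
    bmi = float(bmi)
    if not math.isfinite(bmi) or bmi <= 0:
        raise ValidationError(f"BMI must be finite and positive, got {bmi!r}")
    if bmi > 100:
        raise ValidationError(f"BMI {bmi} is implausible (> 100 kg/m²)")
    if bmi < 18.5:
        return BmiClass.UNDERWEIGHT
    if bmi < 25.0:
        return BmiClass.NORMAL
    if bmi < 30.0:
        return BmiClass.OVERWEIGHT
    return BmiClass.OBESE


def map_dsm5_to_broad(dx: Dsm5Diagnosis | str) -> BroadCategory:
    """Map a DSM-5 diagnosis label to its broad category."""
    if not isinstance(dx, Dsm5Diagnosis):
        dx = Dsm5Diagnosis.from_label(dx)
    return DSM5_TO_BROAD[dx]


# ---------------------------------------------------------------------------
# Patient CSV I/O
#
# Format: UTF-8 CSV with header; columns id, sex, age, bmi, the five
# scoff_* answer columns (binary), and optionally dsm5_diagnosis.
# Unknown columns are preserved on read and written back on write.

REQUIRED_COLUMNS = ("id", "sex", "age", "bmi") + SCOFF_COLUMNS


def frame_to_records(
    df: pd.DataFrame, permissive: bool = False
) -> list[PatientRecord]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"patient table missing columns: {missing}")
    known = set(REQUIRED_COLUMNS) | {"dsm5_diagnosis"}
    extra_cols = [c for c in df.columns if c not in known]
    records: list[PatientRecord] = []
    seen_ids: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        data = dict(zip(df.columns, row))
        rid = str(data["id"])
        if rid in seen_ids:
            raise ValidationError(f"duplicate patient id {rid!r} (row {row_no})")
        seen_ids.add(rid)
        try:
            scoff = ScoffResponse(*(data[c] for c in SCOFF_COLUMNS))
            dx_raw = data.get("dsm5_diagnosis")
            dx = None
            if dx_raw is not None and not (
                isinstance(dx_raw, float) and math.isnan(dx_raw)
            ):
                text = str(dx_raw).strip()
                if text:
                    dx = Dsm5Diagnosis.from_label(text)
            rec = PatientRecord(
                id=rid,
                sex=Sex.from_label(data["sex"]),
                age=float(data["age"]),
                bmi=float(data["bmi"]),
                scoff=scoff,
                dsm5=dx,
                extra={c: data[c] for c in extra_cols},
            )
            rec.validate(permissive=permissive)
        except (ValidationError, TypeError, ValueError) as exc:
            raise ValidationError(f"row {row_no}: {exc}") from exc
        records.append(rec)
    return records


def read_patient_csv(path: str | Path, permissive: bool = False) -> list[PatientRecord]:
    """Read a patient cohort CSV; validates every row."""
    df = pd.read_csv(path, dtype={"id": str})
    return frame_to_records(df, permissive=permissive)


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict = {
            "id": rec.id,
            "sex": rec.sex.value,
            "age": rec.age,
            "bmi": rec.bmi,
        }
        for col, item in zip(SCOFF_COLUMNS, SCOFF_ITEMS):
            row[col] = int(getattr(rec.scoff, item))
        row["dsm5_diagnosis"] = rec.dsm5.value if rec.dsm5 is not None else ""
        row.update(rec.extra)
        rows.append(row)
    return pd.DataFrame(rows)


def write_patient_csv(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write a cohort as CSV, answers normalized to 1/0."""
    records_to_frame(records).to_csv(path, index=False)
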