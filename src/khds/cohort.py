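"""Patient presentations, eligibility, and disposition scoring.

The Kitovu Hospital Disposition Score (KHDS) awards one point each for

* altered mental status,
* impaired mobility (lack of a stable independent gait), and
* a respiratory abnormality: either a low oxygen saturation (SpO2 < 94%)
  or a raised respiratory rate (> 23 breaths/min) — never both.

Three variants differ only in which component source they read:

* ``KHDS_SAT`` — subjective mental status (alert, attentive, calm, coherent)
  and oxygen saturation (the default score);
* ``KHDS_RESP`` — subjective mental status and respiratory rate;
* ``KHDS_MONTHS`` — objective mental status (months-backwards test) and
  oxygen saturation.

A record missing a component required by a variant is excluded from that
variant's analysis set (per-variant complete-case); values are never imputed.
The eligible population is non-pregnant patients aged 12 years or older.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence


class Gait(enum.Enum):
    """Mobility on presentation; anything but a stable independent gait
    counts as impaired."""

    STABLE_INDEPENDENT = "stable_independent"
    UNSTEADY = "unsteady"
    USES_AID = "uses_aid"
    NEEDS_HELP = "needs_help"
    BEDRIDDEN = "bedridden"


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


class ScoreVariant(enum.Enum):
    """Which component sources a score reads.

    KHDS_MONTHS uses the months-backwards test for the mental component but
    oxygen saturation (not respiratory rate) for the respiratory component.
    """

    KHDS_SAT = "sat"
    KHDS_RESP = "resp"
    KHDS_MONTHS = "months"


class MissingComponentError(ValueError):
    """A score component required by the requested variant is absent."""

    def __init__(self, field_name: str, patient_id: str | None = None):
        self.field_name = field_name
        self.patient_id = patient_id
        where = f" (patient {patient_id})" if patient_id else ""
        super().__init__(f"missing component {field_name!r}{where}")


class RecordValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class PatientRecord:
    """One hospital presentation: score components, SATS presentations,
    and disposition outcomes.

    ``day_of_death`` is whole days elapsed since arrival; death within 24
    hours corresponds to day 0.  Deaths are always counted as admissions.
    """

    patient_id: str
    age: int
    sex: Sex
    arrival: datetime
    pregnant: bool
    alert: bool
    attentive: bool
    calm: bool
    coherent: bool
    months_backwards_pass: bool | None
    gait: Gait
    spo2: float | None
    resp_rate: float | None
    presentations: tuple[str, ...]
    admitted: bool
    died_within_24h: bool
    died_in_hospital: bool
    day_of_death: int | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise RecordValidationError(f"age must be >= 0, got {self.age}")
        if self.spo2 is not None and not (0 <= self.spo2 <= 100):
            raise RecordValidationError(f"spo2 out of range [0, 100]: {self.spo2}")
        if self.resp_rate is not None and not (0 <= self.resp_rate <= 120):
            raise RecordValidationError(
                f"resp_rate out of range [0, 120]: {self.resp_rate}"
            )
        if self.died_within_24h and not self.died_in_hospital:
            raise RecordValidationError("died_within_24h requires died_in_hospital")
        if self.died_in_hospital and not self.admitted:
            raise RecordValidationError("in-hospital death requires admission")
        if self.day_of_death is not None:
            if not self.died_in_hospital:
                raise RecordValidationError("day_of_death set but no death recorded")
            if self.day_of_death < 0:
                raise RecordValidationError("day_of_death must be >= 0")
            if self.died_within_24h != (self.day_of_death == 0):
                raise RecordValidationError(
                    "died_within_24h must agree with day_of_death == 0"
                )
        object.__setattr__(self, "presentations", tuple(self.presentations))

    @property
    def subjective_mental_normal(self) -> bool:
        """Normal mental status under the subjective assessment: alert,
        attentive, calm and coherent — all four."""
        return self.alert and self.attentive and self.calm and self.coherent


@dataclass(frozen=True)
class KHDSResult:
    """A computed disposition score: 0-3 points with per-component flags."""

    variant: ScoreVariant
    points: int
    mental_point: int
    mobility_point: int
    respiratory_point: int

    def __post_init__(self) -> None:
        for name in ("mental_point", "mobility_point", "respiratory_point"):
            if getattr(self, name) not in (0, 1):
                raise RecordValidationError(f"{name} must be 0 or 1")
        if self.points != self.mental_point + self.mobility_point + self.respiratory_point:
            raise RecordValidationError("points must equal the component sum")


def mobility_point(gait: Gait) -> int:
    """1 for any gait other than stable and independent (impaired mobility)."""
    if not isinstance(gait, Gait):
        raise RecordValidationError(f"unknown gait category: {gait!r}")
    return 0 if gait is Gait.STABLE_INDEPENDENT else 1


def mental_point(record: PatientRecord, variant: ScoreVariant) -> int:
    """1 for altered mental status under the variant's assessment.

    Subjective variants require all four of alert/attentive/calm/coherent
    for a normal status; KHDS_MONTHS requires passing the months-backwards
    test (reciting December back to July).  A patient unable to attempt the
    test is recorded as a fail, not as missing.
    """
    if variant is ScoreVariant.KHDS_MONTHS:
        if record.months_backwards_pass is None:
            raise MissingComponentError("months_backwards_pass", record.patient_id)
        return 0 if record.months_backwards_pass else 1
    return 0 if record.subjective_mental_normal else 1


def respiratory_point(record: PatientRecord, variant: ScoreVariant) -> int:
    """1 for SpO2 < 94% (KHDS_SAT, KHDS_MONTHS) or respiratory rate > 23
    breaths/min (KHDS_RESP).  Boundary values (94, 23) score 0."""
    if variant is ScoreVariant.KHDS_RESP:
        if record.resp_rate is None:
            raise MissingComponentError("resp_rate", record.patient_id)
        return 1 if record.resp_rate > 23 else 0
    if record.spo2 is None:
        raise MissingComponentError("spo2", record.patient_id)
    return 1 if record.spo2 < 94 else 0


def compute_khds(record: PatientRecord, variant: ScoreVariant = ScoreVariant.KHDS_SAT) -> KHDSResult:
    """Score a presentation under one variant; raises
    :class:`MissingComponentError` if a required component is absent."""
    m = mental_point(record, variant)
    g = mobility_point(record.gait)
    r = respiratory_point(record, variant)
    return KHDSResult(
        variant=variant,
        points=m + g + r,
        mental_point=m,
        mobility_point=g,
        respiratory_point=r,
    )


def is_eligible(record: PatientRecord) -> bool:
    """Study eligibility: aged 12 years or older and not pregnant."""
    return record.age >= 12 and not record.pregnant


def has_sats_ranking(record: PatientRecord) -> bool:
    """True if the record carries any SATS presentation code (including the
    explicit non-urgent pseudo-code); empty means the patient was not ranked."""
    return len(record.presentations) > 0


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age",
    "sex",
    "arrival",
    "pregnant",
    "alert",
    "attentive",
    "calm",
    "coherent",
    "months_backwards_pass",
    "gait",
    "spo2",
    "resp_rate",
    "presentations",
    "admitted",
    "died_within_24h",
    "died_in_hospital",
    "day_of_death",
)


class CohortFileError(ValueError):
    """A cohort CSV failed validation; carries per-row messages."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        shown = "\n".join(errors[:20])
        extra = f"\n... and {len(errors) - 20} more" if len(errors) > 20 else ""
        super().__init__(f"{len(errors)} invalid row(s):\n{shown}{extra}")


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _parse_bool(s: str, field_name: str) -> bool:
    if s == "true":
        return True
    if s == "false":
        return False
    raise ValueError(f"{field_name}: expected true/false, got {s!r}")


def _fmt_opt(v: float | int | bool | None) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return _fmt_bool(v)
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def record_to_row(record: PatientRecord) -> dict[str, str]:
    return {
        "patient_id": record.patient_id,
        "age": str(record.age),
        "sex": record.sex.value,
        "arrival": record.arrival.isoformat(),
        "pregnant": _fmt_bool(record.pregnant),
        "alert": _fmt_bool(record.alert),
        "attentive": _fmt_bool(record.attentive),
        "calm": _fmt_bool(record.calm),
        "coherent": _fmt_bool(record.coherent),
        "months_backwards_pass": _fmt_opt(record.months_backwards_pass),
        "gait": record.gait.value,
        "spo2": _fmt_opt(record.spo2),
        "resp_rate": _fmt_opt(record.resp_rate),
        "presentations": ";".join(record.presentations),
        "admitted": _fmt_bool(record.admitted),
        "died_within_24h": _fmt_bool(record.died_within_24h),
        "died_in_hospital": _fmt_bool(record.died_in_hospital),
        "day_of_death": _fmt_opt(record.day_of_death),
    }


def row_to_record(row: dict[str, str]) -> PatientRecord:
    def opt(name: str) -> str | None:
        v = row[name]
        return None if v == "" else v

    spo2 = opt("spo2")
    rr = opt("resp_rate")
    months = opt("months_backwards_pass")
    dod = opt("day_of_death")
    pres = row["presentations"]
    try:
        arrival = datetime.fromisoformat(row["arrival"])
    except ValueError:
        raise ValueError(f"arrival: unparseable timestamp {row['arrival']!r}") from None
    try:
        gait = Gait(row["gait"])
    except ValueError:
        raise ValueError(f"gait: unknown category {row['gait']!r}") from None
    try:
        sex = Sex(row["sex"])
    except ValueError:
        raise ValueError(f"sex: expected male/female, got {row['sex']!r}") from None
    return PatientRecord(
        patient_id=row["patient_id"],
        age=int(row["age"]),
        sex=sex,
        arrival=arrival,
        pregnant=_parse_bool(row["pregnant"], "pregnant"),
        alert=_parse_bool(row["alert"], "alert"),
        attentive=_parse_bool(row["attentive"], "attentive"),
        calm=_parse_bool(row["calm"], "calm"),
        coherent=_parse_bool(row["coherent"], "coherent"),
        months_backwards_pass=(
            None if months is None else _parse_bool(months, "months_backwards_pass")
        ),
        gait=gait,
        spo2=None if spo2 is None else float(spo2),
        resp_rate=None if rr is None else float(rr),
        presentations=tuple(p for p in pres.split(";") if p),
        admitted=_parse_bool(row["admitted"], "admitted"),
        died_within_24h=_parse_bool(row["died_within_24h"], "died_within_24h"),
        died_in_hospital=_parse_bool(row["died_in_hospital"], "died_in_hospital"),
        day_of_death=None if dod is None else int(dod),
    )


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write a cohort CSV (documented header; empty cell = missing)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for rec in records:
            writer.writerow(record_to_row(rec))


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV; raises :class:`CohortFileError` listing every
    failing row with its 1-based data row number."""
    path = Path(path)
    records: list[PatientRecord] = []
    errors: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != CSV_COLUMNS:
            raise CohortFileError(
                [f"malformed header: expected {','.join(CSV_COLUMNS)}"]
            )
        for i, row in enumerate(reader, start=1):
            try:
                records.append(row_to_record(row))
            except (ValueError, RecordValidationError) as exc:
                errors.append(f"row {i}: {exc}")
    if errors:
        raise CohortFileError(errors)
    return records


def variant_complete(record: PatientRecord, variant: ScoreVariant) -> bool:
    """True if every component the variant reads is present on the record."""
    if variant is ScoreVariant.KHDS_MONTHS and record.months_backwards_pass is None:
        return False
    if variant is ScoreVariant.KHDS_RESP:
        return record.resp_rate is not None
    return record.spo2 is not None


def analysis_set(
    records: Sequence[PatientRecord], variant: ScoreVariant
) -> list[PatientRecord]:
    """The variant's complete-case subset (records with all components)."""
    return [r for r in records if variant_complete(r, variant)]
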