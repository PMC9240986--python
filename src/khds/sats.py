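"""South African Triage Scale (SATS) presentation taxonomy and urgency ranking.

SATS assigns an arbitrary urgency rank (non-urgent < urgent < very urgent <
emergent) to specific clinical presentations.  This module carries the
taxonomy of presentations as observed in a low-resource emergency/outpatient
setting — a subset of the official SATS discriminator list, with reduced
level of consciousness narrowed to coma — and implements the per-patient
ranking rule: a patient with several ranked presentations takes the highest.

The full official SATS discriminator list and the TEWS vital-sign score are
out of scope.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Iterable, Sequence


class UrgencyLevel(enum.IntEnum):
    """Ordinal SATS urgency rank; comparisons follow the integer value."""

    NON_URGENT = 0
    URGENT = 1
    VERY_URGENT = 2
    EMERGENT = 3

    def __str__(self) -> str:  # stable lower-case token for I/O
        return self.name.lower()


#: Pseudo-code a data source may emit to record an explicit non-urgent
#: ranking (as opposed to "no ranked presentation").  Accepted and ignored
#: by :func:`rank_patient`; not part of :func:`taxonomy`.
NON_URGENT_CODE = "non_urgent"


class UnknownPresentationError(KeyError):
    """A presentation code is not in the taxonomy."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:
        return f"unknown SATS presentation code: {self.code!r}"


@dataclass(frozen=True)
class Presentation:
    code: str
    label: str
    urgency: UrgencyLevel


_TAXONOMY: tuple[Presentation, ...] = (
    # emergent
    Presentation("hypoglycaemia", "Hypoglycaemia", UrgencyLevel.EMERGENT),
    Presentation("apnoea_pre_arrest", "Apnoea/Pre-arrest", UrgencyLevel.EMERGENT),
    Presentation("fitting", "Fitting", UrgencyLevel.EMERGENT),
    # very urgent
    Presentation("severe_breathlessness", "Severe breathlessness", UrgencyLevel.VERY_URGENT),
    Presentation(
        "head_injury",
        "Head injury - open wound and/or suspected skull fracture",
        UrgencyLevel.VERY_URGENT,
    ),
    Presentation("high_energy_transfer_injury", "High energy transfer injury", UrgencyLevel.VERY_URGENT),
    Presentation("severe_pain", "Severe pain", UrgencyLevel.VERY_URGENT),
    Presentation("suspected_stroke", "Suspected stroke", UrgencyLevel.VERY_URGENT),
    Presentation("haemoptysis", "Haemoptysis", UrgencyLevel.VERY_URGENT),
    Presentation("uncontrolled_bleeding", "Uncontrolled bleeding", UrgencyLevel.VERY_URGENT),
    Presentation(
        "coma",
        "Coma (responsive only to pain or unresponsive)",
        UrgencyLevel.VERY_URGENT,
    ),
    Presentation("diabetic_ketoacidosis", "Diabetic keto-acidosis", UrgencyLevel.VERY_URGENT),
    Presentation("burns", "Burns", UrgencyLevel.VERY_URGENT),
    Presentation("poisoning", "Poisoning", UrgencyLevel.VERY_URGENT),
    Presentation("chest_pain", "Chest pain", UrgencyLevel.VERY_URGENT),
    # urgent
    Presentation("abdominal_pain", "Abdominal pain", UrgencyLevel.URGENT),
    Presentation("diabetes_without_ketoacidosis", "Diabetes without keto-acidosis", UrgencyLevel.URGENT),
    Presentation("moderate_pain", "Moderate pain", UrgencyLevel.URGENT),
    Presentation("suspected_fracture", "Suspected fracture", UrgencyLevel.URGENT),
    Presentation("controlled_bleeding", "Controlled bleeding", UrgencyLevel.URGENT),
    Presentation("vomiting", "Vomiting", UrgencyLevel.URGENT),
)

_BY_CODE: dict[str, Presentation] = {p.code: p for p in _TAXONOMY}
assert len(_BY_CODE) == len(_TAXONOMY)  # codes unique


def taxonomy() -> list[Presentation]:
    """Return the 21 ranked presentations (3 emergent, 12 very urgent, 6 urgent).

    Presentations that the observed setting could not record (post-ictal,
    compound fracture, dislocations, stabbings, eye injuries,
    pregnancy-related complaints) are deliberately absent; unknown codes
    raise rather than silently mapping to non-urgent.
    """
    return list(_TAXONOMY)


def get_presentation(code: str) -> Presentation:
    try:
        return _BY_CODE[code]
    except KeyError:
        raise UnknownPresentationError(code) from None


def codes_at(level: UrgencyLevel) -> list[str]:
    """Presentation codes at a given urgency level (empty for NON_URGENT)."""
    return [p.code for p in _TAXONOMY if p.urgency is level]


def rank_patient(presentations: Sequence[str] | Iterable[str]) -> UrgencyLevel:
    """Urgency rank of a patient: the highest rank over their presentations.

    An empty list (or only the explicit ``non_urgent`` pseudo-code) ranks
    NON_URGENT.  Order and duplicates are irrelevant.

    Raises
    ------
    UnknownPresentationError
        If a code is not in the taxonomy.
    """
    level = UrgencyLevel.NON_URGENT
    for code in presentations:
        if code == NON_URGENT_CODE:
            continue
        p = get_presentation(code)
        if p.urgency > level:
            level = p.urgency
    return level


def taxonomy_as_json(indent: int | None = 2) -> str:
    """The taxonomy as JSON (code, label, urgency name) for docs/fixtures."""
    rows = [
        {"code": p.code, "label": p.label, "urgency": str(p.urgency)}
        for p in _TAXONOMY
    ]
    return json.dumps(rows, indent=indent)


def urgency_from_token(token: str) -> UrgencyLevel:
    """Parse a lower-case urgency token (inverse of ``str(level)``)."""
    try:
        return UrgencyLevel[token.strip().upper()]
    except KeyError:
        raise ValueError(f"unknown urgency level: {token!r}") from None
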