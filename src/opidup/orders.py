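"""Core domain types for inpatient PRN opioid orders.

A medication order here is the minimal slice of an inpatient pharmacy feed
that duplicate-indication alerting needs: drug, route, formulation, PRN
indication text, administration instructions, start/end timestamps, and the
verification location class (used to censor operating-room and procedural
orders).  Pain categories are the standard 0-10 numeric-rating-scale bands
used on order templates: mild 1-3, moderate 4-6, severe 7-10, plus the two
combined bands 1-6 and 4-10, patient-controlled analgesia (PCA), and an
"unspecified" bucket for indications that carry no pain-scale range.

Timestamps are timezone-naive ISO 8601 at minute precision: one feed is
assumed to come from a single facility clock.  An order's activity window is
half-open, ``[start_time, end_time)`` — a discontinued order stops
contributing to alerts at its end timestamp.
"""

from __future__ import annotations

import enum
from datetime import datetime
from typing import Optional, Tuple

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class Route(str, enum.Enum):
    """Administration route, normalised to a closed token set."""

    ORAL = "oral"
    INTRAVENOUS = "intravenous"
    OTHER = "other"


class Formulation(str, enum.Enum):
    """Dosage formulation, normalised to a closed token set."""

    TABLET = "tablet"
    SOLUTION = "solution"
    INJECTION = "injection"
    PATCH = "patch"
    OTHER = "other"


class LocationClass(str, enum.Enum):
    """Class of the location where the order was verified."""

    ACUTE_CARE = "acute_care"
    ICU = "icu"
    OPERATING_ROOM = "operating_room"
    PROCEDURAL = "procedural"
    OTHER = "other"


class PainKind(str, enum.Enum):
    """Pain-category kinds recognised on PRN opioid order templates."""

    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"
    MILD_MODERATE = "mild_moderate"
    MODERATE_SEVERE = "moderate_severe"
    PCA = "pca"
    UNSPECIFIED = "unspecified"


#: Inclusive numeric-rating-scale bands for the range-bearing kinds.
SCORE_RANGES: dict[PainKind, Tuple[int, int]] = {
    PainKind.MILD: (1, 3),
    PainKind.MODERATE: (4, 6),
    PainKind.SEVERE: (7, 10),
    PainKind.MILD_MODERATE: (1, 6),
    PainKind.MODERATE_SEVERE: (4, 10),
}

# route / formulation synonym tables used at ingest; unknown tokens -> OTHER
_ROUTE_SYNONYMS = {
    "oral": Route.ORAL,
    "po": Route.ORAL,
    "by mouth": Route.ORAL,
    "intravenous": Route.INTRAVENOUS,
    "iv": Route.INTRAVENOUS,
    "ivp": Route.INTRAVENOUS,
    "iv push": Route.INTRAVENOUS,
}
_FORMULATION_SYNONYMS = {
    "tablet": Formulation.TABLET,
    "tab": Formulation.TABLET,
    "capsule": Formulation.TABLET,
    "solution": Formulation.SOLUTION,
    "liquid": Formulation.SOLUTION,
    "elixir": Formulation.SOLUTION,
    "oral solution": Formulation.SOLUTION,
    "injection": Formulation.INJECTION,
    "injectable": Formulation.INJECTION,
    "inj": Formulation.INJECTION,
    "patch": Formulation.PATCH,
    "transdermal": Formulation.PATCH,
    "transdermal patch": Formulation.PATCH,
}
_LOCATION_SYNONYMS = {
    "acute_care": LocationClass.ACUTE_CARE,
    "acute care": LocationClass.ACUTE_CARE,
    "floor": LocationClass.ACUTE_CARE,
    "icu": LocationClass.ICU,
    "intensive care": LocationClass.ICU,
    "operating_room": LocationClass.OPERATING_ROOM,
    "operating room": LocationClass.OPERATING_ROOM,
    "or": LocationClass.OPERATING_ROOM,
    "procedural": LocationClass.PROCEDURAL,
    "procedure": LocationClass.PROCEDURAL,
    "pacu": LocationClass.PROCEDURAL,
    "cath lab": LocationClass.PROCEDURAL,
}


def normalize_route(token: str) -> Route:
    """Map a free-text route token to the closed :class:`Route` set."""
    return _ROUTE_SYNONYMS.get(token.strip().lower(), Route.OTHER)


def normalize_formulation(token: str) -> Formulation:
    """Map a free-text formulation token to the closed :class:`Formulation` set."""
    return _FORMULATION_SYNONYMS.get(token.strip().lower(), Formulation.OTHER)


def normalize_location(token: str) -> LocationClass:
    """Map a free-text verification-location token to :class:`LocationClass`."""
    return _LOCATION_SYNONYMS.get(token.strip().lower(), LocationClass.OTHER)


class PainCategory(BaseModel):
    """Parsed semantics of a PRN indication: a score band, PCA, or unspecified."""

    model_config = ConfigDict(frozen=True)

    kind: PainKind
    score_range: Optional[Tuple[int, int]] = None

    @model_validator(mode="after")
    def _check_range(self) -> "PainCategory":
        expected = SCORE_RANGES.get(self.kind)
        if expected is None:
            if self.score_range is not None:
                raise ValueError(f"{self.kind.value} carries no score range")
        else:
            if self.score_range is None:
                object.__setattr__(self, "score_range", expected)
            elif tuple(self.score_range) != expected:
                raise ValueError(
                    f"{self.kind.value} must carry score range {expected}, "
                    f"got {self.score_range}"
                )
        if self.score_range is not None:
            lo, hi = self.score_range
            if not (1 <= lo <= hi <= 10):
                raise ValueError("score range bounds must satisfy 1 <= lo <= hi <= 10")
        return self

    @classmethod
    def from_kind(cls, kind: PainKind | str) -> "PainCategory":
        kind = PainKind(kind)
        return cls(kind=kind, score_range=SCORE_RANGES.get(kind))


def categories_overlap(a: PainCategory, b: PainCategory) -> bool:
    """True iff two range-bearing categories share at least one integer score.

    Raises :class:`ValueError` if either category lacks a score range (PCA and
    unspecified categories have no band to compare).
    """
    if a.score_range is None or b.score_range is None:
        raise ValueError("categories_overlap requires score ranges on both sides")
    (alo, ahi), (blo, bhi) = a.score_range, b.score_range
    return alo <= bhi and blo <= ahi


class MedicationOrder(BaseModel):
    """One PRN (or PCA) medication order as seen by the alerting feed."""

    model_config = ConfigDict(frozen=True)

    order_id: str
    patient_id: str
    drug_name: str
    is_opioid: bool = True
    route: Route = Route.OTHER
    formulation: Formulation = Formulation.OTHER
    dose_text: str = ""
    frequency_text: str = ""
    is_prn: bool = True
    is_pca: bool = False
    prn_indication_text: str = ""
    admin_instructions: str = ""
    start_time: datetime
    end_time: Optional[datetime] = None
    verify_location_class: LocationClass = LocationClass.ACUTE_CARE
    linked_group_id: Optional[str] = None

    @field_validator("order_id", "patient_id")
    @classmethod
    def _nonempty_ids(cls, v: str) -> str:
        if not v:
            raise ValueError("identifiers must be nonempty")
        return v

    @model_validator(mode="after")
    def _check_invariants(self) -> "MedicationOrder":
        if self.end_time is not None and self.end_time < self.start_time:
            raise ValueError(
                f"order {self.order_id}: end_time {self.end_time} precedes "
                f"start_time {self.start_time}"
            )
        if self.is_pca and self.route is not Route.INTRAVENOUS:
            raise ValueError(f"order {self.order_id}: PCA orders must be intravenous")
        return self


def is_active(order: MedicationOrder, t: datetime) -> bool:
    """True iff ``t`` falls in the half-open activity window ``[start, end)``.

    Open-ended orders (no ``end_time``) are active at every ``t >= start_time``.
    """
    if t < order.start_time:
        return False
    return order.end_time is None or t < order.end_time


def is_detection_relevant(order: MedicationOrder) -> bool:
    """True iff the order can contribute to duplicate detection at all:
    an opioid ordered either PRN or as a PCA."""
    return order.is_opioid and (order.is_prn or order.is_pca)
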