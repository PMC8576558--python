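"""The duplicate-indication alert bundle.

Five rules, evaluated over a patient's co-active opioid PRN/PCA orders:

* three *explicit* rules — two or more orders whose indication bands overlap
  the mild (1-3), moderate (4-6) or severe (7-10) level;
* ``"Opioids PRN for pain"`` — at least one co-active order with an unclear
  indication (no pain-scale range) alongside any other order;
* ``"Opioid PRN PCA"`` — a PCA order alongside a separately ordered
  intravenous PRN opioid of any pain level.

Orders verified in an operating room or procedural area are censored before
any rule is evaluated.  Streaming evaluation fires at order-start events and
throttles each (patient, rule) pair to at most one alert per 24 hours.

Rule-bundle versions: version 1 is the bundle as originally launched, whose
unclear-indication rule did not recognise the "breakthrough pain" / "any
pain" forms; version 2 (the default) extends the unclear-indication rule to
those two forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

from .indications import DEFAULT_RULES, ParseRule, classify_order, is_breakthrough_or_any_pain
from .orders import (
    LocationClass,
    MedicationOrder,
    PainKind,
    Route,
    is_active,
    is_detection_relevant,
)

RULE_MILD = "Opioids PRN for mild pain"
RULE_MODERATE = "Opioids PRN for moderate pain"
RULE_SEVERE = "Opioids PRN for severe pain"
RULE_PAIN = "Opioids PRN for pain"
RULE_PCA = "Opioid PRN PCA"

#: Fixed emission order — keeps alert logs reproducible.
RULE_ORDER: tuple[str, ...] = (RULE_MILD, RULE_MODERATE, RULE_SEVERE, RULE_PAIN, RULE_PCA)

_LEVEL_BANDS = {RULE_MILD: (1, 3), RULE_MODERATE: (4, 6), RULE_SEVERE: (7, 10)}

_CENSORED_LOCATIONS = frozenset({LocationClass.OPERATING_ROOM, LocationClass.PROCEDURAL})


@dataclass(frozen=True)
class Alert:
    """One fired rule instance."""

    rule_name: str
    patient_id: str
    fired_at: datetime
    triggering_order_ids: frozenset[str]
    bundle_version: int = 2

    def __post_init__(self) -> None:
        if self.rule_name not in RULE_ORDER:
            raise ValueError(f"unknown rule name: {self.rule_name!r}")
        if len(self.triggering_order_ids) < 2:
            raise ValueError("an alert needs at least two triggering orders")


@dataclass(frozen=True)
class ThrottlePolicy:
    """Alert-fatigue throttle: at most one alert per scope per window.

    ``scope`` is ``"per_rule"`` (one alert per patient per rule name per
    window — the deployed configuration) or ``"per_patient"`` (one alert per
    patient per window regardless of rule, the stricter patient-review mode).
    """

    window: timedelta = timedelta(hours=24)
    scope: str = "per_rule"

    def __post_init__(self) -> None:
        if self.window <= timedelta(0):
            raise ValueError("throttle window must be positive")
        if self.scope not in ("per_rule", "per_patient"):
            raise ValueError(f"unknown throttle scope: {self.scope!r}")


def eligible_orders(
    orders: Iterable[MedicationOrder], t: datetime
) -> list[MedicationOrder]:
    """Opioid PRN/PCA orders active at ``t``, minus censored verification
    locations (operating room, procedural area)."""
    return [
        o
        for o in orders
        if is_detection_relevant(o)
        and is_active(o, t)
        and o.verify_location_class not in _CENSORED_LOCATIONS
    ]


def detect(
    orders: Sequence[MedicationOrder],
    t: datetime,
    bundle_version: int = 2,
    parse_rules: Sequence[ParseRule] = DEFAULT_RULES,
) -> list[Alert]:
    """Evaluate the full bundle for one patient at one time point.

    Returns the fired alerts in the fixed rule order.  All orders must share
    one ``patient_id``; the patient's linked-order-group annotations are
    deliberately ignored (the live data feed carried no linking information).
    """
    patients = {o.patient_id for o in orders}
    if len(patients) > 1:
        raise ValueError(f"detect() expects a single patient, got {sorted(patients)}")
    if not patients:
        return []
    (patient_id,) = patients

    elig = eligible_orders(orders, t)
    if len(elig) < 2:
        return []
    cats = {o.order_id: classify_order(o, parse_rules) for o in elig}

    alerts: list[Alert] = []

    for rule_name, (lo, hi) in _LEVEL_BANDS.items():
        trig = [
            o
            for o in elig
            if cats[o.order_id].score_range is not None
            and cats[o.order_id].score_range[0] <= hi
            and lo <= cats[o.order_id].score_range[1]
        ]
        if len(trig) >= 2:
            alerts.append(
                Alert(
                    rule_name=rule_name,
                    patient_id=patient_id,
                    fired_at=t,
                    triggering_order_ids=frozenset(o.order_id for o in trig),
                    bundle_version=bundle_version,
                )
            )

    unclear = [
        o
        for o in elig
        if cats[o.order_id].kind is PainKind.UNSPECIFIED
        and not o.is_pca
        and (bundle_version >= 2 or not is_breakthrough_or_any_pain(o.prn_indication_text))
    ]
    if unclear:
        # the unclear order duplicates any co-active PRN opioid, so every
        # eligible order is part of the triggering set
        alerts.append(
            Alert(
                rule_name=RULE_PAIN,
                patient_id=patient_id,
                fired_at=t,
                triggering_order_ids=frozenset(o.order_id for o in elig),
                bundle_version=bundle_version,
            )
        )

    pcas = [o for o in elig if o.is_pca]
    iv_partners = [
        o for o in elig if not o.is_pca and o.is_prn and o.route is Route.INTRAVENOUS
    ]
    if pcas and iv_partners:
        alerts.append(
            Alert(
                rule_name=RULE_PCA,
                patient_id=patient_id,
                fired_at=t,
                triggering_order_ids=frozenset(o.order_id for o in pcas + iv_partners),
                bundle_version=bundle_version,
            )
        )

    alerts.sort(key=lambda a: RULE_ORDER.index(a.rule_name))
    return alerts


def stream_detect(
    orders: Sequence[MedicationOrder],
    policy: ThrottlePolicy = ThrottlePolicy(),
    bundle_version: int = 2,
    parse_rules: Sequence[ParseRule] = DEFAULT_RULES,
) -> list[Alert]:
    """Event-driven evaluation over a (possibly multi-patient) order feed.

    The bundle is evaluated at every order-start event against the patient's
    orders, mirroring real-time evaluation on incoming order messages; a
    candidate alert is suppressed when its throttle scope already emitted an
    alert less than ``policy.window`` earlier.  Output is deterministic:
    events are processed in (time, patient, order id) order and alerts are
    emitted in the fixed rule order.
    """
    for o in orders:
        if o.end_time is not None and o.end_time < o.start_time:
            raise ValueError(f"malformed feed: order {o.order_id} ends before it starts")
    seen_ids = [o.order_id for o in orders]
    if len(set(seen_ids)) != len(seen_ids):
        raise ValueError("malformed feed: duplicate order_id values")

    by_patient: dict[str, list[MedicationOrder]] = {}
    for o in orders:
        by_patient.setdefault(o.patient_id, []).append(o)

    events = sorted(
        {(o.start_time, o.patient_id) for o in orders},
        key=lambda e: (e[0], e[1]),
    )

    last_emitted: dict[tuple, datetime] = {}
    log: list[Alert] = []
    for t, patient_id in events:
        for alert in detect(by_patient[patient_id], t, bundle_version, parse_rules):
            key = (
                (patient_id,)
                if policy.scope == "per_patient"
                else (patient_id, alert.rule_name)
            )
            prev = last_emitted.get(key)
            if prev is None or t - prev >= policy.window:
                last_emitted[key] = t
                log.append(alert)
    return log


def patient_flagged(
    alerts: Iterable[Alert],
    patient_id: str,
    interval: tuple[datetime, datetime] | None = None,
) -> bool:
    """Patient-level test-positive state: did any alert fire for this patient
    within the closed interval ``[t0, t1]`` (or ever, if no interval)?"""
    for a in alerts:
        if a.patient_id != patient_id:
            continue
        if interval is None or interval[0] <= a.fired_at <= interval[1]:
            return True
    return False
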