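"""Shared helpers: an order factory, a random order-set generator, and an
independent brute-force re-statement of the five bundle rules used as the
oracle for detector equivalence tests."""

from __future__ import annotations

import random
from datetime import datetime, timedelta

import pytest

from opidup.orders import Formulation, LocationClass, MedicationOrder, PainKind, Route
from opidup.synthetic import indication_text

T0 = datetime(2018, 9, 6, 8, 0)

_SCORES = {
    PainKind.MILD: set(range(1, 4)),
    PainKind.MODERATE: set(range(4, 7)),
    PainKind.SEVERE: set(range(7, 11)),
    PainKind.MILD_MODERATE: set(range(1, 7)),
    PainKind.MODERATE_SEVERE: set(range(4, 11)),
}


def mk_order(
    order_id: str = "O1",
    patient_id: str = "P1",
    kind: PainKind | None = PainKind.SEVERE,
    *,
    drug: str = "oxycodone",
    route: Route = Route.ORAL,
    formulation: Formulation = Formulation.TABLET,
    is_opioid: bool = True,
    is_prn: bool = True,
    is_pca: bool = False,
    text: str | None = None,
    instructions: str = "",
    start: datetime = T0,
    end: datetime | None = T0 + timedelta(days=4),
    location: LocationClass = LocationClass.ACUTE_CARE,
    linked_group_id: str | None = None,
) -> MedicationOrder:
    """Build a valid order with compact syntax; ``kind`` renders the
    templated indication text unless ``text`` overrides it."""
    if is_pca:
        route = Route.INTRAVENOUS
        kind = PainKind.PCA
    if text is None:
        text = indication_text(kind) if kind is not None else ""
    return MedicationOrder(
        order_id=order_id,
        patient_id=patient_id,
        drug_name=drug,
        is_opioid=is_opioid,
        route=route,
        formulation=formulation,
        is_prn=is_prn,
        is_pca=is_pca,
        prn_indication_text=text,
        admin_instructions=instructions,
        start_time=start,
        end_time=end,
        verify_location_class=location,
        linked_group_id=linked_group_id,
    )


def random_order_set(rng: random.Random, max_orders: int = 8):
    """A random single-patient order set plus the generating ground truth
    (kind and breakthrough-form flag per order), for oracle comparisons."""
    n = rng.randint(0, max_orders)
    orders, truths = [], []
    kinds = list(PainKind)
    for i in range(n):
        kind = rng.choice(kinds)
        is_pca = kind is PainKind.PCA
        breakthrough = False
        text = None
        if kind is PainKind.UNSPECIFIED and rng.random() < 0.35:
            text = rng.choice(["breakthrough pain", "any pain"])
            breakthrough = True
        start = T0 + timedelta(hours=rng.randint(-48, 12))
        end = None if rng.random() < 0.2 else start + timedelta(hours=rng.randint(1, 96))
        orders.append(
            mk_order(
                order_id=f"O{i + 1}",
                kind=kind,
                is_opioid=rng.random() < 0.9,
                is_prn=(not is_pca) and rng.random() < 0.95,
                is_pca=is_pca,
                route=Route.INTRAVENOUS if (is_pca or rng.random() < 0.4) else Route.ORAL,
                text=text,
                start=start,
                end=end,
                location=rng.choice(
                    [LocationClass.ACUTE_CARE] * 7
                    + [LocationClass.ICU, LocationClass.OPERATING_ROOM, LocationClass.PROCEDURAL]
                ),
            )
        )
        truths.append((kind, breakthrough))
    return orders, truths


def brute_force_rule_names(orders, truths, t, bundle_version=2) -> set[str]:
    """Independent enumeration of which bundle rules fire at ``t``.

    Works from the generating kinds (not the parser) and from explicit
    integer score sets (not interval arithmetic).
    """
    active = []
    for o, (kind, breakthrough) in zip(orders, truths):
        if not (o.is_opioid and (o.is_prn or o.is_pca)):
            continue
        if not (o.start_time <= t and (o.end_time is None or t < o.end_time)):
            continue
        if o.verify_location_class.value in ("operating_room", "procedural"):
            continue
        active.append((o, kind, breakthrough))

    fired: set[str] = set()
    if len(active) < 2:
        return fired
    for name, level in (
        ("Opioids PRN for mild pain", PainKind.MILD),
        ("Opioids PRN for moderate pain", PainKind.MODERATE),
        ("Opioids PRN for severe pain", PainKind.SEVERE),
    ):
        matching = [
            1
            for _, kind, _ in active
            if kind in _SCORES and _SCORES[kind] & _SCORES[level]
        ]
        if len(matching) >= 2:
            fired.add(name)
    unclear = [
        1
        for _, kind, breakthrough in active
        if kind is PainKind.UNSPECIFIED and (bundle_version >= 2 or not breakthrough)
    ]
    if unclear:
        fired.add("Opioids PRN for pain")
    has_pca = any(o.is_pca for o, _, _ in active)
    has_iv_prn = any(
        (not o.is_pca) and o.is_prn and o.route is Route.INTRAVENOUS for o, _, _ in active
    )
    if has_pca and has_iv_prn:
        fired.add("Opioid PRN PCA")
    return fired


@pytest.fixture(scope="session")
def step2_fixture():
    from opidup.synthetic import make_step2_fixture

    return make_step2_fixture()
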