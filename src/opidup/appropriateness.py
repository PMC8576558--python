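"""Triage of a detected duplicate set into the five-category intervention schema.

A duplicate set (two or more co-active PRN opioid orders covering the same
pain level) is judged on three order attributes:

* **same route and formulation** — any pair of orders in the set sharing both
  tokens is an outright duplicate that should be pared down to one order;
* **clear administration instructions** — every order carries conditional
  guidance telling the bedside nurse when to choose it over the alternative;
* **linked orders** — all orders sit in one EHR linked-order group, whose
  "OR" logic warns nurses about back-to-back administration.

Category mapping (different route/formulation unless stated):

====  ==========================  ======================================
 #    attributes                  recommended intervention
====  ==========================  ======================================
 1    clear + linked              none needed (the only appropriate case)
 2    unclear, linked             clarify administration instructions
 3    clear, unlinked             add orders to a linked order group
 4    unclear, unlinked           clarify instructions and link orders
 5    same route & formulation    discontinue all but one duplicate order
====  ==========================  ======================================

Linking is visible only here, at the chart-review layer: the real-time
detector never sees ``linked_group_id`` because the live order feed carried
no linking information.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Mapping, Optional, Sequence

from .orders import Formulation, MedicationOrder, Route, is_active


class Intervention(str, enum.Enum):
    NONE = "none"
    CLARIFY_INSTRUCTIONS = "clarify_instructions"
    LINK_ORDERS = "link_orders"
    CLARIFY_AND_LINK = "clarify_and_link"
    DISCONTINUE_ALL_BUT_ONE = "discontinue_all_but_one"


_CATEGORY_TABLE: dict[tuple[bool, bool], tuple[int, Intervention]] = {
    # (clear_instructions, linked) for different-formulation sets
    (True, True): (1, Intervention.NONE),
    (False, True): (2, Intervention.CLARIFY_INSTRUCTIONS),
    (True, False): (3, Intervention.LINK_ORDERS),
    (False, False): (4, Intervention.CLARIFY_AND_LINK),
}

#: Default instruction templates keyed by (route, formulation).
INSTRUCTION_TEMPLATES: dict[tuple[Route, Formulation], str] = {
    (Route.ORAL, Formulation.TABLET): "Give if patient can receive oral tablet medication.",
    (Route.ORAL, Formulation.SOLUTION): (
        "Give if patient cannot receive oral tablet medication "
        "but can receive oral solution medication."
    ),
    (Route.INTRAVENOUS, Formulation.INJECTION): (
        "Give if patient is not able to receive oral medication."
    ),
}

GENERIC_TEMPLATE = (
    "Clarify with the prescriber: specify the conditions under which this "
    "order should be used instead of its alternatives."
)

#: Patterns whose presence marks admin instructions as "clear": conditional
#: give-if phrasing, as in the default templates.  Editable per site.
DEFAULT_CLEAR_PATTERNS: tuple[str, ...] = (r"\bgive\s+if\b", r"\buse\s+if\b")


@dataclass(frozen=True)
class DuplicateAssessment:
    """Outcome of triaging one duplicate set."""

    patient_id: str
    order_ids: tuple[str, ...]
    category: int
    same_route_and_formulation: bool
    clear_instructions: bool
    linked: bool
    appropriate: bool
    intervention: Intervention


def has_clear_instructions(
    order: MedicationOrder, patterns: Sequence[str] = DEFAULT_CLEAR_PATTERNS
) -> bool:
    """Nonempty admin instructions matching a conditional-guidance pattern."""
    text = order.admin_instructions.strip()
    return bool(text) and any(re.search(p, text, re.IGNORECASE) for p in patterns)


def assess(
    dup_orders: Iterable[MedicationOrder],
    clear_patterns: Sequence[str] = DEFAULT_CLEAR_PATTERNS,
) -> DuplicateAssessment:
    """Classify a duplicate set into categories 1-5.

    Attribute semantics: *same route and formulation* holds if any pair in
    the set shares both tokens (that pair alone is the hard duplicate);
    *clear* requires conditional instructions on every order; *linked*
    requires all orders to share one present linked-order-group id.  Only
    category 1 is appropriate.  Permutation-invariant in the input set.
    """
    orders = sorted(dup_orders, key=lambda o: o.order_id)
    if len(orders) < 2:
        raise ValueError("assess() needs a duplicate set of at least two orders")
    patients = {o.patient_id for o in orders}
    if len(patients) > 1:
        raise ValueError("assess() expects a single patient's duplicate set")

    same_rf = any(
        a.route is b.route and a.formulation is b.formulation
        for i, a in enumerate(orders)
        for b in orders[i + 1 :]
    )
    clear = all(has_clear_instructions(o, clear_patterns) for o in orders)
    group_ids = {o.linked_group_id for o in orders}
    linked = len(group_ids) == 1 and None not in group_ids

    if same_rf:
        category, intervention = 5, Intervention.DISCONTINUE_ALL_BUT_ONE
    else:
        category, intervention = _CATEGORY_TABLE[(clear, linked)]

    return DuplicateAssessment(
        patient_id=orders[0].patient_id,
        order_ids=tuple(o.order_id for o in orders),
        category=category,
        same_route_and_formulation=same_rf,
        clear_instructions=clear,
        linked=linked,
        appropriate=category == 1,
        intervention=intervention,
    )


def recommend_instruction(order: MedicationOrder) -> str:
    """Suggested administration-instruction text for an order lacking one,
    keyed by route and formulation; unknown combinations get a generic
    prescriber-clarification placeholder."""
    return INSTRUCTION_TEMPLATES.get((order.route, order.formulation), GENERIC_TEMPLATE)


def discontinuation_rationale(
    dup_orders: Iterable[MedicationOrder],
    at: Optional[datetime] = None,
    extras: Optional[Mapping[str, Mapping[str, bool]]] = None,
) -> list[tuple[str, tuple[str, ...]]]:
    """Rank a category-5 set's orders as discontinuation candidates.

    Candidates (orders still active at ``at``, or all orders if ``at`` is
    None) are ranked oldest start first, ties broken by order id, since the
    older of two interchangeable duplicates is the usual discontinuation
    target.  ``extras`` may supply chart facts the feed lacks, keyed by
    order id with boolean flags ``no_recent_administration``,
    ``documented_adverse_event`` and ``no_order_set``; the matching reason
    codes are emitted only when supplied.

    Returns ``[(order_id, reason_codes), ...]`` in rank order.
    """
    orders = list(dup_orders)
    if not orders:
        return []
    candidates = [o for o in orders if at is None or is_active(o, at)]
    candidates.sort(key=lambda o: (o.start_time, o.order_id))
    latest_start = max(o.start_time for o in orders)

    ranked: list[tuple[str, tuple[str, ...]]] = []
    for o in candidates:
        reasons: list[str] = []
        if o.start_time < latest_start:
            reasons.append("older_start_date")
        info = (extras or {}).get(o.order_id, {})
        for key, code in (
            ("no_recent_administration", "no_recent_administration"),
            ("documented_adverse_event", "documented_adverse_event"),
            ("no_order_set", "no_associated_order_set"),
        ):
            if info.get(key):
                reasons.append(code)
        if not reasons:
            reasons.append(
                "sole_active_candidate" if len(candidates) == 1 else "tie_broken_by_order_id"
            )
        ranked.append((o.order_id, tuple(reasons)))
    return ranked
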