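"""Five-category triage of duplicate sets and its intervention mapping."""

from datetime import timedelta
from itertools import permutations, product

import pytest

from opidup.appropriateness import (
    GENERIC_TEMPLATE,
    INSTRUCTION_TEMPLATES,
    Intervention,
    assess,
    discontinuation_rationale,
    recommend_instruction,
)
from opidup.orders import Formulation, PainKind, Route

from conftest import T0, mk_order

CLEAR_ORAL_TAB = "Give if patient can receive oral tablet medication."
CLEAR_IV = "Give if patient is not able to receive oral medication."

# independent restatement of the policy table:
# (clear instructions, linked) -> (category, intervention), different formulations
EXPECTED_DIFFERENT_RF = {
    (True, True): (1, Intervention.NONE),
    (False, True): (2, Intervention.CLARIFY_INSTRUCTIONS),
    (True, False): (3, Intervention.LINK_ORDERS),
    (False, False): (4, Intervention.CLARIFY_AND_LINK),
}


def duplicate_pair(same_rf: bool, clear: bool, linked: bool):
    group = "LG-1" if linked else None
    a = mk_order(
        "O1",
        kind=PainKind.SEVERE,
        drug="oxycodone",
        route=Route.ORAL,
        formulation=Formulation.TABLET,
        instructions=CLEAR_ORAL_TAB if clear else "",
        linked_group_id=group,
    )
    b = mk_order(
        "O2",
        kind=PainKind.SEVERE,
        drug="morphine" if not same_rf else "hydrocodone-acetaminophen",
        route=Route.ORAL if same_rf else Route.INTRAVENOUS,
        formulation=Formulation.TABLET if same_rf else Formulation.INJECTION,
        instructions=(CLEAR_ORAL_TAB if same_rf else CLEAR_IV) if clear else "",
        linked_group_id=group,
    )
    return [a, b]


@pytest.mark.parametrize(
    "same_rf, clear, linked", list(product([False, True], repeat=3))
)
def test_category_truth_table_is_exhaustive(same_rf, clear, linked):
    """All eight attribute combinations map onto the policy's five
    categories; same route+formulation dominates, and only category 1 is
    appropriate."""
    result = assess(duplicate_pair(same_rf, clear, linked))
    if same_rf:
        expected_cat, expected_iv = 5, Intervention.DISCONTINUE_ALL_BUT_ONE
    else:
        expected_cat, expected_iv = EXPECTED_DIFFERENT_RF[(clear, linked)]
    assert result.category == expected_cat
    assert result.intervention is expected_iv
    assert result.appropriate is (expected_cat == 1)
    assert result.same_route_and_formulation is same_rf
    assert result.clear_instructions is clear
    assert result.linked is linked


def test_oral_tablet_plus_oral_solution_can_be_appropriate():
    # same route, different formulations: not a category-5 duplicate
    a = mk_order("O1", kind=PainKind.MODERATE, route=Route.ORAL,
                 formulation=Formulation.TABLET, instructions=CLEAR_ORAL_TAB,
                 linked_group_id="LG-2")
    b = mk_order("O2", kind=PainKind.MODERATE, route=Route.ORAL,
                 formulation=Formulation.SOLUTION,
                 instructions=INSTRUCTION_TEMPLATES[(Route.ORAL, Formulation.SOLUTION)],
                 linked_group_id="LG-2")
    result = assess([a, b])
    assert result.category == 1 and result.appropriate


def test_any_matching_pair_dominates_in_larger_sets():
    trio = duplicate_pair(False, True, True) + [
        mk_order("O3", kind=PainKind.SEVERE, route=Route.ORAL,
                 formulation=Formulation.TABLET, instructions=CLEAR_ORAL_TAB,
                 linked_group_id="LG-1")
    ]
    # O1 and O3 are both oral tablets -> category 5 despite clear+linked
    assert assess(trio).category == 5


def test_assess_is_permutation_invariant():
    orders = duplicate_pair(False, False, False) + [
        mk_order("O3", kind=PainKind.SEVERE, route=Route.ORAL,
                 formulation=Formulation.SOLUTION)
    ]
    results = {tuple(sorted(assess(list(p)).order_ids)) for p in permutations(orders)}
    categories = {assess(list(p)).category for p in permutations(orders)}
    assert len(results) == 1 and len(categories) == 1


def test_assess_contract_violations():
    with pytest.raises(ValueError):
        assess([mk_order("O1")])
    with pytest.raises(ValueError):
        assess([mk_order("O1", "P1"), mk_order("O2", "P2")])


def test_partial_linking_is_not_linked():
    a, b = duplicate_pair(False, True, True)
    b = b.model_copy(update={"linked_group_id": "LG-other"})
    assert assess([a, b]).linked is False
    c = b.model_copy(update={"linked_group_id": None})
    assert assess([a, c]).linked is False


def test_instruction_templates_are_byte_exact():
    oral_tab = mk_order(route=Route.ORAL, formulation=Formulation.TABLET)
    oral_sol = mk_order(route=Route.ORAL, formulation=Formulation.SOLUTION)
    iv = mk_order(route=Route.INTRAVENOUS, formulation=Formulation.INJECTION)
    patch = mk_order(route=Route.OTHER, formulation=Formulation.PATCH)
    assert recommend_instruction(oral_tab) == (
        "Give if patient can receive oral tablet medication."
    )
    assert recommend_instruction(oral_sol) == (
        "Give if patient cannot receive oral tablet medication "
        "but can receive oral solution medication."
    )
    assert recommend_instruction(iv) == (
        "Give if patient is not able to receive oral medication."
    )
    assert recommend_instruction(patch) == GENERIC_TEMPLATE


def test_discontinuation_prefers_older_start():
    older = mk_order("O2", kind=PainKind.SEVERE, start=T0)
    newer = mk_order("O1", kind=PainKind.SEVERE, start=T0 + timedelta(days=2),
                     end=T0 + timedelta(days=6))
    ranked = discontinuation_rationale([newer, older])
    assert ranked[0][0] == "O2"
    assert "older_start_date" in ranked[0][1]


def test_discontinuation_tie_breaks_by_order_id():
    a = mk_order("O2", kind=PainKind.SEVERE)
    b = mk_order("O1", kind=PainKind.SEVERE)
    ranked = discontinuation_rationale([a, b])
    assert [oid for oid, _ in ranked] == ["O1", "O2"]


def test_discontinuation_single_active_candidate():
    ended = mk_order("O1", kind=PainKind.SEVERE, start=T0, end=T0 + timedelta(days=1))
    active = mk_order("O2", kind=PainKind.SEVERE, start=T0, end=T0 + timedelta(days=6))
    ranked = discontinuation_rationale([ended, active], at=T0 + timedelta(days=2))
    assert len(ranked) == 1
    oid, reasons = ranked[0]
    assert oid == "O2" and reasons  # a reason code is always emitted


def test_discontinuation_extra_reason_codes_only_when_supplied():
    a = mk_order("O1", kind=PainKind.SEVERE, start=T0)
    b = mk_order("O2", kind=PainKind.SEVERE, start=T0 + timedelta(days=1))
    plain = discontinuation_rationale([a, b])
    assert all(
        set(r) <= {"older_start_date", "tie_broken_by_order_id"} for _, r in plain
    )
    with_extras = discontinuation_rationale(
        [a, b],
        extras={"O1": {"no_recent_administration": True, "no_order_set": True}},
    )
    assert with_extras[0] == (
        "O1", ("older_start_date", "no_recent_administration", "no_associated_order_set")
    )
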