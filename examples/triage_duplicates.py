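"""Triage detected duplicate sets into the five intervention categories.

Two scenarios: an appropriate oral-tablet/IV pair with clear conditional
instructions in one linked group (category 1), and two interchangeable oral
tablets (category 5) with a ranked discontinuation recommendation.
"""

from datetime import datetime, timedelta

from opidup import (
    MedicationOrder,
    Route,
    Formulation,
    assess,
    discontinuation_rationale,
    recommend_instruction,
)

t0 = datetime(2018, 9, 6, 8, 0)


def order(oid, drug, route, formulation, instructions="", linked=None, start=t0):
    return MedicationOrder(
        order_id=oid,
        patient_id="P001",
        drug_name=drug,
        route=route,
        formulation=formulation,
        prn_indication_text="PRN for severe pain (score 7-10)",
        admin_instructions=instructions,
        start_time=start,
        end_time=start + timedelta(days=5),
        linked_group_id=linked,
    )


appropriate_pair = [
    order("O1", "oxycodone", Route.ORAL, Formulation.TABLET,
          "Give if patient can receive oral tablet medication.", linked="LG-1"),
    order("O2", "morphine", Route.INTRAVENOUS, Formulation.INJECTION,
          "Give if patient is not able to receive oral medication.", linked="LG-1"),
]
a = assess(appropriate_pair)
print(f"Oral tablet + IV, instructed, linked -> category {a.category}, "
      f"appropriate={a.appropriate}, intervention={a.intervention.value}")

hard_duplicate = [
    order("O3", "hydrocodone-acetaminophen", Route.ORAL, Formulation.TABLET),
    order("O4", "oxycodone", Route.ORAL, Formulation.TABLET,
          start=t0 + timedelta(days=2)),
]
b = assess(hard_duplicate)
print(f"Two oral tablets -> category {b.category}, "
      f"intervention={b.intervention.value}")
for oid, reasons in discontinuation_rationale(hard_duplicate):
    print(f"  discontinue candidate {oid}: {', '.join(reasons)}")

bare = hard_duplicate[0]
print(f"\nSuggested instruction for {bare.drug_name}: "
      f"{recommend_instruction(bare)!r}")
print(
    "\nCategory 1 is the only appropriate duplication; category 5 sets are"
    "\npared down starting with the order with the older start date."
)
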