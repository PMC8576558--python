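"""Fire the duplicate-indication alert bundle over a tiny order stream.

Builds one patient's order history — two intravenous PRN opioids for severe
pain, then a third severe-pain order the next day — and shows both the
point-in-time evaluation and the throttled streaming evaluation.
"""

from datetime import datetime, timedelta

from opidup import MedicationOrder, Route, Formulation, detect, stream_detect

t0 = datetime(2018, 9, 6, 8, 0)


def order(oid, drug, text, start, route=Route.INTRAVENOUS):
    return MedicationOrder(
        order_id=oid,
        patient_id="P001",
        drug_name=drug,
        route=route,
        formulation=Formulation.INJECTION,
        prn_indication_text=text,
        start_time=start,
        end_time=start + timedelta(days=4),
    )


orders = [
    order("O1", "hydromorphone", "PRN for severe pain (score 7-10)", t0),
    order("O2", "fentanyl", "PRN for severe pain (score 7-10)", t0 + timedelta(hours=2)),
    order("O3", "morphine", "PRN for severe pain (score 7-10)", t0 + timedelta(hours=30)),
]

print("Point-in-time evaluation at 11:00 on day 1:")
for alert in detect(orders, t0 + timedelta(hours=3)):
    print(f"  {alert.rule_name}: orders {sorted(alert.triggering_order_ids)}")

print("\nStreaming evaluation with the 24-hour throttle:")
for alert in stream_detect(orders):
    print(f"  {alert.fired_at}  {alert.rule_name}: {sorted(alert.triggering_order_ids)}")

print(
    "\nThe severe-pain rule fires once when the second order arrives; the"
    "\nthird order keeps the duplication alive, so after the 24-hour window"
    "\nexpires the same rule fires again for the same patient."
)
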