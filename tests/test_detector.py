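"""Alert-bundle semantics: rule firing, censoring, throttling, streaming."""

import random
from datetime import timedelta

import pytest

from opidup.detector import (
    RULE_MILD,
    RULE_MODERATE,
    RULE_ORDER,
    RULE_PAIN,
    RULE_PCA,
    RULE_SEVERE,
    ThrottlePolicy,
    detect,
    eligible_orders,
    patient_flagged,
    stream_detect,
)
from opidup.orders import Formulation, LocationClass, PainKind, Route

from conftest import T0, brute_force_rule_names, mk_order, random_order_set


def rule_names(alerts):
    return [a.rule_name for a in alerts]


def test_two_severe_orders_fire_severe_alert():
    orders = [
        mk_order("O1", kind=PainKind.SEVERE, drug="hydromorphone", route=Route.INTRAVENOUS,
                 formulation=Formulation.INJECTION),
        mk_order("O2", kind=PainKind.SEVERE, drug="fentanyl", route=Route.INTRAVENOUS,
                 formulation=Formulation.INJECTION),
    ]
    alerts = detect(orders, T0 + timedelta(hours=1))
    assert rule_names(alerts) == [RULE_SEVERE]
    assert alerts[0].triggering_order_ids == {"O1", "O2"}


def test_unclear_indication_fires_implicit_pain_alert():
    orders = [
        mk_order("O1", text="PRN for pain", drug="hydrocodone-acetaminophen"),
        mk_order("O2", kind=PainKind.SEVERE, drug="morphine"),
    ]
    assert rule_names(detect(orders, T0)) == [RULE_PAIN]


def test_pca_with_iv_partner_fires_pca_alert():
    orders = [
        mk_order("O1", is_pca=True, drug="hydromorphone", text=""),
        mk_order("O2", kind=PainKind.SEVERE, drug="morphine", route=Route.INTRAVENOUS),
    ]
    assert rule_names(detect(orders, T0)) == [RULE_PCA]


def test_pca_with_oral_partner_does_not_fire():
    orders = [
        mk_order("O1", is_pca=True, drug="hydromorphone", text=""),
        mk_order("O2", kind=PainKind.SEVERE, drug="oxycodone", route=Route.ORAL),
    ]
    assert detect(orders, T0) == []


def test_single_order_never_fires():
    assert detect([mk_order(kind=PainKind.MODERATE, drug="tramadol")], T0) == []


def test_combined_band_duplicates_overlapping_levels():
    orders = [
        mk_order("O1", kind=PainKind.MODERATE_SEVERE),
        mk_order("O2", kind=PainKind.SEVERE),
    ]
    assert rule_names(detect(orders, T0)) == [RULE_SEVERE]
    orders.append(mk_order("O3", kind=PainKind.MODERATE))
    # moderate now also duplicated through the combined band
    assert rule_names(detect(orders, T0)) == [RULE_MODERATE, RULE_SEVERE]


def test_censoring_of_operating_room_and_procedural_orders():
    sev_or = mk_order("O1", kind=PainKind.SEVERE, location=LocationClass.OPERATING_ROOM)
    sev_proc = mk_order("O2", kind=PainKind.SEVERE, location=LocationClass.PROCEDURAL)
    sev = mk_order("O3", kind=PainKind.SEVERE)
    ended = mk_order("O4", kind=PainKind.SEVERE, end=T0 + timedelta(hours=1))
    t = T0 + timedelta(hours=2)
    assert eligible_orders([sev_or, sev_proc, sev, ended], t) == [sev]
    assert detect([sev_or, sev], t) == []


def test_detect_rejects_mixed_patients():
    with pytest.raises(ValueError):
        detect([mk_order("O1", "P1"), mk_order("O2", "P2")], T0)


def test_bundle_version_gates_breakthrough_forms():
    orders = [
        mk_order("O1", text="breakthrough pain"),
        mk_order("O2", kind=PainKind.SEVERE),
    ]
    assert detect(orders, T0, bundle_version=1) == []
    assert rule_names(detect(orders, T0, bundle_version=2)) == [RULE_PAIN]


def test_detector_matches_bruteforce_oracle():
    """Random single-patient sets of <=8 orders: detect() must fire exactly
    the rules an independent score-set enumeration fires, never reference a
    censored order, and ignore linked-group annotations."""
    rng = random.Random(20180906)
    for _ in range(400):
        orders, truths = random_order_set(rng)
        t = T0 + timedelta(hours=rng.randint(-24, 96))
        for version in (1, 2):
            alerts = detect(orders, t, bundle_version=version)
            assert set(rule_names(alerts)) == brute_force_rule_names(
                orders, truths, t, version
            )
            assert rule_names(alerts) == sorted(
                rule_names(alerts), key=RULE_ORDER.index
            )
            censored = {
                o.order_id
                for o in orders
                if o.verify_location_class
                in (LocationClass.OPERATING_ROOM, LocationClass.PROCEDURAL)
            }
            for a in alerts:
                assert len(a.triggering_order_ids) >= 2
                assert not (a.triggering_order_ids & censored)
        # linking-blindness: annotating a shared group changes nothing
        linked = [o.model_copy(update={"linked_group_id": "LG-X"}) for o in orders]
        assert rule_names(detect(linked, t)) == rule_names(detect(orders, t))


def test_adding_an_order_is_monotone():
    rng = random.Random(13)
    for _ in range(200):
        orders, truths = random_order_set(rng, max_orders=6)
        t = T0 + timedelta(hours=rng.randint(0, 72))
        before = set(rule_names(detect(orders, t)))
        extra, _ = random_order_set(rng, max_orders=1)
        if not extra:
            continue
        extra_order = extra[0].model_copy(update={"order_id": "O99"})
        after = set(rule_names(detect(orders + [extra_order], t)))
        assert before <= after


def test_throttle_suppresses_within_24h():
    orders = [
        mk_order("O1", kind=PainKind.SEVERE, start=T0, end=T0 + timedelta(days=4)),
        mk_order("O2", kind=PainKind.SEVERE, start=T0, end=T0 + timedelta(days=4)),
        mk_order("O3", kind=PainKind.SEVERE, start=T0 + timedelta(hours=6),
                 end=T0 + timedelta(days=4)),
    ]
    log = stream_detect(orders, bundle_version=1)
    assert [a.rule_name for a in log] == [RULE_SEVERE]
    assert log[0].fired_at == T0


def test_throttle_releases_after_window():
    orders = [
        mk_order("O1", kind=PainKind.SEVERE, start=T0, end=T0 + timedelta(days=4)),
        mk_order("O2", kind=PainKind.SEVERE, start=T0, end=T0 + timedelta(days=4)),
        mk_order("O3", kind=PainKind.SEVERE, start=T0 + timedelta(hours=26),
                 end=T0 + timedelta(days=4)),
    ]
    log = stream_detect(orders)
    assert [a.fired_at for a in log] == [T0, T0 + timedelta(hours=26)]


def test_distinct_rules_throttle_independently_by_default():
    orders = [
        mk_order("O1", kind=PainKind.SEVERE),
        mk_order("O2", kind=PainKind.SEVERE),
        mk_order("O3", kind=PainKind.MODERATE, start=T0 + timedelta(hours=2)),
        mk_order("O4", kind=PainKind.MODERATE, start=T0 + timedelta(hours=2)),
    ]
    per_rule = stream_detect(orders)
    assert [a.rule_name for a in per_rule] == [RULE_SEVERE, RULE_MODERATE]
    per_patient = stream_detect(orders, policy=ThrottlePolicy(scope="per_patient"))
    assert [a.rule_name for a in per_patient] == [RULE_SEVERE]


def test_empty_feed_and_non_opioid_feed():
    assert stream_detect([]) == []
    feed = [
        mk_order("O1", is_opioid=False),
        mk_order("O2", is_opioid=False),
    ]
    assert stream_detect(feed) == []


def test_stream_rejects_duplicate_order_ids():
    with pytest.raises(ValueError):
        stream_detect([mk_order("O1"), mk_order("O1")])


def test_throttle_bound_holds_on_random_feeds():
    """In every emitted log, consecutive alerts for one (patient, rule) pair
    are at least the throttle window apart."""
    rng = random.Random(99)
    window = timedelta(hours=24)
    for _ in range(60):
        feed = []
        for p in range(rng.randint(1, 4)):
            orders, _ = random_order_set(rng)
            for o in orders:
                feed.append(
                    o.model_copy(
                        update={
                            "patient_id": f"P{p + 1}",
                            "order_id": f"P{p + 1}-{o.order_id}",
                        }
                    )
                )
        log = stream_detect(feed, policy=ThrottlePolicy(window=window))
        times: dict[tuple, list] = {}
        for a in log:
            times.setdefault((a.patient_id, a.rule_name), []).append(a.fired_at)
        for fired in times.values():
            assert fired == sorted(fired)
            assert all(b - a >= window for a, b in zip(fired, fired[1:]))


def test_patient_flagged_interval_is_closed():
    orders = [
        mk_order("O1", kind=PainKind.MODERATE, start=T0 + timedelta(days=1)),
        mk_order("O2", kind=PainKind.MODERATE, start=T0 + timedelta(days=1)),
    ]
    log = stream_detect(orders)
    fired = log[0].fired_at
    assert patient_flagged(log, "P1", (fired, fired + timedelta(days=1)))
    assert patient_flagged(log, "P1", (fired - timedelta(days=1), fired))
    assert not patient_flagged(log, "P1", (fired + timedelta(minutes=1), fired + timedelta(days=1)))
    assert not patient_flagged(log, "P2", None)
    assert not patient_flagged([], "P1", None)
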