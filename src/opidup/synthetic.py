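"""Seeded synthetic inpatient opioid order streams with ground-truth labels.

The generator emulates a cross-sectional validation cohort: a few hundred
inpatients observed over a 5-day window, each carrying a Poisson number of
background PRN opioid orders whose indication categories follow the
order-level mix observed on adult acute-care and ICU floors (moderate and
severe dominate).  A configurable fraction of patients additionally carries
one planted duplicate set whose level follows the duplicate-type mix seen in
chart review (moderate / severe / both / unclear-indication), together with
the triage attribute triple (same route+formulation, clear instructions,
linked) so the appropriateness classifier can be exercised end to end.

Background orders are placed so that they never form a duplicate among
themselves or with a planted set: when a freshly drawn order would co-occur
with a conflicting order, its window is shifted past the conflict.  With all
noise modes off, the detector therefore recovers the planted labels exactly
(sensitivity = specificity = 100%).

Noise modes produce the realistic failure causes:

* ``parser_evading`` (FN under rule-bundle v1): a planted order's indication
  is rewritten to "breakthrough pain", a form the original bundle did not
  recognise;
* ``procedural_verification`` (FN): one planted order is verified in an
  operating room and is censored away from the detector;
* ``chart_only`` (FN): the duplicate is visible to chart review but never
  enters the order feed;
* ``transient_duplicate`` (FP): a reference-negative patient briefly holds a
  second overlapping order that is discontinued again before chart review.

``make_step2_fixture`` builds a fixed 201-patient cohort (34 chart-review
duplicate patients — 12 moderate, 9 severe, 7 both, 6 unclear — with one
censoring miss and one breakthrough-form miss, plus 7 transient false
positives) whose patient-level evaluation under rule-bundle v1 yields the
2x2 table TP=32, FP=7, FN=2, TN=160.
"""

from __future__ import annotations

import math
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .appropriateness import INSTRUCTION_TEMPLATES
from .orders import (
    Formulation,
    LocationClass,
    MedicationOrder,
    PainKind,
    Route,
    SCORE_RANGES,
)

_DEFAULT_CATEGORY_MIX = {
    PainKind.MILD: 0.01,
    PainKind.MODERATE: 0.51,
    PainKind.SEVERE: 0.39,
    PainKind.MILD_MODERATE: 0.01,
    PainKind.MODERATE_SEVERE: 0.02,
    PainKind.PCA: 0.02,
    PainKind.UNSPECIFIED: 0.04,
}

_DEFAULT_DUPLICATE_TYPE_MIX = {
    "moderate": 0.35,
    "severe": 0.26,
    "both": 0.21,
    "unspecified": 0.18,
}

_ORAL_OPIOIDS = (
    "oxycodone",
    "hydrocodone-acetaminophen",
    "tramadol",
    "morphine",
    "acetaminophen-codeine",
)
_IV_OPIOIDS = ("morphine", "hydromorphone", "fentanyl")

_KIND_LABEL = {
    PainKind.MILD: "mild",
    PainKind.MODERATE: "moderate",
    PainKind.SEVERE: "severe",
    PainKind.MILD_MODERATE: "mild to moderate",
    PainKind.MODERATE_SEVERE: "moderate to severe",
}

_RF_CYCLE = (
    (Route.ORAL, Formulation.TABLET),
    (Route.INTRAVENOUS, Formulation.INJECTION),
    (Route.ORAL, Formulation.SOLUTION),
)

LABEL_COLUMNS = (
    "patient_id",
    "has_duplicate",
    "duplicate_kinds",
    "same_route_and_formulation",
    "clear_instructions",
    "linked",
    "noise_mode",
)


def indication_text(kind: PainKind) -> str:
    """Render the templated indication string for a pain kind."""
    if kind is PainKind.PCA:
        return ""
    if kind is PainKind.UNSPECIFIED:
        return "PRN for pain"
    lo, hi = SCORE_RANGES[kind]
    return f"PRN for {_KIND_LABEL[kind]} pain (score {lo}-{hi})"


class NoiseConfig(BaseModel):
    """Per-patient probabilities of the four documented noise modes."""

    model_config = ConfigDict(frozen=True)

    parser_evading: float = Field(0.0, ge=0.0, le=1.0)
    procedural_verification: float = Field(0.0, ge=0.0, le=1.0)
    chart_only: float = Field(0.0, ge=0.0, le=1.0)
    transient_duplicate: float = Field(0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _fn_modes_sum(self) -> "NoiseConfig":
        s = self.parser_evading + self.procedural_verification + self.chart_only
        if s > 1.0 + 1e-9:
            raise ValueError("FN noise-mode probabilities may not sum past 1")
        return self


class GeneratorConfig(BaseModel):
    """Study conditions for one synthetic cohort."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(201, gt=0)
    mean_opioid_orders_per_patient: float = Field(1.2, ge=0.0)
    category_mix: dict[PainKind, float] = Field(
        default_factory=lambda: dict(_DEFAULT_CATEGORY_MIX)
    )
    duplicate_prevalence: float = Field(0.17, ge=0.0, le=1.0)
    duplicate_type_mix: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_DUPLICATE_TYPE_MIX)
    )
    p_same_route_formulation: float = Field(0.5, ge=0.0, le=1.0)
    p_clear_instructions: float = Field(0.4, ge=0.0, le=1.0)
    p_linked: float = Field(0.15, ge=0.0, le=1.0)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    window_days: int = Field(5, gt=0)
    window_start: datetime = datetime(2018, 9, 6, 0, 0)
    seed: int = 0

    @model_validator(mode="after")
    def _mixes_normalised(self) -> "GeneratorConfig":
        for name, mix in (
            ("category_mix", self.category_mix),
            ("duplicate_type_mix", self.duplicate_type_mix),
        ):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} probabilities must be nonnegative")
        unknown = set(self.duplicate_type_mix) - {"moderate", "severe", "both", "unspecified"}
        if unknown:
            raise ValueError(f"unknown duplicate types: {sorted(unknown)}")
        return self


def _pair_conflicts(
    a_kind: PainKind,
    a_pca: bool,
    a_route: Route,
    b_kind: PainKind,
    b_pca: bool,
    b_route: Route,
) -> bool:
    """Would two co-active opioid PRN/PCA orders satisfy any bundle rule?"""
    ra, rb = SCORE_RANGES.get(a_kind), SCORE_RANGES.get(b_kind)
    if ra and rb and ra[0] <= rb[1] and rb[0] <= ra[1]:
        return True
    if a_kind is PainKind.UNSPECIFIED or b_kind is PainKind.UNSPECIFIED:
        return True
    if a_pca and (b_route is Route.INTRAVENOUS or b_pca):
        return True
    if b_pca and a_route is Route.INTRAVENOUS:
        return True
    return False


class _Builder:
    """Accumulates one patient's orders, shifting conflicting background
    windows so no unplanned duplicate pair is ever co-active."""

    def __init__(self, patient_id: str) -> None:
        self.patient_id = patient_id
        self.orders: list[MedicationOrder] = []
        self._n = 0

    def new_id(self) -> str:
        self._n += 1
        return f"{self.patient_id}-O{self._n}"

    def add(self, order: MedicationOrder) -> None:
        self.orders.append(order)

    def add_background(
        self,
        kind: PainKind,
        start: datetime,
        duration: timedelta,
        route: Route,
        formulation: Formulation,
        drug: str,
    ) -> None:
        is_pca = kind is PainKind.PCA
        if is_pca:
            route, formulation = Route.INTRAVENOUS, Formulation.INJECTION
        end = start + duration
        # shift past any conflicting placed order until co-activity is gone
        for _ in range(64):
            clash = [
                o
                for o in self.orders
                if o.start_time < end
                and (o.end_time is None or start < o.end_time)
                and _pair_conflicts(
                    kind,
                    is_pca,
                    route,
                    _kind_of(o),
                    o.is_pca,
                    o.route,
                )
            ]
            if not clash:
                break
            latest = max(o.end_time for o in clash if o.end_time is not None)
            start = latest
            end = start + duration
        self.add(
            MedicationOrder(
                order_id=self.new_id(),
                patient_id=self.patient_id,
                drug_name=drug,
                route=route,
                formulation=formulation,
                dose_text="1 dose",
                frequency_text="every 6 hours",
                is_prn=not is_pca,
                is_pca=is_pca,
                prn_indication_text=indication_text(kind),
                start_time=start,
                end_time=end,
            )
        )


def _kind_of(order: MedicationOrder) -> PainKind:
    # local, import-cycle-free re-derivation for generated orders whose
    # indication text is always templated
    from .indications import classify_order

    return classify_order(order).kind


def _set_kinds(dup_type: str, rng: np.random.Generator) -> list[PainKind]:
    if dup_type == "moderate":
        return [PainKind.MODERATE, PainKind.MODERATE]
    if dup_type == "severe":
        return [PainKind.SEVERE, PainKind.SEVERE]
    if dup_type == "both":
        return [PainKind.MODERATE, PainKind.SEVERE, PainKind.MODERATE_SEVERE]
    partner = PainKind.MODERATE if rng.random() < 0.57 else PainKind.SEVERE
    return [PainKind.UNSPECIFIED, partner]


def _plant_set(
    builder: _Builder,
    kinds: Sequence[PainKind],
    start: datetime,
    attrs: tuple[bool, bool, bool],
    rng_pick: int,
) -> list[MedicationOrder]:
    """Plant one co-active duplicate set with the given attribute triple."""
    same_rf, clear, linked = attrs
    planted: list[MedicationOrder] = []
    group_id = f"LG-{builder.patient_id}" if linked else None
    for i, kind in enumerate(kinds):
        if same_rf:
            route, formulation = Route.ORAL, Formulation.TABLET
        else:
            route, formulation = _RF_CYCLE[i % len(_RF_CYCLE)]
        drug_pool = _ORAL_OPIOIDS if route is Route.ORAL else _IV_OPIOIDS
        drug = drug_pool[(rng_pick + i) % len(drug_pool)]
        instructions = (
            INSTRUCTION_TEMPLATES.get(
                (route, formulation), "Give if alternative order cannot be used."
            )
            if clear
            else ""
        )
        order = MedicationOrder(
            order_id=builder.new_id(),
            patient_id=builder.patient_id,
            drug_name=drug,
            route=route,
            formulation=formulation,
            dose_text="1 dose",
            frequency_text="every 4 hours",
            prn_indication_text=indication_text(kind),
            admin_instructions=instructions,
            start_time=start + timedelta(hours=4 * i),
            end_time=start + timedelta(days=4),
            linked_group_id=group_id,
        )
        builder.add(order)
        planted.append(order)
    return planted


def generate(config: GeneratorConfig) -> tuple[list[MedicationOrder], pd.DataFrame]:
    """Generate an order feed plus per-patient ground-truth labels.

    Returns the feed sorted by (start time, patient, order id) and a labels
    frame with one row per patient (:data:`LABEL_COLUMNS`).  Identical
    configs (including seed) produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    kinds = list(config.category_mix.keys())
    kind_p = np.array([config.category_mix[k] for k in kinds], dtype=float)
    kind_p = kind_p / kind_p.sum()
    dup_types = sorted(config.duplicate_type_mix.keys())
    dup_p = np.array([config.duplicate_type_mix[t] for t in dup_types], dtype=float)
    dup_p = dup_p / dup_p.sum()
    window = timedelta(days=config.window_days)

    noise = config.noise
    orders: list[MedicationOrder] = []
    label_rows: list[dict] = []
    width = max(4, len(str(config.n_patients)))

    for i in range(config.n_patients):
        patient_id = f"P{i + 1:0{width}d}"
        builder = _Builder(patient_id)
        is_dup = bool(rng.random() < config.duplicate_prevalence)
        row: dict = {
            "patient_id": patient_id,
            "has_duplicate": is_dup,
            "duplicate_kinds": "",
            "same_route_and_formulation": None,
            "clear_instructions": None,
            "linked": None,
            "noise_mode": "",
        }

        if is_dup:
            dup_type = dup_types[int(rng.choice(len(dup_types), p=dup_p))]
            set_kinds = _set_kinds(dup_type, rng)
            dup_levels = (
                ["moderate", "severe"] if dup_type == "both" else [dup_type]
            )
            attrs = (
                bool(rng.random() < config.p_same_route_formulation),
                bool(rng.random() < config.p_clear_instructions),
                bool(rng.random() < config.p_linked),
            )
            u = rng.random()
            if u < noise.chart_only:
                mode = "chart_only"
            elif u < noise.chart_only + noise.procedural_verification:
                mode = "procedural_verification"
            elif u < (
                noise.chart_only + noise.procedural_verification + noise.parser_evading
            ):
                mode = "parser_evading"
            else:
                mode = ""
            row["noise_mode"] = mode

            start = config.window_start + timedelta(
                minutes=int(rng.integers(0, int((window - timedelta(days=1)).total_seconds() // 60)))
            )
            if mode != "chart_only":
                planted = _plant_set(
                    builder, set_kinds, start, attrs, int(rng.integers(0, 1000))
                )
                if mode == "procedural_verification":
                    victim = (
                        next(
                            p
                            for p, k in zip(planted, set_kinds)
                            if k is PainKind.MODERATE_SEVERE
                        )
                        if dup_type == "both"
                        else planted[0]
                    )
                    builder.orders[builder.orders.index(victim)] = victim.model_copy(
                        update={"verify_location_class": LocationClass.OPERATING_ROOM}
                    )
                elif mode == "parser_evading":
                    victim = (
                        next(
                            p
                            for p, k in zip(planted, set_kinds)
                            if k in (PainKind.MODERATE_SEVERE, PainKind.UNSPECIFIED)
                        )
                        if dup_type in ("both", "unspecified")
                        else planted[0]
                    )
                    builder.orders[builder.orders.index(victim)] = victim.model_copy(
                        update={"prn_indication_text": "breakthrough pain"}
                    )
                    dup_levels = ["unspecified"]
            row["duplicate_kinds"] = ";".join(sorted(set(dup_levels)))
            row["same_route_and_formulation"] = attrs[0]
            row["clear_instructions"] = attrs[1]
            row["linked"] = attrs[2]
        elif rng.random() < noise.transient_duplicate:
            row["noise_mode"] = "transient_duplicate"
            start = config.window_start + timedelta(
                minutes=int(rng.integers(0, int((window - timedelta(days=1)).total_seconds() // 60)))
            )
            base = MedicationOrder(
                order_id=builder.new_id(),
                patient_id=patient_id,
                drug_name=_ORAL_OPIOIDS[int(rng.integers(0, len(_ORAL_OPIOIDS)))],
                route=Route.ORAL,
                formulation=Formulation.TABLET,
                prn_indication_text=indication_text(PainKind.MODERATE),
                start_time=start,
                end_time=start + timedelta(days=3),
            )
            builder.add(base)
            builder.add(
                MedicationOrder(
                    order_id=builder.new_id(),
                    patient_id=patient_id,
                    drug_name="tramadol",
                    route=Route.ORAL,
                    formulation=Formulation.TABLET,
                    prn_indication_text=indication_text(PainKind.MODERATE),
                    start_time=start + timedelta(hours=6),
                    end_time=start + timedelta(hours=8),
                )
            )

        n_background = int(rng.poisson(config.mean_opioid_orders_per_patient))
        for _ in range(n_background):
            kind = kinds[int(rng.choice(len(kinds), p=kind_p))]
            start = config.window_start + timedelta(
                minutes=int(rng.integers(0, int(window.total_seconds() // 60)))
            )
            duration = timedelta(hours=int(rng.integers(24, 73)))
            route, formulation = _RF_CYCLE[int(rng.integers(0, len(_RF_CYCLE)))]
            drug_pool = _ORAL_OPIOIDS if route is Route.ORAL else _IV_OPIOIDS
            drug = drug_pool[int(rng.integers(0, len(drug_pool)))]
            builder.add_background(kind, start, duration, route, formulation, drug)

        orders.extend(builder.orders)
        label_rows.append(row)

    orders.sort(key=lambda o: (o.start_time, o.patient_id, o.order_id))
    labels = pd.DataFrame(label_rows, columns=list(LABEL_COLUMNS))
    return orders, labels


# --------------------------------------------------------------------------
# Fixed 201-patient accuracy-evaluation cohort


def _fixture_order(
    patient_id: str,
    seq: int,
    kind: PainKind,
    start: datetime,
    end: datetime,
    route: Route = Route.ORAL,
    formulation: Formulation = Formulation.TABLET,
    drug: Optional[str] = None,
    text: Optional[str] = None,
    instructions: str = "",
    linked_group_id: Optional[str] = None,
    location: LocationClass = LocationClass.ACUTE_CARE,
) -> MedicationOrder:
    is_pca = kind is PainKind.PCA
    if is_pca:
        route, formulation = Route.INTRAVENOUS, Formulation.INJECTION
    pool = _ORAL_OPIOIDS if route is Route.ORAL else _IV_OPIOIDS
    return MedicationOrder(
        order_id=f"{patient_id}-O{seq}",
        patient_id=patient_id,
        drug_name=drug or pool[seq % len(pool)],
        route=route,
        formulation=formulation,
        dose_text="1 dose",
        frequency_text="every 6 hours",
        is_prn=not is_pca,
        is_pca=is_pca,
        prn_indication_text=indication_text(kind) if text is None else text,
        admin_instructions=instructions,
        start_time=start,
        end_time=end,
        verify_location_class=location,
        linked_group_id=linked_group_id,
    )


#: attribute triples cycled across planted true-positive sets, covering all
#: five triage categories: (same_rf, clear, linked) -> categories 1..5
_ATTR_CYCLE = (
    (False, True, True),
    (False, False, True),
    (False, True, False),
    (False, False, False),
    (True, False, False),
)

_TN_KIND_CYCLE = (
    PainKind.MODERATE,
    PainKind.SEVERE,
    PainKind.MODERATE,
    PainKind.SEVERE,
    PainKind.MODERATE,
    PainKind.UNSPECIFIED,
    PainKind.MODERATE,
    PainKind.SEVERE,
    PainKind.MODERATE,
    PainKind.PCA,
    PainKind.MODERATE,
    PainKind.SEVERE,
    PainKind.MILD,
    PainKind.MODERATE_SEVERE,
    PainKind.MODERATE,
    PainKind.MILD_MODERATE,
)


def make_step2_fixture() -> tuple[list[MedicationOrder], pd.DataFrame]:
    """Deterministic 201-patient accuracy cohort.

    Chart review (the labels) finds a duplicate for 34 patients: 12 on the
    moderate scale, 9 severe, 7 on both scales, 6 with unclear indications.
    Two of the 34 are invisible to the rule bundle as deployed (one set is
    censored by operating-room verification; one unclear set uses the
    "breakthrough pain" form that bundle v1 ignores) and 7 reference-negative
    patients carry transient duplicates that alert before being discontinued,
    so patient-level evaluation of ``stream_detect(..., bundle_version=1)``
    against the labels yields TP=32, FP=7, FN=2, TN=160.
    """
    base = datetime(2018, 9, 6, 8, 0)
    orders: list[MedicationOrder] = []
    rows: list[dict] = []
    tp_counter = 0

    def planted_attrs() -> tuple[bool, bool, bool]:
        nonlocal tp_counter
        attrs = _ATTR_CYCLE[tp_counter % len(_ATTR_CYCLE)]
        tp_counter += 1
        return attrs

    def plant_pair(
        pid: str,
        kinds: Sequence[PainKind],
        day: int,
        attrs: tuple[bool, bool, bool],
        texts: Optional[Sequence[Optional[str]]] = None,
        locations: Optional[Sequence[LocationClass]] = None,
    ) -> None:
        same_rf, clear, linked = attrs
        group = f"LG-{pid}" if linked else None
        start0 = base + timedelta(days=day)
        for i, kind in enumerate(kinds):
            if same_rf:
                route, formulation = Route.ORAL, Formulation.TABLET
            else:
                route, formulation = _RF_CYCLE[i % len(_RF_CYCLE)]
            instructions = (
                INSTRUCTION_TEMPLATES.get(
                    (route, formulation), "Give if alternative order cannot be used."
                )
                if clear
                else ""
            )
            orders.append(
                _fixture_order(
                    pid,
                    i + 1,
                    kind,
                    start0 + timedelta(hours=4 * i),
                    start0 + timedelta(days=4),
                    route=route,
                    formulation=formulation,
                    text=None if texts is None else texts[i],
                    instructions=instructions,
                    linked_group_id=group,
                    location=LocationClass.ACUTE_CARE
                    if locations is None
                    else locations[i],
                )
            )

    def label(pid: str, dup: bool, kinds: str, attrs, noise: str = "") -> None:
        rows.append(
            {
                "patient_id": pid,
                "has_duplicate": dup,
                "duplicate_kinds": kinds,
                "same_route_and_formulation": None if attrs is None else attrs[0],
                "clear_instructions": None if attrs is None else attrs[1],
                "linked": None if attrs is None else attrs[2],
                "noise_mode": noise,
            }
        )

    idx = 0

    # 12 moderate-scale duplicate patients (all detected)
    for _ in range(12):
        idx += 1
        pid = f"S{idx:03d}"
        attrs = planted_attrs()
        plant_pair(pid, [PainKind.MODERATE, PainKind.MODERATE], idx % 4, attrs)
        label(pid, True, "moderate", attrs)

    # 9 severe-scale duplicate patients; the last is censored (OR-verified)
    for j in range(9):
        idx += 1
        pid = f"S{idx:03d}"
        attrs = planted_attrs()
        if j < 8:
            plant_pair(pid, [PainKind.SEVERE, PainKind.SEVERE], idx % 4, attrs)
            label(pid, True, "severe", attrs)
        else:
            plant_pair(
                pid,
                [PainKind.SEVERE, PainKind.SEVERE],
                idx % 4,
                attrs,
                locations=[LocationClass.ACUTE_CARE, LocationClass.OPERATING_ROOM],
            )
            label(pid, True, "severe", attrs, noise="procedural_verification")

    # 7 patients duplicated on both scales (moderate + severe + combined band)
    for _ in range(7):
        idx += 1
        pid = f"S{idx:03d}"
        attrs = planted_attrs()
        plant_pair(
            pid,
            [PainKind.MODERATE, PainKind.SEVERE, PainKind.MODERATE_SEVERE],
            idx % 4,
            attrs,
        )
        label(pid, True, "moderate;severe", attrs)

    # 6 unclear-indication duplicate patients; the last uses the
    # "breakthrough pain" form that bundle v1 does not recognise
    for j in range(6):
        idx += 1
        pid = f"S{idx:03d}"
        attrs = planted_attrs()
        if j < 5:
            plant_pair(pid, [PainKind.UNSPECIFIED, PainKind.MODERATE], idx % 4, attrs)
            label(pid, True, "unspecified", attrs)
        else:
            plant_pair(
                pid,
                [PainKind.UNSPECIFIED, PainKind.SEVERE],
                idx % 4,
                attrs,
                texts=["breakthrough pain", None],
            )
            label(pid, True, "unspecified", attrs, noise="parser_evading")

    # 7 transient-duplicate patients: alert fires, chart review later finds a
    # single active order (reference negative)
    for _ in range(7):
        idx += 1
        pid = f"S{idx:03d}"
        start0 = base + timedelta(days=idx % 4)
        orders.append(
            _fixture_order(
                pid, 1, PainKind.MODERATE, start0, start0 + timedelta(days=4)
            )
        )
        orders.append(
            _fixture_order(
                pid,
                2,
                PainKind.MODERATE,
                start0 + timedelta(hours=6),
                start0 + timedelta(hours=8),
            )
        )
        label(pid, False, "", None, noise="transient_duplicate")

    # 160 reference-negative patients: mostly one lone order, some none,
    # some with non-duplicative pairs (disjoint pain bands)
    for j in range(160):
        idx += 1
        pid = f"S{idx:03d}"
        start0 = base + timedelta(days=j % 5, hours=j % 7)
        if j % 8 == 7:
            pass  # no opioid PRN orders at all
        elif j % 16 == 2:
            orders.append(
                _fixture_order(pid, 1, PainKind.MILD, start0, start0 + timedelta(days=3))
            )
            orders.append(
                _fixture_order(
                    pid,
                    2,
                    PainKind.SEVERE,
                    start0 + timedelta(hours=4),
                    start0 + timedelta(days=3),
                    route=Route.INTRAVENOUS,
                    formulation=Formulation.INJECTION,
                )
            )
        else:
            orders.append(
                _fixture_order(
                    pid,
                    1,
                    _TN_KIND_CYCLE[j % len(_TN_KIND_CYCLE)],
                    start0,
                    start0 + timedelta(days=3),
                )
            )
        label(pid, False, "", None)

    assert idx == 201
    orders.sort(key=lambda o: (o.start_time, o.patient_id, o.order_id))
    labels = pd.DataFrame(rows, columns=list(LABEL_COLUMNS))
    return orders, labels
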