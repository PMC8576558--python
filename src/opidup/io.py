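"""Readers and writers for order feeds, alert logs, labels and assessments.

Three order-feed dialects share one flat record layout (:data:`FEED_COLUMNS`):

* **CSV** — fixed header, booleans as ``true``/``false``, timestamps as
  minute-precision ISO 8601 (``2018-09-06T08:00``), absent values empty;
* **JSON lines** — one object per order, identical field names, native JSON
  booleans and ``null``;
* **HL7-lite** — a documented, minimal pipe-delimited dialect shaped like an
  HL7 v2 pharmacy-order message (it is *not* a certified HL7 implementation).
  One message per order, blank-line separated::

      MSH|^~\\&|OPIDUP
      PID|1||<patient_id>
      ORC|NW|<order_id>|<linked_group_id>|<start YYYYMMDDHHMM>|<end>|<verify_location>
      RXE|<drug_name>|<dose_text>|<route>|<formulation>|<pca Y/N>|<opioid Y/N>|<prn Y/N>
      TQ1|<frequency_text>
      NTE|1|IND|<prn indication text>
      NTE|2|INS|<admin instructions>

  PID and RXE are mandatory; TQ1/NTE are optional.  Free text may not
  contain the ``|`` delimiter.

Whether a drug is an opioid is taken from the feed when the field is present
and nonempty; otherwise it is resolved against a configurable formulary list
(substring match on the drug name).  Malformed rows are reported with their
line (or message) number; by default they are skipped with a logged warning,
``strict=True`` raises instead.
"""

from __future__ import annotations

import csv
import io as _stdio
import json
import logging
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .appropriateness import DuplicateAssessment
from .detector import Alert
from .orders import (
    MedicationOrder,
    normalize_formulation,
    normalize_location,
    normalize_route,
)

logger = logging.getLogger("opidup")

#: Opioids recognised by default when a feed omits the is_opioid flag.
DEFAULT_OPIOID_FORMULARY: tuple[str, ...] = (
    "tramadol",
    "codeine",
    "hydrocodone",
    "oxycodone",
    "hydromorphone",
    "morphine",
    "fentanyl",
)

FEED_COLUMNS: tuple[str, ...] = (
    "order_id",
    "patient_id",
    "drug_name",
    "is_opioid",
    "route",
    "formulation",
    "dose_text",
    "frequency_text",
    "is_prn",
    "is_pca",
    "prn_indication_text",
    "admin_instructions",
    "start_time",
    "end_time",
    "verify_location_class",
    "linked_group_id",
)

ALERT_COLUMNS = ("rule_name", "patient_id", "fired_at", "triggering_order_ids", "bundle_version")

_TIME_FMT = "%Y-%m-%dT%H:%M"
_HL7_TIME_FMT = "%Y%m%d%H%M"


class FeedParseError(ValueError):
    """A feed row/message that cannot be turned into a valid order."""


def _fmt_time(t: Optional[datetime], fmt: str = _TIME_FMT) -> str:
    return "" if t is None else t.strftime(fmt)


def _parse_time(s: str, fmt: str = _TIME_FMT) -> Optional[datetime]:
    s = s.strip()
    if not s:
        return None
    try:
        return datetime.strptime(s, fmt)
    except ValueError:
        # tolerate second-precision ISO input
        return datetime.fromisoformat(s).replace(second=0, microsecond=0)


def _parse_bool(v, default: Optional[bool] = None) -> Optional[bool]:
    if isinstance(v, bool):
        return v
    s = str(v or "").strip().lower()
    if s in ("true", "t", "yes", "y", "1"):
        return True
    if s in ("false", "f", "no", "n", "0"):
        return False
    if s == "":
        return default
    raise ValueError(f"unparseable boolean: {v!r}")


def is_opioid_drug(
    drug_name: str, formulary: Sequence[str] = DEFAULT_OPIOID_FORMULARY
) -> bool:
    """Substring match of the drug name against the opioid formulary."""
    name = drug_name.lower()
    return any(tok in name for tok in formulary)


def order_to_record(order: MedicationOrder) -> dict:
    """Flatten an order to the shared feed-record layout (JSON-safe values)."""
    return {
        "order_id": order.order_id,
        "patient_id": order.patient_id,
        "drug_name": order.drug_name,
        "is_opioid": order.is_opioid,
        "route": order.route.value,
        "formulation": order.formulation.value,
        "dose_text": order.dose_text,
        "frequency_text": order.frequency_text,
        "is_prn": order.is_prn,
        "is_pca": order.is_pca,
        "prn_indication_text": order.prn_indication_text,
        "admin_instructions": order.admin_instructions,
        "start_time": _fmt_time(order.start_time),
        "end_time": _fmt_time(order.end_time),
        "verify_location_class": order.verify_location_class.value,
        "linked_group_id": order.linked_group_id,
    }


def record_to_order(
    rec: dict, formulary: Sequence[str] = DEFAULT_OPIOID_FORMULARY
) -> MedicationOrder:
    """Build a validated order from one flat feed record."""
    start = _parse_time(str(rec.get("start_time") or ""))
    if start is None:
        raise FeedParseError("missing start_time")
    is_opioid = _parse_bool(rec.get("is_opioid"), default=None)
    if is_opioid is None:
        is_opioid = is_opioid_drug(str(rec.get("drug_name") or ""), formulary)
    linked = rec.get("linked_group_id")
    linked = str(linked).strip() if linked not in (None, "") else None
    return MedicationOrder(
        order_id=str(rec.get("order_id") or ""),
        patient_id=str(rec.get("patient_id") or ""),
        drug_name=str(rec.get("drug_name") or ""),
        is_opioid=is_opioid,
        route=normalize_route(str(rec.get("route") or "")),
        formulation=normalize_formulation(str(rec.get("formulation") or "")),
        dose_text=str(rec.get("dose_text") or ""),
        frequency_text=str(rec.get("frequency_text") or ""),
        is_prn=_parse_bool(rec.get("is_prn"), default=True),
        is_pca=_parse_bool(rec.get("is_pca"), default=False),
        prn_indication_text=str(rec.get("prn_indication_text") or ""),
        admin_instructions=str(rec.get("admin_instructions") or ""),
        start_time=start,
        end_time=_parse_time(str(rec.get("end_time") or "")),
        verify_location_class=normalize_location(str(rec.get("verify_location_class") or "")),
        linked_group_id=linked,
    )


def _collect(
    items: Iterable[tuple[int, dict]],
    formulary: Sequence[str],
    strict: bool,
    unit: str,
) -> list[MedicationOrder]:
    orders: list[MedicationOrder] = []
    for lineno, rec in items:
        try:
            orders.append(record_to_order(rec, formulary))
        except (FeedParseError, ValueError) as exc:
            msg = f"{unit} {lineno}: rejected ({exc})"
            if strict:
                raise FeedParseError(msg) from exc
            logger.warning(msg)
    return orders


def read_feed(
    path: str | Path,
    format: str = "csv",
    formulary: Sequence[str] = DEFAULT_OPIOID_FORMULARY,
    strict: bool = False,
) -> list[MedicationOrder]:
    """Read an order feed in one of the three dialects.

    Returns validated orders; malformed rows are logged with line numbers
    and skipped (or raised, with ``strict=True``).  An empty file yields an
    empty list with a warning.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        logger.warning("feed %s is empty", path)
        return []
    if format == "csv":
        reader = csv.DictReader(_stdio.StringIO(text))
        items = ((i, row) for i, row in enumerate(reader, start=2))
    elif format == "jsonl":
        items = (
            (i, json.loads(line))
            for i, line in enumerate(text.splitlines(), start=1)
            if line.strip()
        )
    elif format == "hl7lite":
        return _read_hl7lite(text, formulary, strict)
    else:
        raise ValueError(f"unknown feed format: {format!r}")
    unit = "line"
    orders = _collect(items, formulary, strict, unit)
    seen: set[str] = set()
    for o in orders:
        if o.order_id in seen:
            raise FeedParseError(f"duplicate order_id in feed: {o.order_id}")
        seen.add(o.order_id)
    return orders


def write_feed(
    orders: Sequence[MedicationOrder], path: str | Path, format: str = "csv"
) -> None:
    """Write an order feed in the CSV, JSONL or HL7-lite dialect."""
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(FEED_COLUMNS))
            writer.writeheader()
            for o in orders:
                rec = order_to_record(o)
                rec = {
                    k: ("" if v is None else str(v).lower() if isinstance(v, bool) else v)
                    for k, v in rec.items()
                }
                writer.writerow(rec)
    elif format == "jsonl":
        with path.open("w") as fh:
            for o in orders:
                fh.write(json.dumps(order_to_record(o)) + "\n")
    elif format == "hl7lite":
        path.write_text("\n\n".join(_to_hl7lite(o) for o in orders) + "\n")
    else:
        raise ValueError(f"unknown feed format: {format!r}")


# ----------------------------------------------------------------- HL7-lite


def _to_hl7lite(order: MedicationOrder) -> str:
    yn = lambda b: "Y" if b else "N"
    segments = [
        "MSH|^~\\&|OPIDUP",
        f"PID|1||{order.patient_id}",
        "ORC|NW|{oid}|{link}|{start}|{end}|{loc}".format(
            oid=order.order_id,
            link=order.linked_group_id or "",
            start=_fmt_time(order.start_time, _HL7_TIME_FMT),
            end=_fmt_time(order.end_time, _HL7_TIME_FMT),
            loc=order.verify_location_class.value,
        ),
        "RXE|{drug}|{dose}|{route}|{form}|{pca}|{opi}|{prn}".format(
            drug=order.drug_name,
            dose=order.dose_text,
            route=order.route.value,
            form=order.formulation.value,
            pca=yn(order.is_pca),
            opi=yn(order.is_opioid),
            prn=yn(order.is_prn),
        ),
        f"TQ1|{order.frequency_text}",
        f"NTE|1|IND|{order.prn_indication_text}",
        f"NTE|2|INS|{order.admin_instructions}",
    ]
    return "\n".join(segments)


def _field(parts: list[str], i: int) -> str:
    return parts[i] if i < len(parts) else ""


def _read_hl7lite(
    text: str, formulary: Sequence[str], strict: bool
) -> list[MedicationOrder]:
    messages = [m for m in text.split("\n\n") if m.strip()]
    items: list[tuple[int, dict]] = []
    for n, message in enumerate(messages, start=1):
        seg: dict[str, list[str]] = {}
        notes: dict[str, str] = {}
        for raw in message.strip().splitlines():
            parts = raw.strip().split("|")
            tag = parts[0]
            if tag == "NTE":
                notes[_field(parts, 2)] = _field(parts, 3)
            else:
                seg.setdefault(tag, parts)
        if "PID" not in seg or "RXE" not in seg:
            msg = f"message {n}: rejected (missing PID or RXE segment)"
            if strict:
                raise FeedParseError(msg)
            logger.warning(msg)
            continue
        orc = seg.get("ORC", ["ORC"])
        rxe = seg["RXE"]
        rec = {
            "patient_id": _field(seg["PID"], 3),
            "order_id": _field(orc, 2),
            "linked_group_id": _field(orc, 3),
            "start_time": "",
            "end_time": "",
            "verify_location_class": _field(orc, 6),
            "drug_name": _field(rxe, 1),
            "dose_text": _field(rxe, 2),
            "route": _field(rxe, 3),
            "formulation": _field(rxe, 4),
            "is_pca": _field(rxe, 5) == "Y",
            "is_opioid": _field(rxe, 6) if _field(rxe, 6) else None,
            "is_prn": _field(rxe, 7) if _field(rxe, 7) else True,
            "frequency_text": _field(seg.get("TQ1", ["TQ1"]), 1),
            "prn_indication_text": notes.get("IND", ""),
            "admin_instructions": notes.get("INS", ""),
        }
        try:
            start = _parse_time(_field(orc, 4), _HL7_TIME_FMT)
            end = _parse_time(_field(orc, 5), _HL7_TIME_FMT)
        except ValueError:
            start = end = None
        rec["start_time"] = _fmt_time(start)
        rec["end_time"] = _fmt_time(end)
        items.append((n, rec))
    return _collect(items, formulary, strict, "message")


# ------------------------------------------------------ alert / label output


def write_alert_log(alerts: Sequence[Alert], path: str | Path, format: str = "csv") -> None:
    """Write an alert log; triggering order ids are semicolon-joined, sorted."""
    rows = [
        {
            "rule_name": a.rule_name,
            "patient_id": a.patient_id,
            "fired_at": _fmt_time(a.fired_at),
            "triggering_order_ids": ";".join(sorted(a.triggering_order_ids)),
            "bundle_version": a.bundle_version,
        }
        for a in alerts
    ]
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(ALERT_COLUMNS))
            writer.writeheader()
            writer.writerows(rows)
    elif format == "jsonl":
        with path.open("w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        raise ValueError(f"unknown alert-log format: {format!r}")


def read_alert_log(path: str | Path, format: str = "csv") -> list[Alert]:
    path = Path(path)
    text = path.read_text()
    if format == "csv":
        rows = list(csv.DictReader(_stdio.StringIO(text)))
    elif format == "jsonl":
        rows = [json.loads(line) for line in text.splitlines() if line.strip()]
    else:
        raise ValueError(f"unknown alert-log format: {format!r}")
    return [
        Alert(
            rule_name=row["rule_name"],
            patient_id=row["patient_id"],
            fired_at=_parse_time(row["fired_at"]),
            triggering_order_ids=frozenset(
                t for t in str(row["triggering_order_ids"]).split(";") if t
            ),
            bundle_version=int(row["bundle_version"]),
        )
        for row in rows
    ]


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    """Write per-patient ground-truth labels as CSV (absent attributes empty)."""
    out = labels.copy()
    for col in out.columns:
        out[col] = out[col].map(
            lambda v: "" if v is None or (isinstance(v, float) and pd.isna(v))
            else str(bool(v)).lower() if isinstance(v, (bool, np.bool_)) else v
        )
    out.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["has_duplicate"] = df["has_duplicate"].map(lambda s: _parse_bool(s, default=False))
    for col in ("same_route_and_formulation", "clear_instructions", "linked"):
        if col in df.columns:
            df[col] = df[col].map(lambda s: _parse_bool(s, default=None))
    return df


def write_assessments(
    assessments: Sequence[DuplicateAssessment], path: str | Path, format: str = "csv"
) -> None:
    """Write appropriateness-triage results (one row per assessed set)."""
    rows = [
        {
            "patient_id": a.patient_id,
            "order_ids": ";".join(a.order_ids),
            "category": a.category,
            "same_route_and_formulation": str(a.same_route_and_formulation).lower(),
            "clear_instructions": str(a.clear_instructions).lower(),
            "linked": str(a.linked).lower(),
            "appropriate": str(a.appropriate).lower(),
            "intervention": a.intervention.value,
        }
        for a in assessments
    ]
    path = Path(path)
    fieldnames = [
        "patient_id",
        "order_ids",
        "category",
        "same_route_and_formulation",
        "clear_instructions",
        "linked",
        "appropriate",
        "intervention",
    ]
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            writer.writerows(rows)
    elif format == "jsonl":
        with path.open("w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        raise ValueError(f"unknown assessment format: {format!r}")
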