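"""Map free-text PRN indication strings to pain categories.

Order templates typically render the indication as e.g. ``"PRN for moderate
pain (score 4-6)"``.  Parsing is deliberately rule-based and total: every
string maps to exactly one :class:`~opidup.orders.PainCategory`.

Precedence:

1. A valid numeric score range anywhere in the text (``"score 4-6"``,
   ``"4-10"``, ``"7 to 10"``) wins over any word label.  A range that matches
   one of the five template bands maps to it directly; an off-template range
   (e.g. ``2-5``) maps to the narrowest enclosing band if that is unique,
   otherwise to ``unspecified``.
2. Word labels, matched case-insensitively through an ordered, editable rule
   table (combined labels like "moderate to severe" before single labels).
3. Anything else — empty text, bare "pain", "breakthrough pain", "any pain",
   or unrecognised prose — is ``unspecified``.

"breakthrough pain" and "any pain" matter downstream: the original alert
bundle (version 1) did not trigger its unclear-indication alert on these two
forms; version 2 does.  :func:`is_breakthrough_or_any_pain` exposes that
distinction to the detector.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .orders import SCORE_RANGES, MedicationOrder, PainCategory, PainKind, is_detection_relevant


@dataclass(frozen=True, order=True)
class ParseRule:
    """One word-label rule: case-insensitive regex pattern -> pain kind.

    Rules are tried in increasing ``priority``; the first match wins.
    """

    priority: int
    pattern: str
    target_kind: PainKind

    def matches(self, text: str) -> bool:
        return re.search(self.pattern, text, flags=re.IGNORECASE) is not None


#: Default word-label rule table covering the standard template vocabulary.
DEFAULT_RULES: tuple[ParseRule, ...] = (
    ParseRule(10, r"mild\s*(?:to|and|through|[-/&])\s*moderate", PainKind.MILD_MODERATE),
    ParseRule(11, r"moderate\s*(?:to|and|through|[-/&])\s*severe", PainKind.MODERATE_SEVERE),
    ParseRule(20, r"\bmild\b", PainKind.MILD),
    ParseRule(21, r"\bmoderate\b", PainKind.MODERATE),
    ParseRule(22, r"\bsevere\b", PainKind.SEVERE),
    ParseRule(30, r"breakthrough", PainKind.UNSPECIFIED),
    ParseRule(31, r"\bany\s+pain\b", PainKind.UNSPECIFIED),
    ParseRule(40, r"\bpain\b", PainKind.UNSPECIFIED),
)

_RANGE_RE = re.compile(r"(\d{1,2})\s*(?:-|–|—|to|through)\s*(\d{1,2})", re.IGNORECASE)
_BREAKTHROUGH_RE = re.compile(r"breakthrough|\bany\s+pain\b", re.IGNORECASE)


def load_rules(path: str | Path) -> tuple[ParseRule, ...]:
    """Load a word-label rule table from a YAML file.

    The file is a list of mappings with keys ``pattern``, ``kind`` and
    ``priority``, e.g.::

        - {pattern: "post[- ]?op pain", kind: unspecified, priority: 35}
    """
    raw = yaml.safe_load(Path(path).read_text())
    rules = [
        ParseRule(int(entry["priority"]), str(entry["pattern"]), PainKind(entry["kind"]))
        for entry in raw
    ]
    return tuple(sorted(rules))


def _extract_score_range(text: str) -> Optional[tuple[int, int]]:
    """Return the first valid ``a-b`` score range in the text, if any.

    A range preceded by the word "score" is preferred over bare ``a-b``
    fragments (which can also appear in dose strings like ``5-325 mg``).
    Valid means ``1 <= a <= b <= 10``.
    """
    candidates: list[tuple[int, tuple[int, int]]] = []
    for m in _RANGE_RE.finditer(text):
        a, b = int(m.group(1)), int(m.group(2))
        if not (1 <= a <= b <= 10):
            continue
        prefix = text[max(0, m.start() - 12) : m.start()].lower()
        scored = "score" in prefix or "scale" in prefix
        candidates.append((0 if scored else 1, (a, b)))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[0])
    return candidates[0][1]


def _kind_for_range(rng: tuple[int, int]) -> PainKind:
    """Map a numeric range to a template band: exact, else narrowest unique
    enclosing band, else unspecified."""
    for kind, band in SCORE_RANGES.items():
        if band == rng:
            return kind
    lo, hi = rng
    enclosing = [
        (bhi - blo, kind)
        for kind, (blo, bhi) in SCORE_RANGES.items()
        if blo <= lo and hi <= bhi
    ]
    if not enclosing:
        return PainKind.UNSPECIFIED
    enclosing.sort()
    if len(enclosing) > 1 and enclosing[0][0] == enclosing[1][0]:
        return PainKind.UNSPECIFIED
    return enclosing[0][1]


def parse_indication(
    text: str, rules: Sequence[ParseRule] = DEFAULT_RULES
) -> PainCategory:
    """Parse a PRN indication string into a :class:`PainCategory`.

    Total function: never raises, every input maps to exactly one kind.
    """
    stripped = text.strip()
    if not stripped:
        return PainCategory.from_kind(PainKind.UNSPECIFIED)
    rng = _extract_score_range(stripped)
    if rng is not None:
        return PainCategory.from_kind(_kind_for_range(rng))
    for rule in sorted(rules):
        if rule.matches(stripped):
            return PainCategory.from_kind(rule.target_kind)
    return PainCategory.from_kind(PainKind.UNSPECIFIED)


def is_breakthrough_or_any_pain(text: str) -> bool:
    """True for the two unclear-indication forms ("breakthrough pain",
    "any pain") that only rule-bundle version 2 alerts on."""
    return _BREAKTHROUGH_RE.search(text) is not None


def classify_order(
    order: MedicationOrder, rules: Sequence[ParseRule] = DEFAULT_RULES
) -> PainCategory:
    """Pain category of a detection-relevant order.

    PCA orders are categorised ``pca`` regardless of indication text; all
    other orders go through :func:`parse_indication`.  Raises
    :class:`ValueError` for orders outside the detection scope (non-opioid,
    or neither PRN nor PCA).
    """
    if not is_detection_relevant(order):
        raise ValueError(
            f"order {order.order_id} is not an opioid PRN/PCA order; "
            "classification is undefined"
        )
    if order.is_pca:
        return PainCategory.from_kind(PainKind.PCA)
    return parse_indication(order.prn_indication_text, rules)
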