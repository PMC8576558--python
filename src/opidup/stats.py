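"""Diagnostic-validation statistics for the alert bundle.

The alert bundle is evaluated like a diagnostic test at the patient level:
pharmacist chart review is the reference standard, "any alert fired" is the
test-positive state.  From the resulting 2x2 table the five standard
performance metrics are derived, each with a Clopper-Pearson exact binomial
confidence interval:

* sensitivity = TP / (TP + FN)
* specificity = TN / (TN + FP)
* PPV         = TP / (TP + FP)
* NPV         = TN / (TN + FN)
* accuracy    = (TP + TN) / N

The Clopper-Pearson interval for x successes in n trials at confidence
1 - alpha is, via the beta quantile function,

    lower = B(alpha/2; x, n - x + 1)        (0 when x = 0)
    upper = B(1 - alpha/2; x + 1, n - x)    (1 when x = n)

One-sided lower bounds use B(alpha; x, n - x + 1); for x = n this reduces to
the closed form alpha**(1/n).

Percent display uses two-stage half-up rounding — to one decimal percent,
then to integer percent — matching how clinical software typically rounds a
one-decimal display value for reporting.  Raw proportions are always kept
alongside.

Time effort per reviewed patient is modelled as a saturated categorical
(cell-means) regression: ordinary least squares of minutes on action-category
indicators without an intercept, so fitted coefficients are per-category mean
minutes and their confidence intervals come from the pooled residual
variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import beta as beta_dist

#: Mutually exclusive pharmacist action categories for time-effort modelling.
ACTION_CATEGORIES: tuple[str, ...] = (
    "no_action",
    "discontinued",
    "advanced_modification",
    "contacted_provider_or_nurse",
)


def percent_display(p: float) -> int:
    """Round a proportion to an integer percent, half-up in two stages
    (one decimal percent first, then integer)."""
    d = Decimal(repr(p * 100.0))
    one_dp = d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return int(one_dp.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Patient-level 2x2 table: alert state vs chart-review reference."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    alert_flags: Sequence[bool], truth_flags: Sequence[bool]
) -> ConfusionMatrix:
    """Cross-tabulate aligned per-patient alert and reference-standard flags."""
    if len(alert_flags) != len(truth_flags):
        raise ValueError(
            f"flag vectors differ in length: {len(alert_flags)} vs {len(truth_flags)}"
        )
    a = np.asarray(alert_flags, dtype=bool)
    t = np.asarray(truth_flags, dtype=bool)
    return ConfusionMatrix(
        tp=int(np.sum(a & t)),
        fp=int(np.sum(a & ~t)),
        fn=int(np.sum(~a & t)),
        tn=int(np.sum(~a & ~t)),
    )


def exact_ci(
    successes: int,
    n: int,
    confidence: float = 0.95,
    sided: str = "two",
) -> Tuple[float, float]:
    """Clopper-Pearson exact binomial interval for ``successes / n``.

    ``sided="two"`` gives the usual equal-tailed interval;
    ``sided="lower_one_sided"`` gives ``(lower_bound, 1.0)`` at the stated
    one-sided confidence level.
    """
    if not (0 <= successes <= n) or n < 1:
        raise ValueError(f"invalid counts: successes={successes}, n={n}")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    if sided == "two":
        lower = 0.0 if successes == 0 else float(
            beta_dist.ppf(alpha / 2.0, successes, n - successes + 1)
        )
        upper = 1.0 if successes == n else float(
            beta_dist.ppf(1.0 - alpha / 2.0, successes + 1, n - successes)
        )
        return lower, upper
    if sided == "lower_one_sided":
        lower = 0.0 if successes == 0 else float(
            beta_dist.ppf(alpha, successes, n - successes + 1)
        )
        return lower, 1.0
    raise ValueError(f"unknown sidedness: {sided!r}")


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its exact confidence interval."""

    successes: int
    n: int
    point: float
    ci_low: float
    ci_high: float

    @property
    def point_pct(self) -> int:
        return percent_display(self.point)

    @property
    def ci_pct(self) -> tuple[int, int]:
        return percent_display(self.ci_low), percent_display(self.ci_high)


def proportion_estimate(
    successes: int, n: int, confidence: float = 0.95
) -> ProportionEstimate:
    lo, hi = exact_ci(successes, n, confidence)
    return ProportionEstimate(successes, n, successes / n, lo, hi)


@dataclass(frozen=True)
class PerformanceReport:
    """The five diagnostic metrics, each with an exact CI."""

    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    ppv: ProportionEstimate
    npv: ProportionEstimate
    accuracy: ProportionEstimate
    confidence: float = 0.95

    def as_dict(self) -> dict:
        out: dict = {"confidence": self.confidence}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            est: ProportionEstimate = getattr(self, name)
            out[name] = {
                "successes": est.successes,
                "n": est.n,
                "proportion": est.point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "percent": est.point_pct,
                "ci_percent": list(est.ci_pct),
            }
        return out

    def to_table(self) -> str:
        lines = ["metric         value(%)  95% CI (%)"]
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            est: ProportionEstimate = getattr(self, name)
            lo, hi = est.ci_pct
            lines.append(f"{name:<14} {est.point_pct:>7}   {lo}-{hi}")
        return "\n".join(lines)


def performance(cm: ConfusionMatrix, confidence: float = 0.95) -> PerformanceReport:
    """Compute the five metrics with Clopper-Pearson intervals.

    Raises :class:`ZeroDivisionError`-flavoured :class:`ValueError` when a
    metric's denominator is zero (e.g. PPV with no alerts at all).
    """
    pairs = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
        "accuracy": (cm.tp + cm.tn, cm.total),
    }
    estimates = {}
    for name, (x, n) in pairs.items():
        if n == 0:
            raise ValueError(f"{name} undefined: denominator is zero")
        estimates[name] = proportion_estimate(x, n, confidence)
    return PerformanceReport(confidence=confidence, **estimates)


@dataclass(frozen=True)
class TimeEffortModel:
    """Per-category mean minutes with pooled-variance OLS confidence intervals."""

    estimates: Mapping[str, tuple[float, float, float]]  # category -> (mean, lo, hi)
    n_per_category: Mapping[str, int]
    confidence: float = 0.95

    def mean(self, category: str) -> float:
        return self.estimates[category][0]

    def ci(self, category: str) -> tuple[float, float]:
        _, lo, hi = self.estimates[category]
        return lo, hi


def fit_time_effort(
    records: Iterable[tuple[str, float]] | pd.DataFrame,
    confidence: float = 0.95,
    categories: Sequence[str] | None = None,
) -> TimeEffortModel:
    """Fit the saturated categorical time-effort regression.

    ``records`` is an iterable of ``(action_category, minutes)`` pairs or a
    DataFrame with columns ``category`` and ``minutes``.  Minutes are
    regressed on category indicators without an intercept, so each fitted
    coefficient equals its category's sample mean and CIs use the pooled
    residual variance.  If ``categories`` is given, every listed category
    must appear in the data.
    """
    if isinstance(records, pd.DataFrame):
        df = records[["category", "minutes"]].copy()
    else:
        df = pd.DataFrame(list(records), columns=["category", "minutes"])
    if df.empty:
        raise ValueError("no time-effort records supplied")
    present = list(dict.fromkeys(df["category"]))
    if categories is not None:
        missing = [c for c in categories if c not in present]
        if missing:
            raise ValueError(f"no records for categories: {missing}")
        present = list(categories)
        df = df[df["category"].isin(present)]

    X = pd.get_dummies(df["category"], dtype=float)[present]
    model = sm.OLS(df["minutes"].astype(float), X)
    fit = model.fit()
    ci = fit.conf_int(alpha=1.0 - confidence)
    estimates = {
        cat: (float(fit.params[cat]), float(ci.loc[cat, 0]), float(ci.loc[cat, 1]))
        for cat in present
    }
    counts = df["category"].value_counts().to_dict()
    return TimeEffortModel(
        estimates=estimates,
        n_per_category={c: int(counts[c]) for c in present},
        confidence=confidence,
    )
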