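"""Diagnostic accuracy: pooled confusion tables, exact CIs, predictive values.

Positive = marker-positive assay call; disease = carcinoma (cFTC) by
histology.  Confidence intervals are exact Clopper–Pearson binomial
intervals; percent renderings use round-half-up to integers (raw fractions
are always retained in machine output).  Cases with an insufficient assay
result are excluded from the table (not counted as negative), with the
exclusion count logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import beta

logger = logging.getLogger(__name__)


@dataclass
class ConfusionTable:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


def pool_confusion(
    per_set_calls: Mapping[str, Sequence[tuple[str, str, str]]],
) -> ConfusionTable:
    """Pool per-set (case id, histology label, assay call) triples.

    ``call`` is positive/negative/insufficient; insufficient cases are
    excluded with a logged count.  A case id recurring across sets is an
    error.
    """
    seen: set[str] = set()
    table = ConfusionTable()
    n_insufficient = 0
    for set_name, records in per_set_calls.items():
        for case_id, label, call in records:
            if case_id in seen:
                raise ValueError(f"duplicate case id across sets: {case_id}")
            seen.add(case_id)
            if call == "insufficient":
                n_insufficient += 1
                continue
            if call not in ("positive", "negative"):
                raise ValueError(f"invalid call {call!r} for case {case_id}")
            if label not in ("cFA", "cFTC"):
                raise ValueError(f"invalid label {label!r} for case {case_id}")
            positive = call == "positive"
            diseased = label == "cFTC"
            if diseased and positive:
                table.tp += 1
            elif diseased:
                table.fn += 1
            elif positive:
                table.fp += 1
            else:
                table.tn += 1
    if n_insufficient:
        logger.info("excluded %d insufficient case(s) from the table",
                    n_insufficient)
    return table


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI by inverting binomial tails (beta quantiles)."""
    if not (0 <= x <= n) or n <= 0:
        raise ValueError("require 0 <= x <= n with n > 0")
    a = (1 - level) / 2
    lo = 0.0 if x == 0 else float(beta.ppf(a, x, n - x + 1))
    hi = 1.0 if x == n else float(beta.ppf(1 - a, x + 1, n - x))
    return lo, hi


def percent(fraction: float, decimals: int = 0) -> float:
    """Round-half-up percent rendering of a fraction."""
    scaled = fraction * 100 * 10**decimals
    return math.floor(scaled + 0.5) / 10**decimals


@dataclass
class Proportion:
    """A diagnostic statistic as numerator/denominator with its exact CI."""

    numerator: int
    denominator: int
    fraction: float | None
    ci_low: float | None
    ci_high: float | None

    @property
    def defined(self) -> bool:
        return self.fraction is not None

    @property
    def pct(self) -> float | None:
        return None if self.fraction is None else percent(self.fraction)

    @property
    def ci_render(self) -> str | None:
        if self.ci_low is None or self.ci_high is None:
            return None
        return f"{percent(self.ci_low):.0f}–{percent(self.ci_high):.0f}"


def _proportion(x: int, n: int, level: float) -> Proportion:
    if n == 0:
        logger.warning("zero denominator; statistic undefined")
        return Proportion(x, n, None, None, None)
    lo, hi = clopper_pearson(x, n, level)
    return Proportion(x, n, x / n, lo, hi)


@dataclass
class AccuracyReport:
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    accuracy: Proportion
    prevalence: Proportion
    level: float

    def as_dict(self) -> dict:
        out: dict = {"ci_level": self.level}
        for name in ("sensitivity", "specificity", "ppv", "npv",
                     "accuracy", "prevalence"):
            p: Proportion = getattr(self, name)
            out[name] = {
                "numerator": p.numerator,
                "denominator": p.denominator,
                "fraction": p.fraction,
                "ci_low": p.ci_low,
                "ci_high": p.ci_high,
                "pct": p.pct,
                "ci_render": p.ci_render,
            }
        return out


def accuracy_stats(table: ConfusionTable, level: float = 0.95) -> AccuracyReport:
    """All accuracy statistics of a 2x2 table with exact binomial CIs."""
    if table.total == 0:
        raise ValueError("empty confusion table")
    t = table
    return AccuracyReport(
        sensitivity=_proportion(t.tp, t.tp + t.fn, level),
        specificity=_proportion(t.tn, t.tn + t.fp, level),
        ppv=_proportion(t.tp, t.tp + t.fp, level),
        npv=_proportion(t.tn, t.tn + t.fn, level),
        accuracy=_proportion(t.tp + t.tn, t.total, level),
        prevalence=_proportion(t.tp + t.fn, t.total, level),
        level=level,
    )


def adjust_prevalence(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """Predictive values at an assumed disease prevalence (Bayes' rule)."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must lie strictly inside (0, 1)")
    pi = prevalence
    ppv_num = sensitivity * pi
    ppv_den = ppv_num + (1 - specificity) * (1 - pi)
    npv_num = specificity * (1 - pi)
    npv_den = (1 - sensitivity) * pi + npv_num
    ppv = ppv_num / ppv_den if ppv_den > 0 else float("nan")
    npv = npv_num / npv_den if npv_den > 0 else float("nan")
    return ppv, npv


def positivity_rates(
    per_set_calls: Mapping[str, Sequence[tuple[str, str, str]]],
) -> dict[str, tuple[int, int, float]]:
    """Per-set and pooled positivity among diseased (cFTC) cases.

    Returns set name -> (positives, cFTC tested, fraction); the pooled row
    is keyed ``"pooled"`` and uses the same counting code as the per-set
    rows.
    """

    def rate(records: Sequence[tuple[str, str, str]]) -> tuple[int, int, float]:
        tested = [r for r in records if r[1] == "cFTC" and r[2] != "insufficient"]
        pos = sum(r[2] == "positive" for r in tested)
        return pos, len(tested), (pos / len(tested) if tested else float("nan"))

    out = {name: rate(records) for name, records in per_set_calls.items()}
    pooled: list[tuple[str, str, str]] = []
    for records in per_set_calls.values():
        pooled.extend(records)
    out["pooled"] = rate(pooled)
    return out
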