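"""Diagnostic-accuracy statistics with exact confidence intervals.

The evaluation crosses the four-category index test against the binary
reference standard in a typed contingency table (bleeding categories ×
MAJOR/NOT_MAJOR). For the overall binary comparison the three bleeding
categories collapse to "positive":

    TP = index-positive & MAJOR      FP = index-positive & NOT_MAJOR
    FN = index-negative & MAJOR      TN = index-negative & NOT_MAJOR

Sensitivity, specificity, PPV and NPV are binomial proportions; their
confidence intervals are exact two-sided Clopper-Pearson intervals
(beta-quantile inversion of the binomial tails). Likelihood ratios
LR+ = se/(1-sp) and LR- = (1-se)/sp carry log-normal (Simel-type)
intervals; a zero cell gets a +0.5 continuity adjustment for the interval
only (the point estimate stays the closed-form ratio) and is flagged.
Undefined quantities (zero denominators) are reported as not-applicable
with a reason, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Union

import numpy as np
from scipy import stats

from .codesets import BLEED_CATEGORIES, Category
from .classify import IndexLabeling

__all__ = [
    "TypedContingency",
    "MetricEstimate",
    "LREstimate",
    "AccuracyReport",
    "build_contingency",
    "clopper_pearson",
    "diagnostic_metrics",
    "likelihood_ratio_ci",
    "category_ppv",
    "round_half_up",
]

REF_POSITIVE = "MAJOR"
REF_NEGATIVE = "NOT_MAJOR"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.25 -> 0.3 at 1 digit), used for display."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TypedContingency:
    """Index category × reference status cross-table.

    ``cells`` maps (category, reference status) to a count; every stay of
    the evaluated cohort sits in exactly one cell.
    """

    cells: Mapping[tuple[Category, str], int]

    def __post_init__(self) -> None:
        full = {}
        for cat in Category:
            for ref in (REF_POSITIVE, REF_NEGATIVE):
                n = int(self.cells.get((cat, ref), 0))
                if n < 0:
                    raise ValueError(f"negative count in cell ({cat.value}, {ref})")
                full[(cat, ref)] = n
        object.__setattr__(self, "cells", full)

    def positives(self, cat: Category) -> int:
        return self.cells[(cat, REF_POSITIVE)]

    def negatives(self, cat: Category) -> int:
        return self.cells[(cat, REF_NEGATIVE)]

    @property
    def tp(self) -> int:
        return sum(self.positives(c) for c in BLEED_CATEGORIES)

    @property
    def fp(self) -> int:
        return sum(self.negatives(c) for c in BLEED_CATEGORIES)

    @property
    def fn(self) -> int:
        return self.positives(Category.NONE)

    @property
    def tn(self) -> int:
        return self.negatives(Category.NONE)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def scaled(self, factor: int) -> "TypedContingency":
        return TypedContingency({k: v * factor for k, v in self.cells.items()})

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "index_category": cat.value,
                "reference_positive": self.positives(cat),
                "reference_negative": self.negatives(cat),
            }
            for cat in Category
        ]
        return pd.DataFrame(rows)


def build_contingency(
    index: Union[IndexLabeling, Mapping[str, Category]],
    reference: Mapping[str, str],
) -> TypedContingency:
    """Cross index labels with reference labels over identical stay-id sets.

    ``reference`` maps stay_id to ``"MAJOR"``/``"NOT_MAJOR"`` (objects with
    a ``verdict`` attribute, e.g. :class:`~bleedvalidate.reference.ReferenceResult`,
    are accepted too).
    """
    labels = index.labels if isinstance(index, IndexLabeling) else dict(index)
    ref = {sid: getattr(v, "verdict", v) for sid, v in reference.items()}
    diff = set(labels) ^ set(ref)
    if diff:
        raise ValueError(
            f"index and reference stay_id sets differ by {len(diff)} ids: {sorted(diff)[:5]}"
        )
    cells: dict[tuple[Category, str], int] = {}
    for sid, cat in labels.items():
        status = ref[sid]
        if status not in (REF_POSITIVE, REF_NEGATIVE):
            raise ValueError(f"stay {sid}: bad reference status {status!r}")
        key = (cat, status)
        cells[key] = cells.get(key, 0) + 1
    return TypedContingency(cells)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for k successes in n.

    Lower bound is 0 at k=0 and upper bound 1 at k=n; otherwise the
    standard beta-quantile inversion. The interval always contains k/n.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


@dataclass(frozen=True)
class MetricEstimate:
    """A binomial proportion k/n with its exact confidence interval."""

    point: float
    lower: float
    upper: float
    k: int
    n: int

    def as_percent(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round_half_up(100 * self.point, ndigits),
            round_half_up(100 * self.lower, ndigits),
            round_half_up(100 * self.upper, ndigits),
        )


@dataclass(frozen=True)
class LREstimate:
    """A likelihood ratio with a log-normal interval.

    ``adjusted`` flags that a zero cell forced the +0.5 continuity
    adjustment in the interval (never in the point estimate).
    """

    point: float
    lower: Optional[float]
    upper: Optional[float]
    adjusted: bool = False


@dataclass
class AccuracyReport:
    """All overall accuracy measures; unavailable ones are None with a
    reason under ``not_applicable``."""

    table: TypedContingency
    alpha: float
    se: Optional[MetricEstimate]
    sp: Optional[MetricEstimate]
    ppv: Optional[MetricEstimate]
    npv: Optional[MetricEstimate]
    lr_pos: Optional[LREstimate]
    lr_neg: Optional[LREstimate]
    not_applicable: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def prop(m: Optional[MetricEstimate]):
            if m is None:
                return None
            return {"point": m.point, "lower": m.lower, "upper": m.upper, "k": m.k, "n": m.n}

        def lr(m: Optional[LREstimate]):
            if m is None:
                return None
            return {"point": m.point, "lower": m.lower, "upper": m.upper, "adjusted": m.adjusted}

        t = self.table
        return {
            "alpha": self.alpha,
            "counts": {
                "tp": t.tp,
                "fp": t.fp,
                "fn": t.fn,
                "tn": t.tn,
                "n": t.n,
                "cells": {
                    f"{cat.value}": [t.positives(cat), t.negatives(cat)] for cat in Category
                },
            },
            "sensitivity": prop(self.se),
            "specificity": prop(self.sp),
            "ppv": prop(self.ppv),
            "npv": prop(self.npv),
            "lr_positive": lr(self.lr_pos),
            "lr_negative": lr(self.lr_neg),
            "not_applicable": dict(self.not_applicable),
        }


def _proportion(k: int, n: int, alpha: float) -> Optional[MetricEstimate]:
    if n == 0:
        return None
    lo, hi = clopper_pearson(k, n, alpha)
    return MetricEstimate(point=k / n, lower=lo, upper=hi, k=k, n=n)


def likelihood_ratio_ci(
    table: TypedContingency, alpha: float = 0.05, method: str = "log_normal"
) -> tuple[Optional[LREstimate], Optional[LREstimate]]:
    """LR+ and LR- with log-normal (Simel-type) confidence intervals.

    On the log scale the standard error for LR+ is
    sqrt(1/TP - 1/(TP+FN) + 1/FP - 1/(FP+TN)); LR- uses the FN/TN cells
    analogously. A zero numerator/denominator cell gets +0.5 added to all
    four cells for the interval computation only, and the estimate is
    flagged ``adjusted``. Point estimates are always the closed-form ratios;
    a ratio with an undefined denominator is returned as None.
    """
    if method != "log_normal":
        raise ValueError(f"unsupported LR interval method {method!r}")
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    npos, nneg = tp + fn, tn + fp

    def one(num_k: int, den_k: int) -> Optional[LREstimate]:
        # LR = (num_k/npos) / (den_k/nneg)
        if npos == 0 or nneg == 0:
            return None
        point = math.inf if den_k == 0 else (num_k / npos) / (den_k / nneg)
        if num_k == 0 or den_k == 0:
            # a zero cell: adjusted cells give a finite interval around a
            # point estimate that is exactly 0 (or infinite)
            a, b = num_k + 0.5, den_k + 0.5
            na, nb = npos + 0.5, nneg + 0.5
            adjusted = True
        else:
            a, b, na, nb = float(num_k), float(den_k), float(npos), float(nneg)
            adjusted = False
        se_log = math.sqrt(max(1 / a - 1 / na, 0.0) + max(1 / b - 1 / nb, 0.0))
        z = stats.norm.ppf(1 - alpha / 2)
        center = math.log((a / na) / (b / nb))
        return LREstimate(
            point=point,
            lower=math.exp(center - z * se_log),
            upper=math.exp(center + z * se_log),
            adjusted=adjusted,
        )

    return one(tp, fp), one(fn, tn)


def diagnostic_metrics(table: TypedContingency, alpha: float = 0.05) -> AccuracyReport:
    """Se, Sp, PPV, NPV with exact Clopper-Pearson intervals, plus LR±."""
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    na: dict[str, str] = {}
    se = _proportion(tp, tp + fn, alpha)
    if se is None:
        na["sensitivity"] = "no reference-positive stays (TP+FN=0)"
    sp = _proportion(tn, tn + fp, alpha)
    if sp is None:
        na["specificity"] = "no reference-negative stays (TN+FP=0)"
    ppv = _proportion(tp, tp + fp, alpha)
    if ppv is None:
        na["ppv"] = "no index-positive stays (TP+FP=0)"
    npv = _proportion(tn, tn + fn, alpha)
    if npv is None:
        na["npv"] = "no index-negative stays (TN+FN=0)"
    lr_pos, lr_neg = likelihood_ratio_ci(table, alpha)
    if lr_pos is not None and math.isinf(lr_pos.point):
        lr_pos = None
    if lr_neg is not None and math.isinf(lr_neg.point):
        lr_neg = None
    if lr_pos is None:
        na["lr_positive"] = "undefined: specificity is 1 or margins empty"
    if lr_neg is None:
        na["lr_negative"] = "undefined: specificity is 0 or margins empty"
    return AccuracyReport(
        table=table,
        alpha=alpha,
        se=se,
        sp=sp,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        not_applicable=na,
    )


def category_ppv(
    table: TypedContingency, category: Category, alpha: float = 0.05
) -> Optional[MetricEstimate]:
    """Positive predictive value within one bleeding category: among stays
    the index test put in ``category``, the fraction the reference confirmed
    as major bleeding."""
    if category is Category.NONE:
        raise ValueError("PPV is defined for bleeding categories only")
    k = table.positives(category)
    n = k + table.negatives(category)
    return _proportion(k, n, alpha)
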