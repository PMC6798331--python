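"""The index test: classify each stay from its primary discharge diagnosis.

Only the primary hospital discharge diagnosis is consulted; emergency-ward
codes and any secondary diagnoses never influence the index label. Each stay
receives exactly one of four exclusive categories: intracranial (ICH),
gastrointestinal (GI), other bleeding, or no bleeding event (NONE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .codesets import BLEED_CATEGORIES, BleedTypeMap, Category, match_category
from .cohort import Cohort, HospitalStay

__all__ = ["IndexLabeling", "classify_stay", "classify_cohort", "code_frequency_report"]


@dataclass
class IndexLabeling:
    """Index-test category per stay_id, with the code map that produced it."""

    labels: dict[str, Category]
    map_used: BleedTypeMap

    def positives(self) -> list[str]:
        return [sid for sid, cat in self.labels.items() if cat is not Category.NONE]

    def counts(self) -> dict[Category, int]:
        out = {cat: 0 for cat in Category}
        for cat in self.labels.values():
            out[cat] += 1
        return out


def classify_stay(stay: HospitalStay, bleed_map: BleedTypeMap) -> Category:
    """Index category of one stay — a pure function of its primary diagnosis."""
    return match_category(stay.primary_dx, bleed_map)


def classify_cohort(cohort: Cohort, bleed_map: BleedTypeMap) -> IndexLabeling:
    """Apply the index test to every stay. Deterministic and order-invariant."""
    return IndexLabeling(
        labels={s.stay_id: classify_stay(s, bleed_map) for s in cohort},
        map_used=bleed_map,
    )


def code_frequency_report(
    cohort: Cohort,
    labeling: IndexLabeling,
    aggregation: str = "3-char",
) -> pd.DataFrame:
    """Frequency of primary discharge codes among index-positive stays.

    Returns a frame with columns ``category``, ``code``, ``count``,
    ``percent`` (percent within category, unrounded; sums to 100 per
    non-empty category). ``aggregation="3-char"`` groups codes by their
    first three normalized characters (the style used to summarise events
    per code family); ``"as-listed"`` keeps full codes.
    """
    if aggregation not in ("3-char", "as-listed"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    missing = set(labeling.labels) ^ set(cohort.ids())
    if missing:
        raise ValueError(f"labeling does not match cohort; differing ids: {sorted(missing)[:5]}")
    counts: dict[tuple[Category, str], int] = {}
    totals: dict[Category, int] = {cat: 0 for cat in BLEED_CATEGORIES}
    for stay in cohort:
        cat = labeling.labels[stay.stay_id]
        if cat is Category.NONE:
            continue
        code = stay.primary_dx.normalized
        if aggregation == "3-char":
            code = code[:3]
        counts[(cat, code)] = counts.get((cat, code), 0) + 1
        totals[cat] += 1
    rows = [
        {
            "category": cat.value,
            "code": code,
            "count": n,
            "percent": 100.0 * n / totals[cat],
        }
        for (cat, code), n in counts.items()
    ]
    frame = pd.DataFrame(rows, columns=["category", "code", "count", "percent"])
    if len(frame):
        order = {cat.value: i for i, cat in enumerate(BLEED_CATEGORIES)}
        frame = frame.sort_values(
            by=["category", "count", "code"],
            key=lambda col: col.map(order) if col.name == "category" else col,
            ascending=[True, False, True],
        ).reset_index(drop=True)
    return frame
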