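"""Profiling of index/reference discordance.

False positives (index-positive, reference NOT_MAJOR) and false negatives
(index-negative, reference MAJOR) are characterised three ways: frequency
of emergency-ward codes among false negatives (one code per stay — the
first recorded — since multiplicity handling in tabulations of "most cited
diagnoses" is by stay), grouping of primary discharge codes by ICD-10
chapter (first letter), and the split of false positives by screen pathway
(adjudicated-but-ruled-non-serious versus never screened in).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .codesets import BleedTypeMap, Category
from .classify import IndexLabeling
from .cohort import Cohort
from .reference import ReferenceResult

__all__ = [
    "DiscordanceProfile",
    "discordant_stays",
    "false_negative_code_table",
    "chapter_group",
    "false_positive_pathway_split",
    "profile_discordance",
]


def _verdicts(reference: Mapping[str, object]) -> dict[str, str]:
    return {sid: getattr(v, "verdict", v) for sid, v in reference.items()}


def discordant_stays(
    index: IndexLabeling, reference: Mapping[str, object]
) -> tuple[list[str], list[str]]:
    """(false positives, false negatives), in the labeling's stay order."""
    ref = _verdicts(reference)
    diff = set(index.labels) ^ set(ref)
    if diff:
        raise ValueError(f"index and reference ids differ: {sorted(diff)[:5]}")
    fp = [
        sid
        for sid, cat in index.labels.items()
        if cat is not Category.NONE and ref[sid] == "NOT_MAJOR"
    ]
    fn = [
        sid for sid, cat in index.labels.items() if cat is Category.NONE and ref[sid] == "MAJOR"
    ]
    return fp, fn


def _freq_frame(values: Iterable[str], total: int) -> pd.DataFrame:
    counts: dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    rows = [
        {"code": code, "count": n, "percent": 100.0 * n / total if total else 0.0}
        for code, n in counts.items()
    ]
    frame = pd.DataFrame(rows, columns=["code", "count", "percent"])
    if len(frame):
        frame = frame.sort_values(["count", "code"], ascending=[False, True]).reset_index(
            drop=True
        )
    return frame


def false_negative_code_table(
    cohort: Cohort,
    fn_ids: Sequence[str],
    source: str = "ew_codes",
    min_percent: Optional[float] = None,
) -> pd.DataFrame:
    """Emergency-ward code frequencies among false-negative stays.

    One code per stay (the first recorded emergency-ward code). Percents
    are of the false-negative total. ``min_percent`` applies a display
    cutoff (e.g. 2.0 keeps only codes cited by more than 2% of stays).
    """
    if source != "ew_codes":
        raise ValueError(f"unsupported source {source!r}")
    by_id = cohort.by_id()
    codes = []
    for sid in fn_ids:
        stay = by_id[sid]
        if stay.ew_codes:
            codes.append(stay.ew_codes[0].normalized)
    frame = _freq_frame(codes, total=len(fn_ids))
    if min_percent is not None and len(frame):
        frame = frame[frame["percent"] > min_percent].reset_index(drop=True)
    return frame


def chapter_group(cohort: Cohort, stay_ids: Sequence[str]) -> pd.DataFrame:
    """Primary-discharge-diagnosis chapters (first letter) within a cell."""
    by_id = cohort.by_id()
    letters = (by_id[sid].primary_dx.normalized[0] for sid in stay_ids)
    frame = _freq_frame(letters, total=len(stay_ids))
    return frame.rename(columns={"code": "chapter"})


def false_positive_pathway_split(
    fp_ids: Sequence[str], reference: Mapping[str, ReferenceResult]
) -> dict[str, int]:
    """Split false positives by screen pathway.

    ``screened_in``: selected by the automated step and ruled non-serious
    at adjudication. ``not_screened``: index-positive stays the screen never
    selected (step-1 negatives).
    """
    split = {"screened_in": 0, "not_screened": 0}
    for sid in fp_ids:
        pathway = reference[sid].pathway
        split["screened_in" if pathway == "adjudicated" else "not_screened"] += 1
    return split


@dataclass
class DiscordanceProfile:
    """All three views of one discordance cell."""

    cell: str
    stays: list[str]
    code_freq: pd.DataFrame
    chapter_freq: pd.DataFrame
    pathway_split: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "cell": self.cell,
            "n": len(self.stays),
            "stays": list(self.stays),
            "code_freq": self.code_freq.to_dict("records"),
            "chapter_freq": self.chapter_freq.to_dict("records"),
            "pathway_split": dict(self.pathway_split),
        }


def profile_discordance(
    cohort: Cohort,
    index: IndexLabeling,
    reference: Mapping[str, ReferenceResult],
) -> dict[str, DiscordanceProfile]:
    """Build FALSE_POSITIVE and FALSE_NEGATIVE profiles in one pass."""
    fp_ids, fn_ids = discordant_stays(index, reference)
    profiles = {}
    for cell, ids in (("FALSE_POSITIVE", fp_ids), ("FALSE_NEGATIVE", fn_ids)):
        pathway = {"screened_in": 0, "not_screened": 0}
        for sid in ids:
            pathway["screened_in" if reference[sid].pathway == "adjudicated" else "not_screened"] += 1
        profiles[cell] = DiscordanceProfile(
            cell=cell,
            stays=list(ids),
            code_freq=false_negative_code_table(cohort, ids) if cell == "FALSE_NEGATIVE" else _freq_frame(
                (cohort.by_id()[sid].primary_dx.normalized for sid in ids), total=len(ids)
            ),
            chapter_freq=chapter_group(cohort, ids),
            pathway_split=pathway,
        )
    return profiles
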