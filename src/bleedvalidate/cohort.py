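"""Stay-level data model and delimited-text I/O.

One row per hospital stay admitted through the emergency ward: the primary
discharge ICD-10 code (the only input to the index test), the emergency-ward
codes and emergency-therapy flags (inputs to the automated screen), and the
structured chart features consumed by the adjudication rules. Synthetic
cohorts additionally carry the latent true bleeding status.

Interchange format: UTF-8 CSV with a header row; in-cell lists (emergency
codes, therapies) are ``;``-separated. Columns outside the documented schema
are preserved verbatim on round-trip. An absent chart feature means the
criterion was not documented in the chart, which the adjudicator treats as
not met.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import pandas as pd

from .codesets import ICDCode, MalformedCodeError, THERAPIES, normalize_code

__all__ = [
    "ChartFeatures",
    "HospitalStay",
    "Cohort",
    "CohortError",
    "read_cohort",
    "write_cohort",
    "COLUMNS",
]

HEMOSTATIC_PROCEDURES = ("none", "embolization", "endoscopic", "surgery")

#: Bleeding locations; the first nine are the life-threatening ones.
LOCATIONS = (
    "intracranial",
    "intraspinal",
    "intraocular",
    "retroperitoneal",
    "pericardial",
    "thoracic",
    "intraarticular",
    "intramuscular_compartment",
    "acute_gi",
    "other",
    "none",
)

LIFE_THREATENING_LOCATIONS = frozenset(LOCATIONS[:9])


class CohortError(ValueError):
    """Invalid cohort data (duplicate ids, bad field values, ...)."""


@dataclass(frozen=True)
class ChartFeatures:
    """Structured clinical facts from chart review.

    Pressures are in mmHg, hematuria duration in hours. ``None`` means the
    item was not documented.
    """

    sbp: Optional[float] = None
    map_pressure: Optional[float] = None
    shock: bool = False
    uncontrollable_bleeding: bool = False
    transfusion: bool = False
    hemostatic_procedure: str = "none"
    location: str = "none"
    nasal_packing_count: int = 0
    hematuria_hours: float = 0.0
    bladder_washing: bool = False

    def __post_init__(self) -> None:
        for name in ("sbp", "map_pressure"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise CohortError(f"{name} must be non-negative, got {v}")
        if self.nasal_packing_count < 0:
            raise CohortError(f"nasal_packing_count must be non-negative, got {self.nasal_packing_count}")
        if self.hematuria_hours < 0:
            raise CohortError(f"hematuria_hours must be non-negative, got {self.hematuria_hours}")
        if self.hemostatic_procedure not in HEMOSTATIC_PROCEDURES:
            raise CohortError(f"unknown hemostatic_procedure {self.hemostatic_procedure!r}")
        if self.location not in LOCATIONS:
            raise CohortError(f"unknown bleeding location {self.location!r}")


@dataclass(frozen=True)
class HospitalStay:
    """One adult admission through the emergency ward."""

    stay_id: str
    age: int
    sex: str
    primary_dx: ICDCode
    ew_codes: tuple[ICDCode, ...] = ()
    therapies: frozenset[str] = frozenset()
    chart: Optional[ChartFeatures] = None
    latent_truth: Optional[str] = None
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.age < 18:
            raise CohortError(f"stay {self.stay_id}: age must be >= 18, got {self.age}")
        if self.sex not in ("M", "F"):
            raise CohortError(f"stay {self.stay_id}: sex must be M or F, got {self.sex!r}")
        unknown = set(self.therapies) - THERAPIES
        if unknown:
            raise CohortError(f"stay {self.stay_id}: unknown therapies {sorted(unknown)}")
        if self.latent_truth not in (None, "MAJOR", "NOT_MAJOR"):
            raise CohortError(f"stay {self.stay_id}: bad latent_truth {self.latent_truth!r}")


@dataclass
class Cohort:
    """An ordered collection of stays with unique ids."""

    stays: list[HospitalStay]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for stay in self.stays:
            if stay.stay_id in seen:
                raise CohortError(f"duplicate stay_id {stay.stay_id!r}")
            seen.add(stay.stay_id)

    def __len__(self) -> int:
        return len(self.stays)

    def __iter__(self) -> Iterator[HospitalStay]:
        return iter(self.stays)

    def ids(self) -> list[str]:
        return [s.stay_id for s in self.stays]

    def by_id(self) -> dict[str, HospitalStay]:
        return {s.stay_id: s for s in self.stays}


_CHART_COLUMNS = (
    "sbp",
    "map_pressure",
    "shock",
    "uncontrollable_bleeding",
    "transfusion",
    "hemostatic_procedure",
    "location",
    "nasal_packing_count",
    "hematuria_hours",
    "bladder_washing",
)

COLUMNS = (
    "stay_id",
    "age",
    "sex",
    "primary_dx",
    "ew_codes",
    "therapies",
    *_CHART_COLUMNS,
    "latent_truth",
)

_TRUE = {"1", "true", "TRUE", "True", "yes"}
_FALSE = {"0", "false", "FALSE", "False", "no", ""}


def _parse_bool(cell: str, col: str, row: int) -> bool:
    if cell in _TRUE:
        return True
    if cell in _FALSE:
        return False
    raise CohortError(f"row {row}: cannot parse {col}={cell!r} as a flag")


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def _chart_to_cells(chart: Optional[ChartFeatures]) -> dict[str, str]:
    if chart is None:
        return {c: "" for c in _CHART_COLUMNS}
    return {
        "sbp": _fmt(chart.sbp),
        "map_pressure": _fmt(chart.map_pressure),
        "shock": _fmt(chart.shock),
        "uncontrollable_bleeding": _fmt(chart.uncontrollable_bleeding),
        "transfusion": _fmt(chart.transfusion),
        "hemostatic_procedure": chart.hemostatic_procedure,
        "location": chart.location,
        "nasal_packing_count": _fmt(chart.nasal_packing_count),
        "hematuria_hours": _fmt(chart.hematuria_hours),
        "bladder_washing": _fmt(chart.bladder_washing),
    }


def _chart_from_cells(cells: dict[str, str], row: int) -> Optional[ChartFeatures]:
    present = {c: cells.get(c, "") for c in _CHART_COLUMNS}
    if all(v == "" for v in present.values()):
        return None
    return ChartFeatures(
        sbp=float(present["sbp"]) if present["sbp"] else None,
        map_pressure=float(present["map_pressure"]) if present["map_pressure"] else None,
        shock=_parse_bool(present["shock"], "shock", row),
        uncontrollable_bleeding=_parse_bool(
            present["uncontrollable_bleeding"], "uncontrollable_bleeding", row
        ),
        transfusion=_parse_bool(present["transfusion"], "transfusion", row),
        hemostatic_procedure=present["hemostatic_procedure"] or "none",
        location=present["location"] or "none",
        nasal_packing_count=int(present["nasal_packing_count"] or 0),
        hematuria_hours=float(present["hematuria_hours"] or 0),
        bladder_washing=_parse_bool(present["bladder_washing"], "bladder_washing", row),
    )


def read_cohort(path: Union[str, Path]) -> Cohort:
    """Read a cohort from a CSV file (schema in :data:`COLUMNS`).

    Unknown columns are kept on each stay's ``extra`` field and written back
    by :func:`write_cohort`. Raises :class:`CohortError` on duplicate ids and
    :class:`MalformedCodeError` (with the row number) on unparseable codes.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "stay_id" not in frame.columns or "primary_dx" not in frame.columns:
        raise CohortError(f"{path}: required columns stay_id and primary_dx missing")
    extra_cols = [c for c in frame.columns if c not in COLUMNS]
    stays: list[HospitalStay] = []
    for i, rec in enumerate(frame.to_dict("records")):
        rownum = i + 2  # 1-based, after header
        try:
            primary = normalize_code(rec["primary_dx"])
            ew = tuple(
                normalize_code(c) for c in str(rec.get("ew_codes", "")).split(";") if c.strip()
            )
        except MalformedCodeError as exc:
            raise MalformedCodeError(f"{path} row {rownum}: {exc}") from exc
        therapies = frozenset(t for t in str(rec.get("therapies", "")).split(";") if t.strip())
        stays.append(
            HospitalStay(
                stay_id=rec["stay_id"],
                age=int(rec.get("age", "18") or 18),
                sex=rec.get("sex", "F") or "F",
                primary_dx=primary,
                ew_codes=ew,
                therapies=therapies,
                chart=_chart_from_cells(rec, rownum),
                latent_truth=rec.get("latent_truth") or None,
                extra=tuple((c, rec[c]) for c in extra_cols),
            )
        )
    return Cohort(stays, provenance=str(path))


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> Path:
    """Write a cohort to CSV such that :func:`read_cohort` round-trips it."""
    path = Path(path)
    extra_cols: list[str] = []
    for stay in cohort:
        for key, _ in stay.extra:
            if key not in extra_cols:
                extra_cols.append(key)
    rows = []
    for stay in cohort:
        row = {
            "stay_id": stay.stay_id,
            "age": str(stay.age),
            "sex": stay.sex,
            "primary_dx": stay.primary_dx.normalized,
            "ew_codes": ";".join(c.normalized for c in stay.ew_codes),
            "therapies": ";".join(sorted(stay.therapies)),
            **_chart_to_cells(stay.chart),
            "latent_truth": stay.latent_truth or "",
        }
        row.update(dict(stay.extra))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(COLUMNS) + extra_cols, dtype=str)
    if not rows:
        frame = pd.DataFrame(columns=list(COLUMNS))
    frame.to_csv(path, index=False)
    return path
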