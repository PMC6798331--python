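"""The two-step reference standard.

Step 1 is an automated screen over emergency-ward data: a stay is selected
when any of its emergency-ward ICD-10 codes matches the screen code list or
when it received one of six emergency therapies (transfusions, vitamin K,
protamine sulfate, PCC, FEIBA). Stays not selected are labelled NOT_MAJOR
without chart review — a step-1 miss is final, which is the design's known
blind spot.

Step 2 adjudicates the selected stays from structured chart features.
MAJOR bleeding requires at least one criterion:

* hemodynamic instability — systolic pressure < 90 mmHg, mean arterial
  pressure < 65 mmHg, or shock;
* uncontrollable bleeding;
* need for transfusion or a hemostatic procedure (embolization, endoscopic
  procedure, surgery);
* a life-threatening location (intracranial, intraspinal, intraocular,
  retroperitoneal, pericardial, thoracic, intra-articular, intramuscular
  with compartment syndrome, acute gastrointestinal);
* epistaxis needing at least two nasal packings;
* hematuria lasting more than 12 h despite bladder washing.

All inequalities are strict as stated; an undocumented item never triggers
a criterion (chart review can only use what is charted), and an absent
chart adjudicates NOT_MAJOR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .codesets import ScreenCodeSet
from .cohort import Cohort, ChartFeatures, HospitalStay, LIFE_THREATENING_LOCATIONS

__all__ = [
    "ScreenResult",
    "AdjudicationVerdict",
    "ReferenceResult",
    "screen_step1",
    "adjudicate",
    "reference_label",
    "label_cohort",
    "CRITERIA",
]

CRITERIA = (
    "hemodynamic",
    "uncontrollable",
    "transfusion_or_hemostasis",
    "life_threatening_location",
    "epistaxis_rule",
    "hematuria_rule",
)


@dataclass(frozen=True)
class ScreenResult:
    """Step-1 outcome: selected iff something triggered."""

    triggered_codes: tuple[str, ...] = ()
    triggered_therapies: tuple[str, ...] = ()

    @property
    def selected(self) -> bool:
        return bool(self.triggered_codes or self.triggered_therapies)


@dataclass(frozen=True)
class AdjudicationVerdict:
    """Step-2 outcome: MAJOR iff at least one criterion is met."""

    criteria_met: frozenset[str]

    @property
    def verdict(self) -> str:
        return "MAJOR" if self.criteria_met else "NOT_MAJOR"


@dataclass(frozen=True)
class ReferenceResult:
    """Final reference label with its pathway.

    ``pathway`` is ``screened_out`` when step 1 did not select the stay
    (no adjudication happened) and ``adjudicated`` otherwise.
    """

    verdict: str
    pathway: str
    screen: ScreenResult
    criteria_met: frozenset[str] = frozenset()


def screen_step1(stay: HospitalStay, screen: ScreenCodeSet) -> ScreenResult:
    """Automated screen: emergency-ward code match or emergency therapy."""
    codes = tuple(c.normalized for c in stay.ew_codes if screen.matches_code(c))
    therapies = tuple(sorted(set(stay.therapies) & set(screen.therapies)))
    return ScreenResult(triggered_codes=codes, triggered_therapies=therapies)


def adjudicate(chart: Optional[ChartFeatures]) -> AdjudicationVerdict:
    """Criteria-based adjudication of one chart; absent chart -> NOT_MAJOR."""
    if chart is None:
        return AdjudicationVerdict(frozenset())
    met = set()
    if (
        (chart.sbp is not None and chart.sbp < 90)
        or (chart.map_pressure is not None and chart.map_pressure < 65)
        or chart.shock
    ):
        met.add("hemodynamic")
    if chart.uncontrollable_bleeding:
        met.add("uncontrollable")
    if chart.transfusion or chart.hemostatic_procedure != "none":
        met.add("transfusion_or_hemostasis")
    if chart.location in LIFE_THREATENING_LOCATIONS:
        met.add("life_threatening_location")
    if chart.nasal_packing_count >= 2:
        met.add("epistaxis_rule")
    if chart.hematuria_hours > 12 and chart.bladder_washing:
        met.add("hematuria_rule")
    return AdjudicationVerdict(frozenset(met))


def reference_label(stay: HospitalStay, screen: ScreenCodeSet) -> ReferenceResult:
    """Two-step composition: screen, then adjudicate only if selected."""
    result = screen_step1(stay, screen)
    if not result.selected:
        return ReferenceResult(verdict="NOT_MAJOR", pathway="screened_out", screen=result)
    verdict = adjudicate(stay.chart)
    return ReferenceResult(
        verdict=verdict.verdict,
        pathway="adjudicated",
        screen=result,
        criteria_met=verdict.criteria_met,
    )


def label_cohort(cohort: Cohort, screen: ScreenCodeSet) -> dict[str, ReferenceResult]:
    """Reference label for every stay, keyed by stay_id."""
    return {s.stay_id: reference_label(s, screen) for s in cohort}
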