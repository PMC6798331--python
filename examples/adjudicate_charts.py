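"""Adjudicate a handful of chart-review records against the major-bleeding
criteria, and show how the two-step reference treats a screen miss."""

from bleedvalidate import ChartFeatures, HospitalStay, adjudicate, normalize_code
from bleedvalidate import default_screen_set, reference_label

charts = [
    ("hypotensive (SBP 85 mmHg)", ChartFeatures(sbp=85)),
    ("SBP exactly 90 mmHg", ChartFeatures(sbp=90)),
    ("transfused", ChartFeatures(transfusion=True)),
    ("intracranial location", ChartFeatures(location="intracranial")),
    ("two nasal packings", ChartFeatures(nasal_packing_count=2)),
    ("hematuria 13 h, no washing", ChartFeatures(hematuria_hours=13)),
    ("hematuria 13 h despite washing",
     ChartFeatures(hematuria_hours=13, bladder_washing=True)),
    ("nothing documented", None),
]
for label, chart in charts:
    verdict = adjudicate(chart)
    met = ", ".join(sorted(verdict.criteria_met)) or "-"
    print(f"{label:32s} -> {verdict.verdict:9s} ({met})")

# The screen gates adjudication: a stay with a clearly major chart but no
# emergency-ward signal is never reviewed and stays NOT_MAJOR.
screen = default_screen_set()
missed = HospitalStay(
    stay_id="missed", age=70, sex="F", primary_dx=normalize_code("S06.0"),
    chart=ChartFeatures(sbp=70, location="intracranial"),
)
result = reference_label(missed, screen)
print(f"\nscreen-missed major bleed -> {result.verdict} via {result.pathway}")
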