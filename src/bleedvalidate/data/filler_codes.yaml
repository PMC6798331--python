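# Plausible non-hemorrhage primary discharge codes used by the synthetic
# generator for stays whose discharge coding does not point to bleeding
# (common emergency presentations: injury, anemia, stroke, heart failure,
# infection, metabolic). None of these match the index code list.
# Replaceable; documented in docs/methods.md.
filler:
  - I10
  - E11.9
  - J18.9
  - A09
  - M54.5
  - R55
  - N17.9
  - G45.9
  - E86
  - K57.3
  - K29.7
  - I63.9
  - I50.0
  - D64.9
  - D68.3
  - S72.0
  - S06.0
  - S42.2
  - J44.1
  - N39.0
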