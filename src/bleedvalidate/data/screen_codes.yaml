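# Automated first-step screen: emergency-ward hemorrhage-related ICD-10
# codes plus the six emergency therapies. The original screening request's
# code list is not public; this default is a documented stand-in built from
# the index code list plus hemorrhage-related emergency-ward codes
# (anemia/shock/injury codes seen among screen-selected stays). Replace via
# a user config if a site-specific list exists.
ew_codes:
  # index algorithm codes (a discharge-coded bleed is also screen-visible)
  - I60
  - I61
  - I62
  - S06.3
  - S06.4
  - S06.5
  - S06.6
  - I85.0
  - K25.0
  - K25.2
  - K25.4
  - K25.6
  - K26.0
  - K26.2
  - K26.4
  - K26.6
  - K27.0
  - K27.2
  - K27.4
  - K27.6
  - K28.0
  - K28.2
  - K28.4
  - K28.6
  - K29.0
  - K62.5
  - K92.0
  - K92.1
  - K92.2
  - D62
  - N02
  - R31
  - R58
  - H11.3
  - H35.6
  - H43.1
  - H45.0
  - H92.2
  - J94.2
  - K66.1
  - M25.0
  - N92.0
  - N92.1
  - N92.4
  - N93.8
  - N93.9
  - N95.0
  - R04.0
  - R04.1
  - R04.2
  - R04.8
  - R04.9
  # emergency-ward stand-in codes: anemia, hypovolemic shock, injuries,
  # procedure complications and other presentations compatible with bleeding
  - D64.9
  - R57.1
  - S39.0
  - S00.0
  - T81.0
  - R10.4
  - R55
  - R11
  - S01.0
  - S20.2
  - T14.1
  - R23.3
  - N89.8
  - J93.9
  - R02
  - I95.9
  - D69.6
  - R42
  - S51.9
  - K64.8
  - R06.0
  - M79.8
therapies:
  - rbc_transfusion
  - platelet_transfusion
  - vitamin_k
  - protamine_sulfate
  - pcc
  - feiba
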