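# Index algorithm: ICD-10 primary discharge diagnosis codes by bleeding
# category. 3-character entries match all their extensions; 4-character
# entries match exactly. Dotted and undotted spellings are equivalent.
intracranial:
  - I60
  - I61
  - I62
  - S06.3
  - S06.4
  - S06.5
  - S06.6
gastrointestinal:
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
other:
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
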