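# Backbone diagnostic ion series, anchored on theoretical anion m/z (neutral
# monoisotopic mass minus the proton mass -- the package-wide convention),
# never on individual measured values.  A backbone is recognized when at
# least three series ions match at the MS2 tolerance; quinate 191.056 versus
# dehydrated hexarate 191.020 disambiguates the two series and requires an
# absolute tolerance below 18 mDa.
backbones:
  quinic:
    neutral: C7H12O6        # quinic acid; [QA-H]- = 191.0561
    positions: [1, 3, 4, 5]
    series:
      - {mz: 191.0561, label: "[QA-H]-"}
      - {mz: 173.0456, label: "[QA-H-H2O]-"}
      - {mz: 111.0452, label: "[QA-H-2H2O-CO2]-"}
      - {mz: 93.0346,  label: "[QA-H-3H2O-CO2]-"}
      - {mz: 85.0295,  label: "[QA-H-2H2O-CO-C2H2O]-"}
  hexaric:
    neutral: C6H10O8        # hexaric (glucaric) acid; [HA-H]- = 209.0303
    positions: [2, 3, 4, 5]
    series:
      - {mz: 209.0303, label: "[HA-H]-"}
      - {mz: 191.0197, label: "[HA-H-H2O]-"}
      - {mz: 173.0092, label: "[HA-H-2H2O]-"}
      - {mz: 147.0299, label: "[HA-H-H2O-CO2]-"}
      - {mz: 129.0193, label: "[HA-H-2H2O-CO2]-"}
      - {mz: 111.0088, label: "[HA-H-3H2O-CO2]-"}
      - {mz: 85.0295,  label: "[HA-H-2H2O-2CO2]-"}
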