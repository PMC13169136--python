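# Acyl residue registry for quinic/hexaric backbones and glycoside esters.
#
# loss:     elemental formula of the neutral lost on ester cleavage
#           (acid minus H2O), e.g. caffeoyl = C9H6O3 = 162.0317 Da.
# contexts: branches of the key in which the residue may be proposed.
#           197.045 is syringoyl only in the phenolic-glycoside branch and
#           hydroxydihydrocaffeoyl only in the quinic branch; the two are
#           isobaric (C9H8O4) and must never be resolved globally.
# markers:  diagnostic anions; roles with null m/z are derived from the loss
#           formula (acid = loss + H2O - proton; decarboxylated = acid - CO2;
#           dehydrated = acid - H2O).  Explicit m/z overrides the derivation
#           (used for radical ions such as the demethylated ferulate).
acyls:
  caffeoyl:
    loss: C9H6O3
    contexts: [quinic, hexaric, glycoside]
    markers:
      acid: null            # 179.0350
      decarboxylated: null  # 135.0452
      dehydrated: null      # 161.0244
  feruloyl:
    loss: C10H8O3
    contexts: [quinic]
    markers:
      acid: null            # 193.0506
      decarboxylated: null  # 149.0608
      demethylated: null    # 134.0373, [ferulate - CO2 - CH3]- radical anion
  p-coumaroyl:
    loss: C9H6O2
    contexts: [quinic]
    markers:
      acid: null            # 163.0401
      decarboxylated: null  # 119.0503
  dihydrocaffeoyl:
    loss: C9H8O3
    contexts: [quinic]
    markers:
      acid: null            # 181.0506
  hydroxydihydrocaffeoyl:
    loss: C9H8O4
    contexts: [quinic]
    markers:
      acid: null            # 197.0455
      decarboxylated: null  # 153.0557
  hydroxybenzoyl:
    loss: C7H4O2
    contexts: [quinic, hexaric, glycoside]
    markers:
      acid: null            # 137.0244
      decarboxylated: null  # 93.0346
  protocatechuoyl:
    loss: C7H4O3
    contexts: [quinic, glycoside]
    markers:
      acid: null            # 153.0193
      decarboxylated: null  # 109.0295
  vanillyl:
    loss: C8H6O3
    contexts: [glycoside]
    markers:
      acid: null            # 167.0350
  syringoyl:
    loss: C9H8O4
    contexts: [glycoside]
    markers:
      acid: null            # 197.0455
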