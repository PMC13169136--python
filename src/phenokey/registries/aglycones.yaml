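# Aglycone lookup table: residual fragment after the sugar loss (flavonoids)
# or the free-acid anion (phenolic acids).  [M-H]- m/z derives from the
# formula.  isobaric_with groups aglycones with identical formulas that MS/MS
# cannot separate without retention-time priors; such hits are reported as
# either/or.
aglycones:
  myricetin:      {formula: C15H10O8, class: flavonoid}           # 317.0303
  quercetin:      {formula: C15H10O7, class: flavonoid}           # 301.0354
  luteolin:       {formula: C15H10O6, class: flavonoid, isobaric_with: kaempferol}    # 285.0405
  kaempferol:     {formula: C15H10O6, class: flavonoid, isobaric_with: luteolin}
  patuletin:      {formula: C16H12O8, class: flavonoid}           # 331.0459
  nepetin:        {formula: C16H12O7, class: flavonoid, isobaric_with: isorhamnetin}  # 315.0510
  isorhamnetin:   {formula: C16H12O7, class: flavonoid, isobaric_with: nepetin}
  apigenin:       {formula: C15H10O5, class: flavonoid}           # 269.0455
  genkwanin:      {formula: C16H12O5, class: flavonoid}           # 283.0612
  hydroxybenzoic acid:   {formula: C7H6O3,  class: phenolic-acid} # 137.0244
  protocatechuic acid:   {formula: C7H6O4,  class: phenolic-acid} # 153.0193
  vanillic acid:         {formula: C8H8O4,  class: phenolic-acid} # 167.0350
  syringic acid:         {formula: C9H10O5, class: phenolic-acid} # 197.0455
  caffeic acid:          {formula: C9H8O4,  class: phenolic-acid} # 179.0350
  coumaric acid:         {formula: C9H8O3,  class: phenolic-acid} # 163.0401
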