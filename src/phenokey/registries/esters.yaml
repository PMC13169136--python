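# Small ester substituents seen on caffeoylhexaric acid cores.
#
# attach: net elemental addition to the backbone (acid minus H2O); its mass
#         is the residual left after subtracting the hexarate anion and all
#         caffeoyl losses from the precursor m/z.
# acid:   the free-acid formula; the spectrum may show the loss of either the
#         attach form (e.g. 86.037, C4H6O2) or the acid form (104.047).
# Slash-named entries are constitutional isomers that MS/MS cannot separate.
#
# Note: one literature transcription prints the methylbutanyl loss as
# "102.069 (C5H10O3)"; C5H10O3 is 118.063 -- the 102.068 loss corresponds to
# the C5H10O2 acid used here.
esters:
  hydroxybutanyl:
    attach: C4H6O2          # 86.0368
    acid: C4H8O3
  hydroxyvaleryl/hydroxyisovaleryl:
    attach: C5H8O2          # 100.0524
    acid: C5H10O3
  butanyl/isobutanyl:
    attach: C4H6O           # 70.0419
    acid: C4H8O2
  methylbutanyl/isovaleryl:
    attach: C5H8O           # 84.0575
    acid: C5H10O2
  hydroxybenzoyl:
    attach: C7H4O2          # 120.0211
    acid: C7H6O3
    markers:
      acid: null            # 137.0244
      decarboxylated: null  # 93.0346
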