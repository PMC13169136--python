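# Sugar (and sugar-conjugate) neutral losses for the glycoside branch, plus
# the hexose cross-ring cleavage losses that distinguish sugar esters from
# O-glycosides.
sugars:
  hexose:
    loss: C6H10O5           # 162.0528
  di-hexose:
    loss: C12H20O10         # 324.1057
  rutinosyl:
    loss: C12H20O9          # 308.1107 (deoxyhexose + hexose)
  acetylhexose:
    loss: C8H12O6           # 204.0634 (concomitant hexose + acetyl)
  caffeoylhexose:
    loss: C15H16O8          # 324.0845 (caffeoyl ester of a hexose)
# Cross-ring cleavages of an ester-bound hexose: 0,4Hex / 0,3Hex / 0,2Hex.
cross_ring_losses:
  "0,4Hex": C2H4O2          # -60.0211
  "0,3Hex": C3H6O3          # -90.0317
  "0,2Hex": C4H8O4          # -120.0423
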