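# Genetic fields for natural-gas source diagnostics.
#
# The boundaries below encode the conventional empirical fields used on
# methane source diagrams (Schoell-style dD vs d13C; Bernard-style
# C1/(C2+C3) vs d13C) as drawn throughout the natural-gas geochemistry
# literature.  Published versions of these diagrams draw the fields rather
# than tabulate them, so the vertices here are a deliberately simple,
# editable transcription: rectangles in diagram coordinates.  Edit freely;
# classification is point-in-polygon, first listed field wins on ties.
#
# Schoell coordinates: [d13C_CH4 (permil VPDB), dD_CH4 (permil VSMOW)]
# Bernard coordinates: [d13C_CH4 (permil VPDB), log10(C1/(C2+C3))]

schoell:
  - name: thermogenic
    polygon:
      - [-50, -275]
      - [-20, -275]
      - [-20, -100]
      - [-50, -100]
  - name: biogenic-CO2-reduction
    polygon:
      - [-110, -250]
      - [-60, -250]
      - [-60, -150]
      - [-110, -150]
  - name: biogenic-methyl-fermentation
    polygon:
      - [-65, -400]
      - [-50, -400]
      - [-50, -250]
      - [-65, -250]

bernard:
  - name: thermogenic
    polygon:
      - [-50, -1.0]
      - [-20, -1.0]
      - [-20, 2.0]
      - [-50, 2.0]
  - name: biogenic
    polygon:
      - [-110, 2.0]
      - [-55, 2.0]
      - [-55, 5.0]
      - [-110, 5.0]
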