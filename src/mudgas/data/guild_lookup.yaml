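# Default taxon -> metabolic-guild lookup for hydrocarbon-cycling seeps.
#
# Patterns are case-insensitive substrings matched at the declared rank of
# a SILVA-style lineage string (d__;p__;c__;o__;f__;g__), or against bare
# names when no rank prefixes are present.  When rules at different ranks
# both match one lineage (e.g. the order Desulfuromonadales and its genus
# Geobacter), the most specific rank wins; two matching rules at the SAME
# rank pointing to different guilds is an error that demands editing this
# file.  Both classical and SILVA spellings of the sulfate-reducer orders
# are listed.  Edit freely — this file is configuration, not code.

guilds:
  hydrogenotrophic_methanogen:
    - {pattern: Methanoregula, rank: genus}
    - {pattern: Methanobacterium, rank: genus}
    - {pattern: Methanolinea, rank: genus}
    - {pattern: Methanomicrobiales, rank: order}
    - {pattern: Methanomassiliicoccales, rank: order}
    - {pattern: Methanofastidiosa, rank: genus}
  acetoclastic_methanogen:
    - {pattern: Methanosarcinales, rank: order}
    - {pattern: Methanosarcina, rank: genus}
    - {pattern: Methanothrix, rank: genus}
    - {pattern: Methanosaeta, rank: genus}
  ANME:
    - {pattern: ANME, rank: any}
  sulfate_reducer:
    - {pattern: Desulfuromonadales, rank: order}
    - {pattern: Desulfobacterales, rank: order}
    - {pattern: Desulfobacteriales, rank: order}
    - {pattern: Desulfovibrionales, rank: order}
    - {pattern: Desulfarculales, rank: order}
    - {pattern: Desulfarculates, rank: order}
    - {pattern: Syntrophobacterales, rank: order}
    - {pattern: Syntrophobacteriales, rank: order}
  nitrate_reducing_alkane_oxidizer:
    - {pattern: Rhodocyclaceae, rank: family}
  iron_reducer:
    - {pattern: Geobacter, rank: genus}
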