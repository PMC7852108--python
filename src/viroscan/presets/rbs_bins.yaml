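# Raw gene-caller RBS motif strings -> the 11 motif bins used as features.
# Keys are bin names; values list raw motif spellings (prodigal-style) that
# fall in the bin. Anything absent/empty bins as "None"; any other
# non-empty string bins as "Other". Override by passing a custom mapping to
# bin_rbs_motif / the feature extractor.
SD_Canonical:
  - GGA/GAG/AGG
  - AGGA
  - AGGAG
  - GAGGA
  - AGGAGG
  - AGGAG(G)/GGAGG
  - GGAG/GAGG
  - GGAGG
  - GGAG
  - GAGG
  - AGxAG
  - AGxAGG/AGGxGG
SD_Bacteroidetes:
  - TAA
  - TAAA
  - TAAAA
  - TA/TAA
TATATA_3-6:
  - TATATA
  - ATATAT
OnlyA:
  - AAA
  - AAAA
  - AAAAA
OnlyT:
  - TTT
  - TTTT
  - TTTTT
DoubleA:
  - AAxAA
  - AAxAAA
DoubleT:
  - TTxTT
  - TTxTTT
Other_GA:
  - GA
  - GAx
  - GGxGG
  - GxGG
NoA:
  - CTC
  - CCTC
  - TCTC
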