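# "easy" preset: well-separated viral and host gene-level profiles.
# Separation is built in at the single-gene level so that regions of any
# size carry class signal: host genes are mostly annotated (bacterial /
# eukaryotic best hits) and carry a host-style RBS almost always
# (Shine-Dalgarno for prokaryotes and plasmids, TATA-like for eukaryotes),
# while viral genes are often unannotated, rarely carry SD/TATA motifs, and
# occasionally carry a group hallmark. Strand switching is frequent in
# cellular sources and rare in viral ones. Contrasts are deliberately
# exaggerated relative to real genomes; the "hard" preset keeps the overlap.
groups:
  dsDNAphage:
    role: viral
    gene_len: [800, 200]
    gene_density_target: 1.05
    genome_len_range: [30000, 60000]
    p_category: {viral: 0.55, bacterial: 0.02, mixed: 0.05, unaligned: 0.38}
    p_hallmark_given_viral: 0.12
    p_strand_switch: 0.05
    p_overlap: 0.25
    start_codon_probs: {ATG: 0.78, GTG: 0.13, TTG: 0.07, other: 0.02}
    gc: [0.42, 0.04]
    rbs_probs: {"None": 0.55, OnlyA: 0.12, DoubleA: 0.08, NoA: 0.10,
                SD_Canonical: 0.03, Other: 0.12}
    bit_score: [120, 40]
  NCLDV:
    role: viral
    gene_len: [900, 300]
    gene_density_target: 0.9
    genome_len_range: [60000, 120000]
    p_category: {viral: 0.45, unaligned: 0.50, mixed: 0.03, eukaryotic: 0.02}
    p_hallmark_given_viral: 0.10
    p_strand_switch: 0.10
    p_overlap: 0.05
    start_codon_probs: {ATG: 0.85, GTG: 0.08, TTG: 0.04, other: 0.03}
    gc: [0.30, 0.04]
    rbs_probs: {"None": 0.80, Other: 0.08, OnlyA: 0.07, NoA: 0.05}
    bit_score: [100, 35]
  RNA:
    role: viral
    gene_len: [2200, 500]
    gene_density_target: 0.45
    genome_len_range: [4000, 30000]
    p_category: {viral: 0.50, unaligned: 0.48, mixed: 0.02}
    p_hallmark_given_viral: 0.30
    p_strand_switch: 0.02
    p_overlap: 0.10
    start_codon_probs: {ATG: 0.92, GTG: 0.04, TTG: 0.02, other: 0.02}
    gc: [0.45, 0.025]
    rbs_probs: {"None": 0.90, Other: 0.10}
    bit_score: [110, 35]
  ssDNA:
    role: viral
    gene_len: [700, 250]
    gene_density_target: 1.2
    genome_len_range: [2000, 10000]
    p_category: {viral: 0.50, unaligned: 0.47, mixed: 0.03}
    p_hallmark_given_viral: 0.30
    p_strand_switch: 0.10
    p_overlap: 0.15
    start_codon_probs: {ATG: 0.85, GTG: 0.08, TTG: 0.05, other: 0.02}
    gc: [0.38, 0.04]
    rbs_probs: {"None": 0.70, OnlyA: 0.15, OnlyT: 0.08, Other: 0.07}
    bit_score: [100, 30]
  lavidaviridae:
    role: viral
    gene_len: [750, 200]
    gene_density_target: 1.0
    genome_len_range: [15000, 30000]
    p_category: {viral: 0.45, unaligned: 0.50, mixed: 0.05}
    p_hallmark_given_viral: 0.25
    p_strand_switch: 0.08
    p_overlap: 0.10
    start_codon_probs: {ATG: 0.80, GTG: 0.10, TTG: 0.08, other: 0.02}
    gc: [0.35, 0.04]
    rbs_probs: {"None": 0.70, Other: 0.12, OnlyT: 0.10, DoubleT: 0.08}
    bit_score: [100, 35]
  prokaryote:
    role: negative
    gene_len: [900, 250]
    gene_density_target: 1.0
    genome_len_range: [30000, 80000]
    p_category: {bacterial: 0.72, archaeal: 0.05, mixed: 0.13, unaligned: 0.08,
                 viral: 0.02}
    p_hallmark_given_viral: 0.0
    p_strand_switch: 0.25
    p_overlap: 0.10
    start_codon_probs: {ATG: 0.75, GTG: 0.15, TTG: 0.08, other: 0.02}
    gc: [0.54, 0.03]
    rbs_probs: {SD_Canonical: 0.82, SD_Bacteroidetes: 0.10, Other_GA: 0.05,
                "None": 0.01, Other: 0.02}
    bit_score: [90, 30]
  eukaryote:
    role: negative
    gene_len: [1500, 350]
    gene_density_target: 0.55
    genome_len_range: [30000, 80000]
    p_category: {eukaryotic: 0.72, mixed: 0.10, unaligned: 0.16, viral: 0.02}
    p_hallmark_given_viral: 0.0
    p_strand_switch: 0.45
    p_overlap: 0.02
    start_codon_probs: {ATG: 0.90, GTG: 0.01, TTG: 0.01, other: 0.08}
    gc: [0.41, 0.03]
    rbs_probs: {TATATA_3-6: 0.80, "None": 0.05, Other: 0.15}
    bit_score: [90, 30]
  plasmid:
    role: negative
    gene_len: [900, 250]
    gene_density_target: 0.95
    genome_len_range: [5000, 40000]
    p_category: {bacterial: 0.63, mixed: 0.20, unaligned: 0.12, viral: 0.05}
    p_hallmark_given_viral: 0.0
    p_strand_switch: 0.20
    p_overlap: 0.12
    start_codon_probs: {ATG: 0.78, GTG: 0.12, TTG: 0.08, other: 0.02}
    gc: [0.52, 0.03]
    rbs_probs: {SD_Canonical: 0.80, Other_GA: 0.10, "None": 0.04, Other: 0.06}
    bit_score: [80, 25]
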