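# "hard" preset: overlapping viral and host profiles. Viral sequences carry
# fewer diagnostic hits and hallmarks, hosts carry more viral-looking genes,
# and GC / strand-switching distributions overlap, so classifiers trained
# here sit closer to their decision boundary.
groups:
  dsDNAphage:
    role: viral
    gene_len: [850, 250]
    gene_density_target: 1.0
    genome_len_range: [30000, 60000]
    p_category: {viral: 0.30, bacterial: 0.10, mixed: 0.10, unaligned: 0.50}
    p_hallmark_given_viral: 0.05
    p_strand_switch: 0.15
    p_overlap: 0.15
    start_codon_probs: {ATG: 0.78, GTG: 0.13, TTG: 0.07, other: 0.02}
    gc: [0.46, 0.05]
    rbs_probs: {"None": 0.35, SD_Canonical: 0.30, OnlyA: 0.10, Other: 0.25}
    bit_score: [80, 30]
  NCLDV:
    role: viral
    gene_len: [950, 300]
    gene_density_target: 0.85
    genome_len_range: [60000, 120000]
    p_category: {viral: 0.25, unaligned: 0.55, mixed: 0.10, eukaryotic: 0.10}
    p_hallmark_given_viral: 0.05
    p_strand_switch: 0.20
    p_overlap: 0.05
    start_codon_probs: {ATG: 0.85, GTG: 0.08, TTG: 0.04, other: 0.03}
    gc: [0.40, 0.05]
    rbs_probs: {"None": 0.70, Other: 0.20, OnlyA: 0.10}
    bit_score: [70, 25]
  RNA:
    role: viral
    gene_len: [1900, 700]
    gene_density_target: 0.45
    genome_len_range: [4000, 30000]
    p_category: {viral: 0.30, unaligned: 0.60, mixed: 0.10}
    p_hallmark_given_viral: 0.10
    p_strand_switch: 0.10
    p_overlap: 0.08
    start_codon_probs: {ATG: 0.92, GTG: 0.04, TTG: 0.02, other: 0.02}
    gc: [0.45, 0.06]
    rbs_probs: {"None": 0.80, Other: 0.20}
    bit_score: [75, 25]
  ssDNA:
    role: viral
    gene_len: [750, 250]
    gene_density_target: 1.1
    genome_len_range: [2000, 10000]
    p_category: {viral: 0.30, unaligned: 0.57, mixed: 0.13}
    p_hallmark_given_viral: 0.10
    p_strand_switch: 0.15
    p_overlap: 0.10
    start_codon_probs: {ATG: 0.85, GTG: 0.08, TTG: 0.05, other: 0.02}
    gc: [0.44, 0.06]
    rbs_probs: {"None": 0.55, OnlyA: 0.15, SD_Canonical: 0.10, Other: 0.20}
    bit_score: [70, 25]
  lavidaviridae:
    role: viral
    gene_len: [800, 220]
    gene_density_target: 0.95
    genome_len_range: [15000, 30000]
    p_category: {viral: 0.25, unaligned: 0.60, mixed: 0.15}
    p_hallmark_given_viral: 0.08
    p_strand_switch: 0.15
    p_overlap: 0.08
    start_codon_probs: {ATG: 0.80, GTG: 0.10, TTG: 0.08, other: 0.02}
    gc: [0.42, 0.05]
    rbs_probs: {"None": 0.60, Other: 0.30, OnlyT: 0.10}
    bit_score: [70, 25]
  prokaryote:
    role: negative
    gene_len: [900, 250]
    gene_density_target: 1.0
    genome_len_range: [30000, 80000]
    p_category: {bacterial: 0.35, archaeal: 0.05, mixed: 0.12, unaligned: 0.40,
                 viral: 0.08}
    p_hallmark_given_viral: 0.0
    p_strand_switch: 0.22
    p_overlap: 0.10
    start_codon_probs: {ATG: 0.75, GTG: 0.15, TTG: 0.08, other: 0.02}
    gc: [0.48, 0.06]
    rbs_probs: {SD_Canonical: 0.40, "None": 0.35, Other: 0.25}
    bit_score: [80, 30]
  eukaryote:
    role: negative
    gene_len: [1400, 500]
    gene_density_target: 0.55
    genome_len_range: [30000, 80000]
    p_category: {eukaryotic: 0.35, mixed: 0.10, unaligned: 0.50, viral: 0.05}
    p_hallmark_given_viral: 0.0
    p_strand_switch: 0.35
    p_overlap: 0.02
    start_codon_probs: {ATG: 0.90, GTG: 0.01, TTG: 0.01, other: 0.08}
    gc: [0.45, 0.06]
    rbs_probs: {"None": 0.75, Other: 0.25}
    bit_score: [80, 30]
  plasmid:
    role: negative
    gene_len: [900, 250]
    gene_density_target: 0.95
    genome_len_range: [5000, 40000]
    p_category: {bacterial: 0.30, mixed: 0.15, unaligned: 0.45, viral: 0.10}
    p_hallmark_given_viral: 0.0
    p_strand_switch: 0.18
    p_overlap: 0.12
    start_codon_probs: {ATG: 0.78, GTG: 0.12, TTG: 0.08, other: 0.02}
    gc: [0.47, 0.05]
    rbs_probs: {SD_Canonical: 0.35, "None": 0.40, Other: 0.25}
    bit_score: [70, 25]
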