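# "provirus" preset: a host / viral profile pair (the well-separated "easy"
# parameterizations) for integrated-virus fixtures, plus default segment
# lengths. simulate_provirus concatenates host-viral-host at a random
# intergenic position and records the true viral interval.
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
provirus:
  host: prokaryote
  viral: dsDNAphage
  host_len: 30000
  viral_len: 20000
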