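# viroscan

Identification of viral contigs and integrated proviruses in assembled
(meta)genomes from **gene-level genomic features**, with one random-forest
"viralness" classifier per viral group.

## The problem

Viruses — especially phages — pervade microbiomes, but assembled contigs
from environmental sequencing are an unlabeled mix of cellular and viral
sequence, and viral genes are often too diverged for direct homology
assignment. Sequence-composition tools struggle with novel groups, and
single "virus vs not" classifiers are dominated by tailed dsDNA phages,
the best-represented group in reference databases. viroscan instead trains
**separate classifiers for five viral groups** (dsDNA phages, NCLDV /
giant viruses, RNA viruses, ssDNA viruses, and virophages
(*Lavidaviridae*)) and combines their predictions, so that groups with
very different genome architectures each get a tailored decision boundary.
It is aimed at microbiome and virome researchers who have contigs, gene
calls, and a profile-search hit table, and want per-contig viralness
scores plus provirus boundaries.

## Method

Each gene on a contig is assigned the category of its best profile hit
(viral, archaeal, bacterial, eukaryotic, or "mixed"; bit score ≥ 30,
ties broken viral-first), or *unaligned* if none. Any gene interval is then
summarized by a 27-dimensional feature vector

* hallmark gene count for the group (capsid, terminase, RdRP, …);
* % of genes in each of the six categories;
* average gene size, same-strand gene-overlap frequency, gene density
  (genes/kb), strand-switching frequency;
* % of ATG / GTG / TTG start codons;
* mean and SD of per-gene GC;
* % of genes in each of 11 ribosome-binding-site motif bins
  (SD_Canonical, SD_Bacteroidetes, TATATA_3-6, OnlyA, OnlyT, DoubleA,
  DoubleT, Other_GA, NoA, Other, None).

Per group, a random forest is trained on min-max-scaled features of random
1 kb+ fragments (5 per genome, 9:1 genome-level train/test split, negative
sources balanced, classes balanced; hyperparameters from a 5-fold
cross-validated grid over 20–200 trees × gini/entropy). At prediction
time every contig is scored whole by every classifier (score = forest
probability ∈ [0,1], cutoff 0.5):

* **score ≥ cutoff** → the contig is (near-)fully viral; an exhaustive
  edge-trim search (up to max(5, 10% of genes) per edge) removes residual
  host genes if that increases the score;
* **all scores < cutoff** → a gene-stepped **sliding window** (width = the
  group's minimal genome size) scans for integrated proviruses; significant
  windows are extended gene-by-gene in 3′ while significant, and detection
  edges are snapped to the outermost genes whose local 3-gene anchor still
  scores viral;
* overlapping detections from different groups are merged, keeping the
  longest.

## Worked example

No external data are needed: the `synthetic_data` module generates
annotated contigs with group-specific statistics (three presets: `easy`,
`hard`, `provirus`).

```bash
# train all five group classifiers on simulated genomes (~1 min)
viroscan train --preset easy --n-genomes 24 --seed 1 --out models/

# simulate 5 host contigs carrying an integrated 20 kb phage
viroscan simulate --preset provirus --mode provirus --n 5 --seed 2 --out data/

# detect
viroscan run --input data/contigs.fa --genes data/genes.gff \
  --hits data/hits.tsv --catalog data/catalog.tsv \
  --db models/ --min-score 0.5 --out out/

# score against the recorded truth
viroscan eval --pred out/ --truth data/truth.tsv --mode provirus --out pv.tsv
```

A typical run prints

```
5 contigs scored, 5 viral predictions -> out/
provirus recall = 1.0000, precision = 1.0000
```

meaning every integrated phage was recovered (≥ 50 % of its span) and no
spurious region was called. `out/` contains `final-viral-score.tsv` (one
row per contig: per-group scores, max score and group, length, hallmark
count, % viral / % cellular genes of the winning region),
`final-viral-boundary.tsv` (detected region coordinates, genes, scores,
kind ∈ {full, trimmed, partial}) and `final-viral-combined.fa` (predicted
viral sequences; partial/trimmed records carry bp coordinates in their
ids). `viroscan run --rerun --out out/ --min-score 0.9` regenerates the
outputs from the cached annotation without re-reading the hit table.

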