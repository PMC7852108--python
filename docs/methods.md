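# Methods

## Model

viroscan treats viral sequence identification as per-group binary
classification on gene-level features. The unit of classification is a
*gene interval* of an annotated contig; nucleotide composition is never
used directly. The assumptions this rests on:

* gene calls (coordinates, strand, start codon, RBS motif, per-gene GC)
  are available and reasonably accurate for the input contigs;
* each gene carries at most one *best* profile hit, mapped to a category
  (viral / archaeal / bacterial / eukaryotic / mixed) through a profile
  catalog, with per-group hallmark flags for diagnostic viral families;
* viral and cellular regions differ in the joint distribution of category
  fractions, hallmark presence, gene architecture (density, size,
  overlaps, strand switching), start-codon and RBS usage, and GC;
* a provirus appears as a contiguous run of viral-like genes inside a
  cellular contig (genes are atomic: boundaries fall between genes).

### Gene annotation

Hits below 30 bits are discarded (inclusive at exactly 30.0 — a hit at
the cutoff is retained; the threshold convention had to be fixed one way).
Among retained hits the best bit score wins; exact ties are broken by the
fixed category priority viral > archaeal > bacterial > eukaryotic > mixed,
then lexicographic profile id, making annotation independent of hit-table
order. Hallmark membership is taken only from a winning *viral* hit.

### Features (27, fixed order)

`hallmark_count`, six category percentages, `avg_gene_size`,
`overlap_freq`, `gene_density`, `strand_switch_freq`, `pct_atg`,
`pct_gtg`, `pct_ttg`, `gc_mean`, `gc_sd`, and 11 RBS-bin percentages.
Conventions that needed fixing:

* pair frequencies (strand switching, same-strand overlap) use the n−1
  adjacent pairs of the region as denominator; single-gene regions get 0;
* gene overlap means same-strand neighbors with start(next) ≤ end(prev);
* `gene_density` = 1000·n/L with L the region's bp span, or the full
  contig length when the region covers every gene;
* `gc_sd` is the population SD (ddof 0); GC statistics are computed on
  the raw per-gene values rather than via prefix sums, which cancel
  catastrophically for near-constant GC;
* only `hallmark_count` is group-specific; the other 26 features are
  shared across groups;
* percentages live on the 0–100 scale before scaling (immaterial after
  min-max scaling, fixed for reproducibility);
* the raw-motif → 11-bin RBS mapping ships as editable YAML
  (`presets/rbs_bins.yaml`); absent motifs bin as "None", unmapped
  non-empty strings as "Other".

Per-contig prefix sums make interval features O(1), so the window scan is
linear in gene count; the test suite keeps an independent per-gene-loop
oracle.

### Training

Five default groups — dsDNAphage, NCLDV, RNA, ssDNA, lavidaviridae — each
get a scaler + forest. Fragments: 5 per genome, start uniform, length
uniform in [1 kb, distance to 3′ end], snapped to the genes whose midpoint
falls inside the window (redrawn when the snapped span is under 1 kb).
Splits are at genome level (9:1) so no genome contributes to both sides.
The three negative sources (prokaryote, eukaryote, plasmid) are subsampled
per-fragment to the smallest source; each group's viral and negative
training fragments are then balanced to the smaller class. Scaling is
min-max fitted on training features only; a constant feature maps to 0;
values outside the training range are *not* clipped (forests tolerate
monotone excess, and clipping would mask covariate shift).
Hyperparameters come from 5-fold cross-validated grid search over
n_estimators {20, 50, 100, 150, 200} × criterion {gini, entropy} (10
cells), refit on the full training set. All sampling flows from one seeded
generator; identical seeds give identical fragments, winners and scores.

### Detection

Full-sequence scores from every group first. Significance is score ≥
cutoff (inclusive, default 0.5) everywhere.

*Fully viral branch.* For each significant group, an exhaustive search
over all (a, b) edge trims with a, b ≤ max(5, ⌈0.10·n⌉) (ceil — rounding
had to be fixed) and a+b < n; the best-scoring candidate is kept only if
it strictly beats the untrimmed score, ties preferring smaller trims.

*Provirus branch* (no group significant). Per group, the window at gene i
is the shortest gene run spanning ≥ the group's minimal window width
(window membership is whole genes, so windows slightly exceed the bp
minimum). The window slides gene by gene; the first significant window is
extended in 3′ one gene at a time while significant; scanning resumes
after the emitted region, so one contig can yield several proviruses.
Minimal-window scores for all starts are computed in one batched forest
call, which keeps the scan fast.

*Boundary refinement.* Extension stops only when the whole growing region
drops below the cutoff, and because adding one host gene dilutes the
region score only slightly, the raw maximal extension systematically
overshoots the 3′ junction (by 5–20 genes in our fixtures) and the first
significant window starts upstream of the 5′ junction. Similarly, the
edge-trim search is depth-capped, so a provirus contig that clears the
cutoff at full length would keep host margins deeper than the cap.
Detection edges are therefore snapped to the outermost genes whose
3-gene inward-facing anchor region scores significant — single-gene
anchors turned out to be fooled by isolated viral-annotated host genes,
three genes are robust — guarded so that a partial's score never falls
below the cutoff and a trim's never below the full-sequence score. The
unrefined scan (`refine_boundaries=False`) retains the pure
maximal-extension property and is cross-checked against brute-force
interval enumeration in the tests.

*Merging.* Overlapping predictions (≥ 1 bp, transitively clustered) from
different groups keep the longest span; ties break by higher score, then
fixed group order. This is applied in both branches so each contig region
is reported once.

A contig with no genes is always non-viral with all scores 0 — a defined
output beats a crash on legal input.

## Synthetic data

`synthetic_data` generates what the pipeline consumes — FASTA + GFF3 +
hit table + catalog — with group-specific statistical structure: gene
lengths ~ truncated Normal, intergenic gaps ~ Exponential tuned to a
density target, Markov strand flips, category/codon/RBS draws per gene,
hit bit scores ~ Normal truncated at the retention cutoff, hallmark hits
with a per-group probability. Nucleotide sequence is generated only so
file formats round-trip (per-gene GC is respected); codon structure is
not attempted, which is fine because the classifiers never read sequence.

Presets (editable YAML):

* **easy** — deliberately well-separated classes. Host genes are mostly
  annotated (bacterial/eukaryotic best hits), carry near-deterministic
  host RBS signatures (Shine–Dalgarno for prokaryotes and plasmids,
  TATA-like for the eukaryote profile) and sit in distinct GC bands,
  while viral genes are often unaligned, rarely carry SD/TATA motifs and
  switch strand rarely. The separation is stronger than in real genomes
  *by design*: it makes class signal available at every region size, down
  to the 1–2-gene windows of the small-genome classifiers. Early, more
  overlapping drafts made an unaligned host gene without an RBS motif
  genuinely more likely viral than host, so short-window false positives
  were irreducible no matter how much training data was used.
* **hard** — overlapping distributions (fewer viral hits and hallmarks,
  shared RBS usage, overlapping GC); classifiers trained here sit close
  to their decision boundary. Used to probe degradation, not for the
  benchmark claims.
* **provirus** — the easy host/viral pair plus default segment lengths
  (host 30 kb, viral 20 kb) for integration fixtures; the insertion point
  is a random intergenic gap and the truth interval is recorded.

What passing tests on this generator do **not** show: robustness to gene
mis-calls and fragmented genes at contig edges, to profile databases with
biased coverage across clades, to mosaic or recently transferred regions,
or to real-world feature correlations (e.g. GC shared between a phage and
its host). Results on the synthetic benchmark are an internal-consistency
check of the pipeline at its documented operating point, not a claim
about accuracy on real viromes.

## Problem sizes

Training uses 24 simulated genomes per group (≈ 110 balanced fragments per
class after the 9:1 split) — enough that every group's held-out F1
exceeds 0.9 while a full train-plus-benchmark cycle stays around three
minutes on one CPU. The benchmark uses 5 replicates of 50+50 fragments at
5/10/20 kb; provirus evaluation uses 20 host-30 kb/viral-20 kb contigs.

## Numerical conventions and degenerate inputs

Score and bit cutoffs are inclusive. Ties: best-hit category priority
(above); trim ties prefer fewer trimmed genes, then the 5′ side; overlap
ties prefer higher score, then canonical group order. Undefined
recall/precision denominators yield 0 with a degenerate flag. Empty
contigs annotate to empty gene lists and score 0; empty regions raise.
Model persistence refuses to load a directory whose manifest feature
order differs from the package's, and corruption raises instead of
falling back.

## Known limitations

* Provirus boundaries are gene-resolution at best; in fixtures they land
  within ±2 genes, but anchors can mislocalize when the integration
  junction is flanked by ambiguous (unaligned, motif-less) genes.
* The NCLDV window (100 kb) means proviruses of giant viruses are only
  detectable on very long contigs; short NCLDV fragments are handled by
  full-sequence scoring only.
* Forest probabilities are uncalibrated; 0.5 is a convention, not a
  posterior. No isotonic/Platt calibration is attempted.
* Group minimal-window defaults are placeholders on the right order of
  magnitude, user-overridable per model.
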