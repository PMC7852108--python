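"""The 27-feature summary of a gene interval.

Every classifier consumes the same fixed-order vector: one group-specific
hallmark gene count, six gene-category percentages, five gene-architecture
statistics (average gene size, same-strand overlap frequency, gene density,
strand switching frequency and the share of ATG/GTG/TTG start codons), the
mean and population SD of per-gene GC content, and the percentage of genes
in each of 11 ribosome-binding-site (RBS) motif bins.

Per-contig prefix sums make feature extraction O(1) per interval, which is
what keeps the gene-stepped sliding-window scan cheap; a naive per-gene loop
is kept in the test suite as an independent oracle.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from viroscan.annotation_io import CATEGORIES, ContigAnnotation

#: The 11 RBS motif bins, in feature order.
RBS_BINS = (
    "SD_Canonical",
    "SD_Bacteroidetes",
    "TATATA_3-6",
    "OnlyA",
    "OnlyT",
    "DoubleA",
    "DoubleT",
    "Other_GA",
    "NoA",
    "Other",
    "None",
)

#: Fixed feature order shared by every group model.
FEATURE_NAMES = (
    "hallmark_count",
    "pct_viral",
    "pct_archaeal",
    "pct_bacterial",
    "pct_eukaryotic",
    "pct_mixed",
    "pct_unaligned",
    "avg_gene_size",
    "overlap_freq",
    "gene_density",
    "strand_switch_freq",
    "pct_atg",
    "pct_gtg",
    "pct_ttg",
    "gc_mean",
    "gc_sd",
) + tuple(f"rbs_{b}" for b in RBS_BINS)

_CODONS = ("ATG", "GTG", "TTG")


class EmptyRegionError(ValueError):
    """Raised when features are requested for a region with no genes."""


@dataclass(frozen=True)
class Region:
    """An inclusive gene-index interval on one contig.

    ``start_bp``/``end_bp`` span from the first gene's start to the last
    gene's end (1-based inclusive).
    """

    contig_id: str
    first_gene: int
    last_gene: int
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.first_gene > self.last_gene or self.first_gene < 0:
            raise ValueError("invalid gene interval")

    @property
    def n_genes(self) -> int:
        return self.last_gene - self.first_gene + 1

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def feature_names() -> list[str]:
    """The stable, documented order of the 27 features."""
    return list(FEATURE_NAMES)


@functools.cache
def default_rbs_mapping() -> dict[str, str]:
    """Raw motif string -> bin, from the packaged (user-overridable) table.

    Bin names map to themselves so already-binned motifs pass through.
    """
    text = resources.files("viroscan.presets").joinpath("rbs_bins.yaml").read_text()
    table = yaml.safe_load(text)
    mapping: dict[str, str] = {b: b for b in RBS_BINS}
    for bin_name, raws in table.items():
        if bin_name not in RBS_BINS:
            raise ValueError(f"unknown RBS bin {bin_name!r} in mapping table")
        for raw in raws or []:
            mapping[str(raw)] = bin_name
    return mapping


def bin_rbs_motif(raw: str | None, mapping: Mapping[str, str] | None = None) -> str:
    """Map a raw RBS motif string to one of the 11 bins.

    Absent or empty motifs bin as "None"; mapped strings follow the table;
    any other non-empty string bins as "Other".
    """
    if raw is None or raw == "" or raw == "None":
        return "None"
    if mapping is None:
        mapping = default_rbs_mapping()
    return mapping.get(raw, "Other")


def make_region(ann: ContigAnnotation, first_gene: int, last_gene: int) -> Region:
    """Build a Region for a gene interval, deriving its bp span."""
    if ann.n_genes == 0:
        raise EmptyRegionError(f"contig {ann.contig.id} has no genes")
    if not (0 <= first_gene <= last_gene < ann.n_genes):
        raise ValueError(
            f"gene interval [{first_gene}, {last_gene}] out of range "
            f"for {ann.n_genes} genes"
        )
    return Region(
        contig_id=ann.contig.id,
        first_gene=first_gene,
        last_gene=last_gene,
        start_bp=ann.genes[first_gene].gene.start,
        end_bp=ann.genes[last_gene].gene.end,
    )


class _ContigArrays:
    """Prefix-sum arrays over one contig's genes for O(1) interval features."""

    def __init__(self, ann: ContigAnnotation, rbs_mapping: Mapping[str, str] | None):
        genes = [ga.gene for ga in ann.genes]
        n = len(genes)
        self.n = n
        self.contig_len = ann.contig.length
        self.starts = np.array([g.start for g in genes], dtype=np.int64)
        self.ends = np.array([g.end for g in genes], dtype=np.int64)

        cat_idx = {c: i for i, c in enumerate(CATEGORIES)}
        cats = np.zeros((n, len(CATEGORIES)))
        codons = np.zeros((n, 3))
        rbs = np.zeros((n, len(RBS_BINS)))
        bin_idx = {b: i for i, b in enumerate(RBS_BINS)}
        gc = np.array([g.gc for g in genes], dtype=np.float64)
        lengths = (self.ends - self.starts + 1).astype(np.float64)
        for i, ga in enumerate(ann.genes):
            cats[i, cat_idx[ga.category]] = 1.0
            if ga.gene.start_codon in _CODONS:
                codons[i, _CODONS.index(ga.gene.start_codon)] = 1.0
            rbs[i, bin_idx[bin_rbs_motif(ga.gene.rbs_motif, rbs_mapping)]] = 1.0

        def prefix(a: np.ndarray) -> np.ndarray:
            out = np.zeros((a.shape[0] + 1,) + a.shape[1:])
            np.cumsum(a, axis=0, out=out[1:])
            return out

        self.cat = prefix(cats)
        self.codon = prefix(codons)
        self.rbs = prefix(rbs)
        self.len_sum = prefix(lengths)
        # gc statistics are computed on the raw slice: prefix-sum variance
        # cancels catastrophically for near-constant gc
        self.gc = gc

        # Pair indicators: entry i describes the (i, i+1) adjacent pair.
        strands = np.array([1 if g.strand == "+" else -1 for g in genes])
        if n > 1:
            switch = (strands[1:] != strands[:-1]).astype(np.float64)
            overlap = (
                (strands[1:] == strands[:-1])
                & (self.starts[1:] <= self.ends[:-1])
            ).astype(np.float64)
        else:
            switch = np.zeros(0)
            overlap = np.zeros(0)
        self.switch = prefix(switch)
        self.overlap = prefix(overlap)

        self._hallmark: dict[str, np.ndarray] = {}
        self._ann = ann

    def hallmark(self, group: str) -> np.ndarray:
        arr = self._hallmark.get(group)
        if arr is None:
            ind = np.array(
                [1.0 if group in ga.hallmark_groups else 0.0 for ga in self._ann.genes]
            )
            arr = np.zeros(self.n + 1)
            np.cumsum(ind, out=arr[1:])
            self._hallmark[group] = arr
        return arr


def _arrays(ann: ContigAnnotation, rbs_mapping: Mapping[str, str] | None) -> _ContigArrays:
    cache = getattr(ann, "_feature_arrays", None)
    if cache is None:
        cache = _ContigArrays(ann, rbs_mapping)
        object.__setattr__(ann, "_feature_arrays", cache)
    return cache


def extract_features(
    ann: ContigAnnotation,
    region: Region,
    group: str,
    rbs_mapping: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Compute the 27-feature vector for ``region`` under ``group``'s hallmarks.

    Frequencies over adjacent gene pairs (strand switching, same-strand
    overlap) use the (n - 1) pairs inside the region as denominator and are
    0 for single-gene regions. The length used for gene density is the
    region's bp span, or the full contig length when the region covers every
    gene. An empty contig raises :class:`EmptyRegionError`.
    """
    return features_for_regions(ann, [region], group, rbs_mapping)[0]


def features_for_regions(
    ann: ContigAnnotation,
    regions: Sequence[Region],
    group: str,
    rbs_mapping: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Vectorized :func:`extract_features` over many regions of one contig."""
    if ann.n_genes == 0:
        raise EmptyRegionError(f"contig {ann.contig.id} has no genes")
    arr = _arrays(ann, rbs_mapping)
    hall = arr.hallmark(group)
    out = np.empty((len(regions), len(FEATURE_NAMES)))
    for k, region in enumerate(regions):
        if region.contig_id != ann.contig.id:
            raise ValueError("region is on a different contig")
        i, j = region.first_gene, region.last_gene
        if j >= arr.n:
            raise ValueError("region exceeds gene count")
        n = j - i + 1
        lo, hi = i, j + 1
        if i == 0 and j == arr.n - 1:
            length = float(arr.contig_len)
        else:
            length = float(arr.ends[j] - arr.starts[i] + 1)

        cat_pct = 100.0 * (arr.cat[hi] - arr.cat[lo]) / n
        codon_pct = 100.0 * (arr.codon[hi] - arr.codon[lo]) / n
        rbs_pct = 100.0 * (arr.rbs[hi] - arr.rbs[lo]) / n
        seg = arr.gc[lo:hi]
        gc_mean = float(seg.mean())
        gc_sd = float(seg.std())  # population SD (ddof 0)
        if n > 1:
            pairs = n - 1
            switch = 100.0 * (arr.switch[j] - arr.switch[i]) / pairs
            overlap = 100.0 * (arr.overlap[j] - arr.overlap[i]) / pairs
        else:
            switch = overlap = 0.0

        out[k, 0] = hall[hi] - hall[lo]
        out[k, 1:7] = cat_pct
        out[k, 7] = (arr.len_sum[hi] - arr.len_sum[lo]) / n
        out[k, 8] = overlap
        out[k, 9] = 1000.0 * n / length
        out[k, 10] = switch
        out[k, 11:14] = codon_pct
        out[k, 14] = gc_mean
        out[k, 15] = gc_sd
        out[k, 16:] = rbs_pct
    return out
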