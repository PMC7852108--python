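"""Seeded simulation of annotated contigs with group-specific structure.

The simulator emulates the statistical contrasts that separate viral from
cellular sequences at the gene level — share of genes with viral vs
cellular profile hits, hallmark gene occurrence, strand switching and gene
overlap rates, gene density and size, start codon and RBS motif usage and
GC content — without attempting nucleotide-level realism (sequence bases
exist so FASTA round-trips work; the classifiers never read them).

Three presets ship as editable YAML: "easy" (well-separated viral and host
profiles), "hard" (overlapping distributions) and "provirus" (a host/viral
profile pair for integrated-virus fixtures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from viroscan.annotation_io import (
    CATEGORIES,
    Contig,
    ContigAnnotation,
    Gene,
    ProfileHit,
    assign_categories,
    write_genes,
)
from viroscan.features import RBS_BINS, Region

_NEGATIVE_SOURCES = ("prokaryote", "eukaryote", "plasmid")
_MIN_GENE_BP = 90


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one sequence source (viral group or host)."""

    name: str
    role: str  # "viral" or "negative"
    gene_len: tuple[float, float]  # mean, sd (bp)
    gene_density_target: float  # genes per kb
    p_category: dict[str, float]
    p_hallmark_given_viral: float
    p_strand_switch: float
    p_overlap: float
    start_codon_probs: dict[str, float]
    gc: tuple[float, float]
    rbs_probs: dict[str, float]
    bit_score: tuple[float, float]
    genome_len_range: tuple[int, int] = (20_000, 50_000)

    def __post_init__(self) -> None:
        for dist, keys in ((self.p_category, CATEGORIES),
                           (self.start_codon_probs, ("ATG", "GTG", "TTG", "other")),
                           (self.rbs_probs, RBS_BINS)):
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ValueError(f"{self.name}: probabilities must sum to 1")
            unknown = set(dist) - set(keys)
            if unknown:
                raise ValueError(f"{self.name}: unknown keys {unknown}")


@dataclass
class Preset:
    """A named collection of profiles plus which are viral vs negative."""

    name: str
    profiles: dict[str, GroupProfile]
    provirus: dict = field(default_factory=dict)

    @property
    def viral_groups(self) -> list[str]:
        return [n for n, p in self.profiles.items() if p.role == "viral"]

    @property
    def negative_sources(self) -> list[str]:
        return [n for n, p in self.profiles.items() if p.role == "negative"]


def load_preset(name_or_path: str | Path) -> Preset:
    """Load a packaged preset by name ("easy", "hard", "provirus") or a YAML path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
        name = path.stem
    else:
        name = str(name_or_path)
        text = resources.files("viroscan.presets").joinpath(f"{name}.yaml").read_text()
    raw = yaml.safe_load(text)
    profiles: dict[str, GroupProfile] = {}
    for pname, cfg in raw["groups"].items():
        profiles[pname] = GroupProfile(
            name=pname,
            role=cfg["role"],
            gene_len=tuple(cfg["gene_len"]),
            gene_density_target=float(cfg["gene_density_target"]),
            p_category={c: float(v) for c, v in cfg["p_category"].items()},
            p_hallmark_given_viral=float(cfg.get("p_hallmark_given_viral", 0.0)),
            p_strand_switch=float(cfg["p_strand_switch"]),
            p_overlap=float(cfg["p_overlap"]),
            start_codon_probs={c: float(v) for c, v in cfg["start_codon_probs"].items()},
            gc=tuple(cfg["gc"]),
            rbs_probs={c: float(v) for c, v in cfg["rbs_probs"].items()},
            bit_score=tuple(cfg["bit_score"]),
            genome_len_range=tuple(cfg.get("genome_len_range", (20_000, 50_000))),
        )
    return Preset(name=name, profiles=profiles, provirus=raw.get("provirus", {}))


def build_catalog(profiles: Mapping[str, GroupProfile]) -> dict[str, tuple[str, frozenset[str]]]:
    """Profile catalog covering every profile id the simulator can emit."""
    catalog: dict[str, tuple[str, frozenset[str]]] = {
        f"{cat}_generic": (cat, frozenset()) for cat in CATEGORIES[:-1]
    }
    for p in profiles.values():
        if p.role == "viral":
            catalog[f"{p.name}_hallmark"] = ("viral", frozenset([p.name]))
    return catalog


def _sample_categorical(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> list[str]:
    keys = list(probs)
    return [keys[i] for i in rng.choice(len(keys), size=n, p=[probs[k] for k in keys])]


def simulate_contig(
    profile: GroupProfile,
    length_bp: int,
    rng: np.random.Generator,
    contig_id: str = "sim",
) -> tuple[Contig, list[Gene], list[ProfileHit]]:
    """Simulate one contig of ``length_bp`` under a profile.

    Genes are laid 5'->3' with lengths ~ Normal(gene_len) truncated at 90 bp
    and intergenic gaps tuned to the gene-density target; strands flip with
    ``p_strand_switch`` and same-strand neighbors overlap with ``p_overlap``.
    Each gene draws its category; non-unaligned genes emit one profile hit
    with a bit score truncated at the retention cutoff, and viral genes
    carry the group's hallmark profile with ``p_hallmark_given_viral``.
    """
    if length_bp < 1000:
        raise ValueError(f"contig length {length_bp} < 1000 bp")
    mean_len, sd_len = profile.gene_len
    period = 1000.0 / profile.gene_density_target
    mean_gap = period - mean_len
    if mean_gap < 0:
        raise ValueError(
            f"{profile.name}: density {profile.gene_density_target}/kb infeasible "
            f"with mean gene length {mean_len} bp"
        )

    genes: list[Gene] = []
    hits: list[ProfileHit] = []
    pos = 1 + int(rng.exponential(mean_gap / 2 + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    prev_end = 0
    prev_strand = None
    while True:
        glen = max(_MIN_GENE_BP, int(rng.normal(mean_len, sd_len)))
        if prev_strand is not None:
            if rng.random() < profile.p_strand_switch:
                strand = "-" if prev_strand == "+" else "+"
            else:
                strand = prev_strand
        if (prev_strand is not None and strand == prev_strand
                and rng.random() < profile.p_overlap):
            overlap = int(rng.integers(1, 31))
            start = max(prev_end - overlap + 1, prev_end - glen + 2, 1)
        else:
            start = pos
        end = start + glen - 1
        if end > length_bp:
            break
        idx = len(genes)
        rbs_bin = _sample_categorical(rng, profile.rbs_probs, 1)[0]
        gc = float(np.clip(rng.normal(*profile.gc), 0.05, 0.95))
        genes.append(Gene(
            contig_id=contig_id, index=idx, start=start, end=end, strand=strand,
            start_codon=_sample_categorical(rng, profile.start_codon_probs, 1)[0],
            gc=gc, rbs_motif=None if rbs_bin == "None" else rbs_bin,
        ))
        category = _sample_categorical(rng, profile.p_category, 1)[0]
        if category != "unaligned":
            if (category == "viral" and profile.role == "viral"
                    and rng.random() < profile.p_hallmark_given_viral):
                pid, groups = f"{profile.name}_hallmark", frozenset([profile.name])
            else:
                pid, groups = f"{category}_generic", frozenset()
            hits.append(ProfileHit(
                contig_id=contig_id, gene_index=idx, profile_id=pid,
                bit_score=max(30.0, float(rng.normal(*profile.bit_score))),
                category=category, hallmark_groups=groups,
            ))
        prev_end, prev_strand = end, strand
        pos = end + 1 + int(rng.exponential(mean_gap)) if mean_gap > 0 else end + 1

    seq = _simulate_sequence(length_bp, genes, profile.gc[0], rng)
    return Contig(id=contig_id, seq=seq), genes, hits


def _simulate_sequence(
    length_bp: int, genes: Sequence[Gene], background_gc: float, rng: np.random.Generator
) -> str:
    p_gc = np.full(length_bp, background_gc)
    for g in genes:
        p_gc[g.start - 1 : g.end] = g.gc
    is_gc = rng.random(length_bp) < p_gc
    half = rng.random(length_bp) < 0.5
    bases = np.where(is_gc, np.where(half, "G", "C"), np.where(half, "A", "T"))
    return "".join(bases.tolist())


def annotate(
    contig: Contig, genes: Sequence[Gene], hits: Sequence[ProfileHit]
) -> ContigAnnotation:
    """Resolve simulated hits into a ContigAnnotation (bit cutoff 30)."""
    return assign_categories([contig], {contig.id: list(genes)}, hits)[0]


def simulate_genome(
    profile: GroupProfile, rng: np.random.Generator, contig_id: str = "genome"
) -> ContigAnnotation:
    """Simulate a full genome with length drawn from the profile's range."""
    lo, hi = profile.genome_len_range
    length = int(rng.integers(lo, hi + 1))
    return annotate(*simulate_contig(profile, length, rng, contig_id))


def simulate_provirus(
    host_profile: GroupProfile,
    viral_profile: GroupProfile,
    host_len: int,
    viral_len: int,
    rng: np.random.Generator,
    contig_id: str = "provirus",
) -> tuple[Contig, list[Gene], list[ProfileHit], Region]:
    """A host contig with a viral segment integrated at a random internal gap.

    Genes are atomic: the insertion point falls in an intergenic gap of the
    host, never inside a gene. The returned truth Region records the viral
    gene interval and the inserted bp span.
    """
    host_c, host_genes, host_hits = simulate_contig(host_profile, host_len, rng, contig_id)
    viral_c, viral_genes, viral_hits = simulate_contig(viral_profile, viral_len, rng, contig_id)
    if len(host_genes) < 2 or not viral_genes:
        raise ValueError("simulated host/viral segments too sparse to integrate")

    # candidate insertion gaps: between consecutive non-overlapping host genes
    gaps = [k for k in range(1, len(host_genes))
            if host_genes[k].start > host_genes[k - 1].end]
    if not gaps:
        raise ValueError("host contig has no intergenic gap for integration")
    k = int(rng.choice(gaps))
    pos = host_genes[k - 1].end  # insert right after this bp

    seq = host_c.seq[:pos] + viral_c.seq + host_c.seq[pos:]
    genes: list[Gene] = []
    hits_by_old: dict[tuple[str, int], list[ProfileHit]] = {}
    for h in host_hits + viral_hits:
        hits_by_old.setdefault((("h" if h in host_hits else "v"), h.gene_index), []).append(h)

    def _shift(g: Gene, offset: int, new_index: int) -> Gene:
        return Gene(contig_id=contig_id, index=new_index, start=g.start + offset,
                    end=g.end + offset, strand=g.strand, start_codon=g.start_codon,
                    gc=g.gc, rbs_motif=g.rbs_motif)

    hits: list[ProfileHit] = []

    def _emit(src: str, old: Sequence[Gene], take: range, offset: int) -> None:
        for oi in take:
            new_index = len(genes)
            genes.append(_shift(old[oi], offset, new_index))
            for h in hits_by_old.get((src, oi), []):
                hits.append(ProfileHit(
                    contig_id=contig_id, gene_index=new_index, profile_id=h.profile_id,
                    bit_score=h.bit_score, category=h.category,
                    hallmark_groups=h.hallmark_groups))

    _emit("h", host_genes, range(0, k), 0)
    first_viral = len(genes)
    _emit("v", viral_genes, range(len(viral_genes)), pos)
    last_viral = len(genes) - 1
    _emit("h", host_genes, range(k, len(host_genes)), viral_len)

    truth = Region(contig_id=contig_id, first_gene=first_viral, last_gene=last_viral,
                   start_bp=pos + 1, end_bp=pos + viral_len)
    return Contig(id=contig_id, seq=seq), genes, hits, truth


@dataclass
class BenchmarkSet:
    """One replicate of labeled fragments at one length."""

    length_bp: int
    replicate: int
    items: list[tuple[ContigAnnotation, int, str]]  # (annotation, label, source)


def simulate_benchmark(
    preset: Preset,
    groups: Sequence[str] | None = None,
    n_viral: int = 50,
    n_nonviral: int = 50,
    lengths: Sequence[int] = (1500, 3000, 5000, 10_000, 20_000),
    replicates: int = 5,
    rng: np.random.Generator | None = None,
) -> list[BenchmarkSet]:
    """Labeled benchmark fragments: per (length, replicate), ``n_viral``
    viral fragments drawn across the requested groups plus ``n_nonviral``
    non-viral ones in equal thirds of prokaryote / eukaryote / plasmid."""
    rng = rng or np.random.default_rng()
    groups = list(groups) if groups is not None else preset.viral_groups
    missing = set(groups) - set(preset.viral_groups)
    if missing:
        raise ValueError(f"preset {preset.name} lacks viral group(s) {sorted(missing)}")
    neg_sources = [s for s in _NEGATIVE_SOURCES if s in preset.negative_sources]
    if len(neg_sources) != 3:
        raise ValueError(f"preset {preset.name} must define the 3 negative sources")

    out: list[BenchmarkSet] = []
    for length in lengths:
        for rep in range(replicates):
            items: list[tuple[ContigAnnotation, int, str]] = []
            for i in range(n_viral):
                g = groups[i % len(groups)]
                cid = f"viral_{g}_{length}_{rep}_{i}"
                items.append((annotate(*simulate_contig(preset.profiles[g], length, rng, cid)), 1, g))
            base, rem = divmod(n_nonviral, 3)
            for si, s in enumerate(neg_sources):
                count = base + (1 if si < rem else 0)
                for i in range(count):
                    cid = f"nonviral_{s}_{length}_{rep}_{i}"
                    items.append((annotate(*simulate_contig(preset.profiles[s], length, rng, cid)), 0, s))
            out.append(BenchmarkSet(length_bp=length, replicate=rep, items=items))
    return out


def training_corpus(
    preset: Preset,
    n_genomes_per_group: int,
    rng: np.random.Generator,
    groups: Sequence[str] | None = None,
) -> tuple[dict[str, list[ContigAnnotation]], dict[str, list[ContigAnnotation]]]:
    """Simulated genome collections for training: (viral per group, negatives)."""
    groups = list(groups) if groups is not None else preset.viral_groups
    viral = {
        g: [simulate_genome(preset.profiles[g], rng, f"{g}_g{i}")
            for i in range(n_genomes_per_group)]
        for g in groups
    }
    negatives = {
        s: [simulate_genome(preset.profiles[s], rng, f"{s}_g{i}")
            for i in range(n_genomes_per_group)]
        for s in preset.negative_sources
    }
    return viral, negatives


def write_dataset(
    out_dir: str | Path,
    contigs: Sequence[Contig],
    genes_by_contig: Mapping[str, Sequence[Gene]],
    hits: Sequence[ProfileHit],
    catalog: Mapping[str, tuple[str, frozenset[str]]],
    truth: Mapping[str, tuple[int, int, int]] | None = None,
) -> dict[str, Path]:
    """Write a simulated dataset in the pipeline's input formats.

    Emits contigs.fa, genes.gff, hits.tsv, catalog.tsv and optionally
    truth.tsv (contig_id, label, truth_start, truth_end).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / v for k, v in
             [("fasta", "contigs.fa"), ("gff", "genes.gff"), ("hits", "hits.tsv"),
              ("catalog", "catalog.tsv"), ("truth", "truth.tsv")]}
    with open(paths["fasta"], "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for k in range(0, len(c.seq), 70):
                fh.write(c.seq[k : k + 70] + "\n")
    write_genes(paths["gff"], genes_by_contig)
    with open(paths["hits"], "w") as fh:
        for h in hits:
            fh.write(f"{h.contig_id}\t{h.gene_index}\t{h.profile_id}\t{h.bit_score:.2f}\n")
    with open(paths["catalog"], "w") as fh:
        for pid in sorted(catalog):
            cat, grp = catalog[pid]
            fh.write(f"{pid}\t{cat}\t{','.join(sorted(grp)) or '-'}\n")
    if truth is not None:
        with open(paths["truth"], "w") as fh:
            fh.write("contig_id\tlabel\ttruth_start\ttruth_end\n")
            for cid in truth:
                label, s, e = truth[cid]
                fh.write(f"{cid}\t{label}\t{s}\t{e}\n")
    else:
        del paths["truth"]
    return paths
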