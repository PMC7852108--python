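"""Reading contigs, gene calls and profile-hit tables; per-gene category assignment.

Input formats
-------------
* Contigs: FASTA (DNA).
* Genes: GFF3 ``CDS`` lines carrying ``start_codon`` (or prodigal's
  ``start_type``), ``rbs_motif`` and ``gc_cont`` attributes.
* Profile hits: a 4-column TSV ``contig_id  gene_index  profile_id
  bit_score`` plus a profile catalog TSV ``profile_id  category
  hallmark_groups`` mapping every profile to its taxonomic category
  (viral / archaeal / bacterial / eukaryotic / mixed) and the viral groups,
  if any, for which it is a hallmark (comma list, ``-`` for none).

The hit table stands in for a profile search (e.g. HMMER3 against a profile
database); running the search itself is out of scope and pluggable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Closed set of gene categories. ``unaligned`` means no retained profile hit.
CATEGORIES = ("viral", "archaeal", "bacterial", "eukaryotic", "mixed", "unaligned")

#: Hit categories (everything but ``unaligned``).
HIT_CATEGORIES = CATEGORIES[:-1]

#: Tie-break priority for equal bit scores: lower rank wins.
_CATEGORY_PRIORITY = {c: i for i, c in enumerate(HIT_CATEGORIES)}

#: Default bit-score cutoff for retaining profile hits (inclusive).
DEFAULT_SCORE_CUTOFF = 30.0

_VALID_BASES = set("ACGTN")
_START_CODONS = ("ATG", "GTG", "TTG", "other")


@dataclass(frozen=True)
class Contig:
    """A DNA contig; ``seq`` is uppercase over {A,C,G,T,N}."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Gene:
    """One called coding sequence.

    Coordinates are 1-based inclusive (GFF3 convention); ``index`` is the
    0-based ordinal along the contig in coordinate order.
    """

    contig_id: str
    index: int
    start: int
    end: int
    strand: str
    start_codon: str = "other"
    gc: float = 0.5
    rbs_motif: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProfileHit:
    """Best-scoring alignment of one gene to one profile."""

    contig_id: str
    gene_index: int
    profile_id: str
    bit_score: float
    category: str
    hallmark_groups: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.category not in HIT_CATEGORIES:
            raise ValueError(f"unknown hit category {self.category!r}")
        if not math.isfinite(self.bit_score):
            raise ValueError(f"non-finite bit score for profile {self.profile_id}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene plus its resolved category and hallmark membership."""

    gene: Gene
    category: str
    best_score: float | None = None
    hallmark_groups: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.hallmark_groups and self.category != "viral":
            raise ValueError("hallmark genes must be viral")


@dataclass
class ContigAnnotation:
    """A contig with its ordered, annotated genes."""

    contig: Contig
    genes: list[GeneAnnotation] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def __post_init__(self) -> None:
        for i, ga in enumerate(self.genes):
            if ga.gene.contig_id != self.contig.id:
                raise ValueError(
                    f"gene on {ga.gene.contig_id} attached to contig {self.contig.id}"
                )
            if ga.gene.index != i:
                raise ValueError("gene indices must be consecutive from 0")


def read_contigs(path: str | Path) -> list[Contig]:
    """Read a FASTA file into a list of :class:`Contig`.

    Sequences are uppercased; characters outside {A,C,G,T,N} are mapped to N
    with a warning. Duplicate ids and empty files are hard errors.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate id {record.id}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            logger.warning(
                "contig %s: %d non-ACGTN characters mapped to N",
                record.id,
                sum(seq.count(c) for c in bad),
            )
            seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
        if not seq:
            raise ValueError(f"empty sequence for contig {record.id}")
        contigs.append(Contig(id=record.id, seq=seq))
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return contigs


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def read_genes(
    path: str | Path, contigs: Sequence[Contig]
) -> dict[str, list[Gene]]:
    """Read CDS records from a GFF3 file and group them per contig.

    Genes are sorted by (start, end) and re-indexed from 0 per contig.
    Missing ``rbs_motif`` maps to no motif (binned as "None" downstream);
    missing start codon maps to "other". A gene outside its contig's bounds
    is a hard error. Contigs with zero genes are retained with empty lists.
    """
    lengths = {c.id: c.length for c in contigs}
    per_contig: dict[str, list[dict]] = {c.id: [] for c in contigs}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields[:9]
            if ftype != "CDS":
                continue
            if seqid not in lengths:
                raise ValueError(f"{path}:{lineno}: unknown contig {seqid!r}")
            start, end = int(start_s), int(end_s)
            if not (1 <= start <= end <= lengths[seqid]):
                raise ValueError(
                    f"{path}:{lineno}: gene {start}-{end} outside contig "
                    f"{seqid} (length {lengths[seqid]})"
                )
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = _parse_gff_attributes(attr_s)
            codon = attrs.get("start_codon", attrs.get("start_type", "other")).upper()
            if codon not in _START_CODONS[:-1]:
                codon = "other"
            rbs = attrs.get("rbs_motif")
            if rbs in ("", "None"):
                rbs = None
            gc = float(attrs.get("gc_cont", 0.5))
            per_contig[seqid].append(
                dict(start=start, end=end, strand=strand, start_codon=codon,
                     gc=gc, rbs_motif=rbs)
            )
    out: dict[str, list[Gene]] = {}
    for cid, rows in per_contig.items():
        rows.sort(key=lambda r: (r["start"], r["end"]))
        out[cid] = [Gene(contig_id=cid, index=i, **row) for i, row in enumerate(rows)]
    return out


def write_genes(path: str | Path, genes_by_contig: Mapping[str, Sequence[Gene]]) -> None:
    """Write genes back to GFF3 (round-trips with :func:`read_genes`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid in genes_by_contig:
            for g in genes_by_contig[cid]:
                attrs = [f"ID={cid}_{g.index}", f"start_codon={g.start_codon}",
                         f"gc_cont={float(g.gc)!r}"]
                if g.rbs_motif is not None:
                    attrs.append(f"rbs_motif={g.rbs_motif}")
                fh.write(
                    f"{cid}\tviroscan\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                    + ";".join(attrs) + "\n"
                )


def read_catalog(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read the profile catalog: profile_id -> (category, hallmark groups)."""
    catalog: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            pid, category, hallmark_s = fields[:3]
            if category not in HIT_CATEGORIES:
                raise ValueError(f"{path}:{lineno}: unknown category {category!r}")
            groups = frozenset() if hallmark_s in ("-", "") else frozenset(hallmark_s.split(","))
            if groups and category != "viral":
                raise ValueError(f"{path}:{lineno}: hallmark profile {pid} must be viral")
            catalog[pid] = (category, groups)
    return catalog


def read_hit_table(
    path: str | Path, catalog: Mapping[str, tuple[str, frozenset[str]]]
) -> list[ProfileHit]:
    """Read the 4-column hit TSV, resolving categories through the catalog.

    A profile_id absent from the catalog or a malformed score is a hard
    error naming the line.
    """
    hits: list[ProfileHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            cid, idx_s, pid, score_s = fields[:4]
            try:
                idx = int(idx_s)
                score = float(score_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if pid not in catalog:
                raise ValueError(f"{path}:{lineno}: profile {pid!r} not in catalog")
            category, groups = catalog[pid]
            hits.append(
                ProfileHit(contig_id=cid, gene_index=idx, profile_id=pid,
                           bit_score=score, category=category, hallmark_groups=groups)
            )
    return hits


def _hit_rank(hit: ProfileHit) -> tuple:
    # Higher score first; ties by category priority, then lexicographic id.
    return (-hit.bit_score, _CATEGORY_PRIORITY[hit.category], hit.profile_id)


def assign_categories(
    contigs: Sequence[Contig],
    genes_by_contig: Mapping[str, Sequence[Gene]],
    hits: Iterable[ProfileHit],
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> list[ContigAnnotation]:
    """Resolve each gene's category from its best retained profile hit.

    Hits below ``score_cutoff`` bits are discarded (a hit at exactly the
    cutoff is retained). Among retained hits the single best by bit score
    wins; ties are broken by category priority viral > archaeal > bacterial
    > eukaryotic > mixed, then lexicographic profile id, so the result is
    independent of hit order. Genes with no retained hit are ``unaligned``.
    """
    by_gene: dict[tuple[str, int], list[ProfileHit]] = {}
    known = {(cid, g.index) for cid, genes in genes_by_contig.items() for g in genes}
    for hit in hits:
        key = (hit.contig_id, hit.gene_index)
        if key not in known:
            raise ValueError(f"hit references unknown gene {key}")
        if hit.bit_score >= score_cutoff:
            by_gene.setdefault(key, []).append(hit)

    annotations: list[ContigAnnotation] = []
    for contig in contigs:
        gas: list[GeneAnnotation] = []
        for gene in genes_by_contig.get(contig.id, []):
            retained = by_gene.get((contig.id, gene.index))
            if not retained:
                gas.append(GeneAnnotation(gene=gene, category="unaligned"))
            else:
                best = min(retained, key=_hit_rank)
                gas.append(
                    GeneAnnotation(
                        gene=gene,
                        category=best.category,
                        best_score=best.bit_score,
                        hallmark_groups=best.hallmark_groups
                        if best.category == "viral"
                        else frozenset(),
                    )
                )
        annotations.append(ContigAnnotation(contig=contig, genes=gas))
    return annotations
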