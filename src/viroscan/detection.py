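"""Contig scoring, edge trimming, provirus sliding-window scan, overlap merging.

Each contig is first scored whole with every group classifier. Any score at
or above the cutoff (default 0.5) marks the contig fully/near-fully viral;
those contigs get an exhaustive edge-trim search for residual host genes.
Contigs below the cutoff for every group are scanned with a gene-stepped
sliding window per group — window width is the group's minimal genome size —
and significant windows are extended gene by gene in 3' while the score
stays significant. Overlapping detections from different groups are merged
by keeping the longest region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from viroscan.annotation_io import (
    Contig,
    ContigAnnotation,
    assign_categories,
    read_catalog,
    read_contigs,
    read_genes,
    read_hit_table,
)
from viroscan.features import Region, features_for_regions, make_region
from viroscan.training import DEFAULT_GROUPS, GroupModel, load_model

#: Default significance cutoff on the viralness score (inclusive).
DEFAULT_SCORE_CUTOFF = 0.5

_KINDS = ("full", "trimmed", "partial")


@dataclass(frozen=True)
class Prediction:
    """A scored (sub)sequence interval attributed to one group."""

    contig_id: str
    region: Region
    group: str
    score: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown prediction kind {self.kind!r}")


@dataclass
class ScoreRecord:
    """Per-contig summary row: all group scores plus winning-region stats."""

    contig_id: str
    scores: dict[str, float]
    max_score: float
    max_group: str
    length_bp: int
    hallmark_count: int
    pct_viral: float
    pct_cellular: float


def score_region(ann: ContigAnnotation, region: Region, model: GroupModel) -> float:
    """Viralness score (forest probability) of one region; 0 with no genes."""
    if ann.n_genes == 0:
        return 0.0
    return float(model.score_regions(ann, [region])[0])


def trim_allowance(n_genes: int) -> int:
    """Maximum genes trimmable per edge: 5 or 10% of genes, whichever larger."""
    return max(5, math.ceil(0.10 * n_genes))


def trim_edges(
    ann: ContigAnnotation,
    model: GroupModel,
    cutoff: float = DEFAULT_SCORE_CUTOFF,
    full_score: float | None = None,
    refine_boundaries: bool = True,
) -> Prediction:
    """Search all 5'/3' edge trims of up to max(5, ceil(10% of genes)) genes.

    Every (a, b) trim with a + b < n is scored; the best-scoring candidate
    is returned as kind "trimmed" only if it strictly beats the untrimmed
    score (ties prefer fewer genes trimmed), else the full prediction.

    The trim search depth is capped, so a contig scoring significant despite
    a host margin deeper than the cap would retain host genes; with
    ``refine_boundaries`` (the default) the chosen region's edges are
    additionally snapped to the outermost genes whose short inward-facing
    anchor scores significant, accepted only when the snapped region scores
    at least as high as the untrimmed sequence.
    """
    n = ann.n_genes
    t = trim_allowance(n)
    candidates = [(a, b) for a in range(min(t, n - 1) + 1)
                  for b in range(min(t, n - 1) + 1) if a + b < n]
    regions = [make_region(ann, a, n - 1 - b) for a, b in candidates]
    scores = model.score_regions(ann, regions)
    if full_score is None:
        full_score = float(scores[candidates.index((0, 0))])
    order = sorted(
        range(len(candidates)),
        key=lambda k: (-scores[k], candidates[k][0] + candidates[k][1], candidates[k][0]),
    )
    best = order[0]
    (a, b), best_score = candidates[best], float(scores[best])
    first, last = a, n - 1 - b
    if refine_boundaries:
        f2, l2, refined = _refine_gene_boundaries(ann, model, first, last,
                                                  best_score, cutoff)
        if refined >= full_score:
            first, last, best_score = f2, l2, refined
    if (first, last) != (0, n - 1) and best_score > full_score:
        return Prediction(ann.contig.id, make_region(ann, first, last), model.group,
                          best_score, "trimmed")
    return Prediction(ann.contig.id, make_region(ann, 0, n - 1), model.group,
                      float(full_score), "full")


def _refine_gene_boundaries(
    ann: ContigAnnotation,
    model: GroupModel,
    first: int,
    last: int,
    score: float,
    cutoff: float,
) -> tuple[int, int, float]:
    # snap detection edges to the outermost genes whose short inward-facing
    # anchor (3 genes) scores viral: the region score dilutes too slowly to
    # localize boundaries, while per-gene anchors flip sharply at the
    # host/virus junction yet ignore isolated viral-looking host genes
    w = min(3, last - first + 1)
    head = [make_region(ann, k, min(k + w - 1, last)) for k in range(first, last + 1)]
    tail = [make_region(ann, max(k - w + 1, first), k) for k in range(first, last + 1)]
    s_head = model.score_regions(ann, head)
    s_tail = model.score_regions(ann, tail)
    sig_head = np.nonzero(s_head >= cutoff)[0]
    sig_tail = np.nonzero(s_tail >= cutoff)[0]
    if sig_head.size == 0 or sig_tail.size == 0:
        return first, last, score
    f2, l2 = first + int(sig_head[0]), first + int(sig_tail[-1])
    if f2 > l2:
        return first, last, score
    if (f2, l2) == (first, last):
        return first, last, score
    refined = float(model.score_regions(ann, [make_region(ann, f2, l2)])[0])
    if refined < cutoff:
        return first, last, score
    return f2, l2, refined


def sliding_window_detect(
    ann: ContigAnnotation,
    model: GroupModel,
    cutoff: float = DEFAULT_SCORE_CUTOFF,
    refine_boundaries: bool = True,
) -> list[Prediction]:
    """Gene-stepped window scan for viral sub-regions (proviruses).

    The window at gene i is the shortest gene run from i spanning at least
    the group's minimal window width. It slides one gene at a time while
    not significant; at the first significant window the 3' end is extended
    one gene at a time while the score stays at or above the cutoff and the
    maximal extended region is found; scanning resumes after its 3' end.
    Contigs too short for the window yield none.

    Because the score dilutes only gradually as host genes accrue, the
    maximal extension systematically overshoots the true viral 3' boundary
    (and the first significant window may start upstream of it). With
    ``refine_boundaries`` (the default) each detection's edges are therefore
    snapped to the outermost genes inside it whose individual gene score is
    significant, which localizes the host/virus junction at gene resolution;
    the raw maximal region is kept whenever no single gene is significant or
    the snapped region itself falls below the cutoff. With
    ``refine_boundaries=False`` the raw maximal extended region is emitted.
    """
    n = ann.n_genes
    if n == 0:
        return []
    starts = np.array([ga.gene.start for ga in ann.genes], dtype=np.int64)
    ends = np.array([ga.gene.end for ga in ann.genes], dtype=np.int64)
    # Minimal window end per start: smallest j with span(i, j) >= min_window.
    j_min = np.searchsorted(ends, starts + model.spec.min_window_bp - 1, side="left")
    valid = np.nonzero(j_min < n)[0]
    if valid.size == 0:
        return []
    last_valid = int(valid[-1])
    minimal = [make_region(ann, int(i), int(j_min[i])) for i in range(last_valid + 1)]
    minimal_scores = model.score_regions(ann, minimal)

    preds: list[Prediction] = []
    i = 0
    while i <= last_valid:
        if minimal_scores[i] < cutoff:
            i += 1
            continue
        j0 = int(j_min[i])
        ext = [make_region(ann, i, jj) for jj in range(j0, n)]
        ext_scores = model.score_regions(ann, ext)
        end = j0
        for off, s in enumerate(ext_scores):
            if s >= cutoff:
                end = j0 + off
            else:
                break
        first, last, score = i, end, float(ext_scores[end - j0])
        if refine_boundaries:
            first, last, score = _refine_gene_boundaries(ann, model, first, last,
                                                         score, cutoff)
        preds.append(
            Prediction(ann.contig.id, make_region(ann, first, last), model.group,
                       score, "partial")
        )
        i = end + 1
    return preds


def _group_rank(group: str, group_order: Sequence[str]) -> tuple[int, str]:
    try:
        return (group_order.index(group), group)
    except ValueError:
        return (len(group_order), group)


def resolve_overlaps(
    predictions: Sequence[Prediction],
    group_order: Sequence[str] = DEFAULT_GROUPS,
) -> list[Prediction]:
    """Merge overlapping predictions across groups, keeping the longest.

    Predictions on one contig are clustered by bp overlap (>= 1 bp,
    transitively); within each cluster the longest bp span wins, ties broken
    by higher score, then fixed group order. Output regions are pairwise
    non-overlapping; disjoint predictions pass through.
    """
    by_contig: dict[str, list[Prediction]] = {}
    for p in predictions:
        by_contig.setdefault(p.contig_id, []).append(p)
    out: list[Prediction] = []
    for cid in sorted(by_contig):
        preds = sorted(by_contig[cid], key=lambda p: (p.region.start_bp, p.region.end_bp))
        cluster: list[Prediction] = []
        cluster_end = -1
        for p in preds + [None]:
            if p is not None and (not cluster or p.region.start_bp <= cluster_end):
                cluster.append(p)
                cluster_end = max(cluster_end, p.region.end_bp)
                continue
            if cluster:
                out.append(
                    min(cluster, key=lambda q: (-q.region.span_bp, -q.score,
                                                _group_rank(q.group, group_order)))
                )
            if p is not None:
                cluster = [p]
                cluster_end = p.region.end_bp
        # note: after picking one winner per cluster, winners cannot overlap
        # because every cluster member lies within the cluster's bp hull
    return out


def classify_contig(
    ann: ContigAnnotation,
    models: Sequence[GroupModel],
    cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> tuple[ScoreRecord, list[Prediction]]:
    """Score one contig with every group model and emit predictions.

    If any full-sequence score is significant the contig is treated as
    (near-)fully viral and edge-trimmed per significant model; otherwise the
    sliding-window scan runs per model. Either way, overlapping predictions
    across groups are resolved to the longest, and a ScoreRecord with every
    group's full-sequence score is always produced (all zeros for a contig
    with no genes).
    """
    if not models:
        raise ValueError("no models supplied")
    group_order = [m.group for m in models]
    n = ann.n_genes
    if n == 0:
        rec = ScoreRecord(ann.contig.id, {m.group: 0.0 for m in models}, 0.0,
                          models[0].group, ann.contig.length, 0, 0.0, 0.0)
        return rec, []

    full = make_region(ann, 0, n - 1)
    full_scores = {m.group: float(m.score_regions(ann, [full])[0]) for m in models}
    significant = [m for m in models if full_scores[m.group] >= cutoff]
    if significant:
        raw = [trim_edges(ann, m, cutoff, full_score=full_scores[m.group])
               for m in significant]
    else:
        raw = [p for m in models for p in sliding_window_detect(ann, m, cutoff)]
    predictions = resolve_overlaps(raw, group_order)

    max_group = max(group_order, key=lambda g: (full_scores[g], -group_order.index(g)))
    if predictions:
        winner = max(predictions, key=lambda p: p.score)
        win_region, win_group = winner.region, winner.group
    else:
        win_region, win_group = full, max_group
    X = features_for_regions(ann, [win_region], win_group)[0]
    rec = ScoreRecord(
        contig_id=ann.contig.id,
        scores=full_scores,
        max_score=float(full_scores[max_group]),
        max_group=max_group,
        length_bp=ann.contig.length,
        hallmark_count=int(round(X[0])),
        pct_viral=float(X[1]),
        pct_cellular=float(X[2] + X[3] + X[4]),
    )
    return rec, predictions


# ---------------------------------------------------------------------------
# Pipeline driver and output files
# ---------------------------------------------------------------------------

SCORE_FILE = "final-viral-score.tsv"
BOUNDARY_FILE = "final-viral-boundary.tsv"
COMBINED_FASTA = "final-viral-combined.fa"


def load_models(db_dir: str | Path, include_groups: Sequence[str] | None = None) -> list[GroupModel]:
    """Load every group model directory under ``db_dir`` (optionally filtered).

    Models are returned in canonical group order, unknown groups last.
    """
    db_dir = Path(db_dir)
    models = [load_model(p) for p in sorted(db_dir.iterdir())
              if p.is_dir() and (p / "manifest.yaml").exists()]
    if include_groups is not None:
        wanted = set(include_groups)
        missing = wanted - {m.group for m in models}
        if missing:
            raise ValueError(f"no model for group(s) {sorted(missing)} in {db_dir}")
        models = [m for m in models if m.group in wanted]
    if not models:
        raise ValueError(f"no models found in {db_dir}")
    models.sort(key=lambda m: _group_rank(m.group, DEFAULT_GROUPS))
    return models


def _fasta_record_id(p: Prediction) -> str:
    if p.kind == "full":
        return f"{p.contig_id}||full"
    return f"{p.contig_id}||{p.kind}:{p.region.start_bp}-{p.region.end_bp}"


def write_outputs(
    out_dir: str | Path,
    contigs: Sequence[Contig],
    results: Sequence[tuple[ScoreRecord, list[Prediction]]],
    groups: Sequence[str],
) -> None:
    """Write the score table, boundary table and combined FASTA."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq_by_id = {c.id: c.seq for c in contigs}

    with open(out_dir / SCORE_FILE, "w") as fh:
        cols = ["seqname"] + [f"{g}_score" for g in groups] + [
            "max_score", "max_score_group", "length", "hallmark", "viral", "cellular"]
        fh.write("\t".join(cols) + "\n")
        for rec, _preds in results:
            row = [rec.contig_id]
            row += [f"{rec.scores[g]:.6f}" for g in groups]
            row += [f"{rec.max_score:.6f}", rec.max_group, str(rec.length_bp),
                    str(rec.hallmark_count), f"{rec.pct_viral:.3f}",
                    f"{rec.pct_cellular:.3f}"]
            fh.write("\t".join(row) + "\n")

    with open(out_dir / BOUNDARY_FILE, "w") as fh:
        fh.write("contig_id\tstart_bp\tend_bp\tfirst_gene\tlast_gene\tgroup\tscore\tkind\n")
        for _rec, preds in results:
            for p in preds:
                r = p.region
                fh.write(f"{p.contig_id}\t{r.start_bp}\t{r.end_bp}\t{r.first_gene}\t"
                         f"{r.last_gene}\t{p.group}\t{p.score:.6f}\t{p.kind}\n")

    with open(out_dir / COMBINED_FASTA, "w") as fh:
        for _rec, preds in results:
            for p in preds:
                seq = seq_by_id[p.contig_id]
                if p.kind == "full":
                    sub = seq
                else:
                    sub = seq[p.region.start_bp - 1 : p.region.end_bp]
                fh.write(f">{_fasta_record_id(p)}\n")
                for k in range(0, len(sub), 70):
                    fh.write(sub[k : k + 70] + "\n")


def classify_all(
    annotations: Sequence[ContigAnnotation],
    models: Sequence[GroupModel],
    cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> list[tuple[ScoreRecord, list[Prediction]]]:
    return [classify_contig(ann, models, cutoff) for ann in annotations]


def run_pipeline(
    input_fasta: str | Path,
    genes_gff: str | Path,
    hits_tsv: str | Path,
    catalog_tsv: str | Path,
    db_dir: str | Path,
    out_dir: str | Path,
    include_groups: Sequence[str] | None = None,
    min_score: float = DEFAULT_SCORE_CUTOFF,
    hit_score_cutoff: float = 30.0,
) -> list[tuple[ScoreRecord, list[Prediction]]]:
    """End-to-end run: read inputs, annotate, classify, write outputs.

    The resolved per-gene annotation is cached under ``out_dir/cache`` so a
    later :func:`rerun` can regenerate outputs (e.g. with a different score
    cutoff or group set) without re-reading the hit table.
    """
    out_dir = Path(out_dir)
    contigs = read_contigs(input_fasta)
    genes = read_genes(genes_gff, contigs)
    catalog = read_catalog(catalog_tsv)
    hits = read_hit_table(hits_tsv, catalog)
    annotations = assign_categories(contigs, genes, hits, score_cutoff=hit_score_cutoff)

    models = load_models(db_dir, include_groups)
    results = classify_all(annotations, models, cutoff=min_score)
    write_outputs(out_dir, contigs, results, [m.group for m in models])

    cache = out_dir / "cache"
    cache.mkdir(parents=True, exist_ok=True)
    _write_annotation_cache(cache / "annotations.tsv", annotations)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {"input_fasta": str(Path(input_fasta).resolve()),
             "db_dir": str(Path(db_dir).resolve()),
             "min_score": float(min_score),
             "include_groups": list(include_groups) if include_groups else None},
            fh, sort_keys=False)
    return results


def rerun(
    out_dir: str | Path,
    include_groups: Sequence[str] | None = None,
    min_score: float | None = None,
) -> list[tuple[ScoreRecord, list[Prediction]]]:
    """Regenerate outputs from a previous run's cached annotation.

    Re-reads the original FASTA and the cached per-gene annotation table;
    the hit table is not touched. ``include_groups`` / ``min_score`` default
    to the previous run's settings.
    """
    out_dir = Path(out_dir)
    with open(out_dir / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    contigs = read_contigs(cfg["input_fasta"])
    annotations = _read_annotation_cache(out_dir / "cache" / "annotations.tsv", contigs)
    groups = include_groups if include_groups is not None else cfg.get("include_groups")
    cutoff = min_score if min_score is not None else float(cfg["min_score"])
    models = load_models(cfg["db_dir"], groups)
    results = classify_all(annotations, models, cutoff=cutoff)
    write_outputs(out_dir, contigs, results, [m.group for m in models])
    return results


def _write_annotation_cache(path: Path, annotations: Sequence[ContigAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tindex\tstart\tend\tstrand\tstart_codon\tgc\t"
                 "rbs_motif\tcategory\tbest_score\thallmark_groups\n")
        for ann in annotations:
            for ga in ann.genes:
                g = ga.gene
                fh.write("\t".join([
                    g.contig_id, str(g.index), str(g.start), str(g.end), g.strand,
                    g.start_codon, repr(g.gc),
                    g.rbs_motif if g.rbs_motif is not None else "-",
                    ga.category,
                    repr(ga.best_score) if ga.best_score is not None else "-",
                    ",".join(sorted(ga.hallmark_groups)) or "-",
                ]) + "\n")


def _read_annotation_cache(path: Path, contigs: Sequence[Contig]) -> list[ContigAnnotation]:
    from viroscan.annotation_io import Gene, GeneAnnotation

    rows: dict[str, list[GeneAnnotation]] = {c.id: [] for c in contigs}
    with open(path) as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            gene = Gene(contig_id=f[0], index=int(f[1]), start=int(f[2]), end=int(f[3]),
                        strand=f[4], start_codon=f[5], gc=float(f[6]),
                        rbs_motif=None if f[7] == "-" else f[7])
            rows[f[0]].append(GeneAnnotation(
                gene=gene, category=f[8],
                best_score=None if f[9] == "-" else float(f[9]),
                hallmark_groups=frozenset() if f[10] == "-" else frozenset(f[10].split(","))))
    return [ContigAnnotation(contig=c, genes=rows[c.id]) for c in contigs]
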