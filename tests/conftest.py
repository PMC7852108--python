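"""Shared fixtures: synthetic presets, a trained model battery, a naive oracle.

Everything is generated programmatically and seeded; the session-scoped
model battery is trained once (24 genomes per group on the "easy" preset)
and reused by detection and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from viroscan.annotation_io import Contig, ContigAnnotation, Gene, GeneAnnotation
from viroscan.features import RBS_BINS, bin_rbs_motif
from viroscan.synthetic_data import load_preset, training_corpus
from viroscan.training import (
    DEFAULT_MIN_WINDOW_BP,
    GroupSpec,
    build_training_sets,
    train_group_classifier,
)

TRAIN_SEED = 101
N_TRAIN_GENOMES = 24


@pytest.fixture(scope="session")
def easy_preset():
    return load_preset("easy")


@pytest.fixture(scope="session")
def provirus_preset():
    return load_preset("provirus")


@pytest.fixture(scope="session")
def trained(easy_preset):
    """(models dict, training sets dict) for all five default groups."""
    rng = np.random.default_rng(TRAIN_SEED)
    viral, negatives = training_corpus(easy_preset, N_TRAIN_GENOMES, rng)
    sets = build_training_sets(viral, negatives, rng=rng)
    models = {
        g: train_group_classifier(ts, GroupSpec(g, DEFAULT_MIN_WINDOW_BP[g]),
                                  seed=TRAIN_SEED)
        for g, ts in sets.items()
    }
    return models, sets


@pytest.fixture(scope="session")
def models(trained):
    return list(trained[0].values())


@pytest.fixture(scope="session")
def phage_model(trained):
    return trained[0]["dsDNAphage"]


@pytest.fixture(scope="session")
def model_db(trained, tmp_path_factory):
    """All trained models saved to a database directory, as `run --db` expects."""
    from viroscan.training import save_model

    db = tmp_path_factory.mktemp("db")
    for group, model in trained[0].items():
        save_model(model, db / group)
    return db


def make_annotation(
    gene_rows: list[tuple],
    contig_len: int | None = None,
    contig_id: str = "c1",
) -> ContigAnnotation:
    """Hand-build a ContigAnnotation from rows of
    (start, end, strand, category, start_codon, gc, rbs, hallmark_groups)."""
    gas = []
    for i, row in enumerate(gene_rows):
        start, end, strand, category = row[:4]
        codon = row[4] if len(row) > 4 else "ATG"
        gc = row[5] if len(row) > 5 else 0.5
        rbs = row[6] if len(row) > 6 else None
        groups = frozenset(row[7]) if len(row) > 7 else frozenset()
        gene = Gene(contig_id=contig_id, index=i, start=start, end=end,
                    strand=strand, start_codon=codon, gc=gc, rbs_motif=rbs)
        gas.append(GeneAnnotation(gene=gene, category=category,
                                  best_score=50.0 if category != "unaligned" else None,
                                  hallmark_groups=groups))
    length = contig_len or max(g.gene.end for g in gas)
    return ContigAnnotation(contig=Contig(contig_id, "A" * length), genes=gas)


def naive_features(ann: ContigAnnotation, first: int, last: int, group: str) -> list[float]:
    """Independent per-gene-loop reimplementation of the 27 features."""
    genes = ann.genes[first : last + 1]
    n = len(genes)
    cats = {c: 0 for c in
            ("viral", "archaeal", "bacterial", "eukaryotic", "mixed", "unaligned")}
    rbs = {b: 0 for b in RBS_BINS}
    codons = {"ATG": 0, "GTG": 0, "TTG": 0}
    hall = 0
    sizes, gcs = [], []
    for ga in genes:
        cats[ga.category] += 1
        rbs[bin_rbs_motif(ga.gene.rbs_motif)] += 1
        if ga.gene.start_codon in codons:
            codons[ga.gene.start_codon] += 1
        if group in ga.hallmark_groups:
            hall += 1
        sizes.append(ga.gene.end - ga.gene.start + 1)
        gcs.append(ga.gene.gc)
    switches = overlaps = 0
    for prev, cur in zip(genes, genes[1:]):
        if prev.gene.strand != cur.gene.strand:
            switches += 1
        elif cur.gene.start <= prev.gene.end:
            overlaps += 1
    pairs = n - 1
    if first == 0 and last == ann.n_genes - 1:
        L = ann.contig.length
    else:
        L = genes[-1].gene.end - genes[0].gene.start + 1
    mean_gc = sum(gcs) / n
    var = sum((g - mean_gc) ** 2 for g in gcs) / n
    out = [float(hall)]
    out += [100.0 * cats[c] / n for c in
            ("viral", "archaeal", "bacterial", "eukaryotic", "mixed", "unaligned")]
    out += [sum(sizes) / n,
            100.0 * overlaps / pairs if pairs else 0.0,
            1000.0 * n / L,
            100.0 * switches / pairs if pairs else 0.0]
    out += [100.0 * codons[c] / n for c in ("ATG", "GTG", "TTG")]
    out += [mean_gc, var ** 0.5]
    out += [100.0 * rbs[b] / n for b in RBS_BINS]
    return out
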