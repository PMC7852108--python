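"""Scoring, edge trimming, sliding-window scan and overlap resolution."""

import numpy as np
import pytest

from viroscan.detection import (
    Prediction,
    classify_contig,
    resolve_overlaps,
    score_region,
    sliding_window_detect,
    trim_allowance,
    trim_edges,
)
from viroscan.features import Region, make_region
from viroscan.synthetic_data import annotate, load_preset, simulate_contig, simulate_provirus


@pytest.fixture(scope="module")
def preset():
    return load_preset("easy")


@pytest.fixture(scope="module")
def pv_preset():
    return load_preset("provirus")


class TestScoreRegion:
    def test_probability_bounds(self, preset, phage_model):
        rng = np.random.default_rng(0)
        ann = annotate(*simulate_contig(preset.profiles["plasmid"], 15_000, rng, "p"))
        for i in (0, ann.n_genes // 2):
            s = score_region(ann, make_region(ann, i, ann.n_genes - 1), phage_model)
            assert 0.0 <= s <= 1.0

    def test_pure_viral_contig_scores_significant(self, preset, phage_model):
        rng = np.random.default_rng(1)
        ann = annotate(*simulate_contig(preset.profiles["dsDNAphage"], 30_000, rng, "v"))
        s = score_region(ann, make_region(ann, 0, ann.n_genes - 1), phage_model)
        assert s >= 0.5

    def test_zero_gene_contig_scores_zero(self, phage_model):
        from viroscan.annotation_io import Contig, ContigAnnotation

        ann = ContigAnnotation(contig=Contig("bare", "A" * 5000), genes=[])
        assert score_region(ann, Region("bare", 0, 0, 1, 5000), phage_model) == 0.0


class TestTrimEdges:
    @pytest.mark.parametrize("n,t", [(100, 10), (20, 5), (49, 5), (51, 6)])
    def test_allowance_rule(self, n, t):
        assert trim_allowance(n) == t

    def test_score_never_below_full_sequence(self, preset, phage_model):
        rng = np.random.default_rng(2)
        for k, profile in enumerate(("dsDNAphage", "prokaryote")):
            ann = annotate(*simulate_contig(preset.profiles[profile], 20_000, rng, f"t{k}"))
            full = score_region(ann, make_region(ann, 0, ann.n_genes - 1), phage_model)
            pred = trim_edges(ann, phage_model, full_score=full)
            assert pred.score >= full

    def test_no_improvement_returns_full(self, preset, phage_model):
        rng = np.random.default_rng(3)
        ann = annotate(*simulate_contig(preset.profiles["dsDNAphage"], 25_000, rng, "v"))
        pred = trim_edges(ann, phage_model)
        if pred.kind == "full":
            assert (pred.region.first_gene, pred.region.last_gene) == (0, ann.n_genes - 1)
        else:
            full = score_region(ann, make_region(ann, 0, ann.n_genes - 1), phage_model)
            assert pred.score > full


class TestSlidingWindow:
    def test_contig_shorter_than_window_yields_nothing(self, preset, phage_model):
        rng = np.random.default_rng(4)
        ann = annotate(*simulate_contig(preset.profiles["prokaryote"], 5_000, rng, "s"))
        assert sliding_window_detect(ann, phage_model) == []

    def test_host_contig_yields_nothing(self, preset, phage_model):
        rng = np.random.default_rng(5)
        ann = annotate(*simulate_contig(preset.profiles["prokaryote"], 40_000, rng, "h"))
        assert sliding_window_detect(ann, phage_model) == []

    def test_provirus_recovered_with_90pct_gene_overlap(self, pv_preset, phage_model):
        rng = np.random.default_rng(6)
        c, genes, hits, truth = simulate_provirus(
            pv_preset.profiles["prokaryote"], pv_preset.profiles["dsDNAphage"],
            20_000, 25_000, rng, "pv")
        ann = annotate(c, genes, hits)
        preds = sliding_window_detect(ann, phage_model)
        assert preds
        best = max(preds, key=lambda p: p.region.span_bp)
        lo = max(best.region.first_gene, truth.first_gene)
        hi = min(best.region.last_gene, truth.last_gene)
        truth_genes = truth.last_gene - truth.first_gene + 1
        assert (hi - lo + 1) / truth_genes >= 0.9

    def test_brute_force_oracle_on_small_contigs(self, pv_preset, phage_model):
        """Raw-scan emissions are significant and 3'-maximal (<= 30 genes)."""
        rng = np.random.default_rng(7)
        cutoff = 0.5
        n_emitted = 0
        for k in range(12):
            if k % 2:
                ann = annotate(*simulate_contig(
                    pv_preset.profiles["prokaryote"], 18_000, rng, f"h{k}"))
            else:
                c, genes, hits, _ = simulate_provirus(
                    pv_preset.profiles["prokaryote"], pv_preset.profiles["dsDNAphage"],
                    8_000, 12_000, rng, f"p{k}")
                ann = annotate(c, genes, hits)
            assert ann.n_genes <= 30
            preds = sliding_window_detect(ann, phage_model, cutoff,
                                          refine_boundaries=False)
            n_emitted += len(preds)
            for p in preds:
                i, j = p.region.first_gene, p.region.last_gene
                assert phage_model.score_regions(ann, [make_region(ann, i, j)])[0] >= cutoff
                if j + 1 < ann.n_genes:
                    ext = phage_model.score_regions(ann, [make_region(ann, i, j + 1)])[0]
                    assert ext < cutoff
        assert n_emitted > 0

    def test_refined_emissions_stay_significant(self, pv_preset, phage_model):
        rng = np.random.default_rng(8)
        c, genes, hits, _ = simulate_provirus(
            pv_preset.profiles["prokaryote"], pv_preset.profiles["dsDNAphage"],
            30_000, 20_000, rng, "pv")
        ann = annotate(c, genes, hits)
        for p in sliding_window_detect(ann, phage_model):
            assert p.score >= 0.5


def _pred(cid, start, end, group="A", score=0.5):
    return Prediction(cid, Region(cid, 0, 0, start, end), group, score, "partial")


class TestResolveOverlaps:
    def test_longest_wins(self):
        a = _pred("c", 1, 12_000, "A", 0.6)
        b = _pred("c", 8_000, 16_000, "B", 0.9)
        assert resolve_overlaps([a, b]) == [a]

    def test_disjoint_all_kept(self):
        a = _pred("c", 1, 5_000)
        b = _pred("c", 6_000, 9_000, "B")
        assert resolve_overlaps([a, b]) == [a, b]

    def test_equal_span_higher_score_wins(self):
        a = _pred("c", 1, 5_000, "A", 0.9)
        b = _pred("c", 1, 5_000, "B", 0.7)
        assert resolve_overlaps([b, a]) == [a]

    def test_transitive_cluster_single_winner(self):
        a = _pred("c", 1, 4_000, "A")
        b = _pred("c", 3_500, 8_000, "B")
        c = _pred("c", 7_500, 9_000, "C")
        out = resolve_overlaps([a, b, c])
        assert out == [b]

    def test_output_pairwise_disjoint(self):
        rng = np.random.default_rng(9)
        preds = [_pred("c", int(s), int(s + rng.integers(500, 8000)),
                       group=str(k), score=float(rng.random()))
                 for k, s in enumerate(rng.integers(1, 30_000, size=25))]
        out = resolve_overlaps(preds)
        spans = sorted((p.region.start_bp, p.region.end_bp) for p in out)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2


class TestClassifyContig:
    def test_score_record_has_all_groups(self, preset, models):
        rng = np.random.default_rng(10)
        ann = annotate(*simulate_contig(preset.profiles["prokaryote"], 10_000, rng, "h"))
        rec, preds = classify_contig(ann, models)
        assert set(rec.scores) == {m.group for m in models}
        assert rec.max_score == max(rec.scores.values())
        assert rec.scores[rec.max_group] == rec.max_score

    def test_group_subset_restricts_columns(self, preset, models):
        rng = np.random.default_rng(11)
        ann = annotate(*simulate_contig(preset.profiles["dsDNAphage"], 15_000, rng, "v"))
        subset = [m for m in models if m.group in ("dsDNAphage", "ssDNA")]
        rec, _ = classify_contig(ann, subset)
        assert set(rec.scores) == {"dsDNAphage", "ssDNA"}

    def test_viral_contig_emits_full_or_trimmed(self, preset, models):
        rng = np.random.default_rng(12)
        ann = annotate(*simulate_contig(preset.profiles["dsDNAphage"], 30_000, rng, "v"))
        rec, preds = classify_contig(ann, models)
        assert preds and all(p.kind in ("full", "trimmed") for p in preds)
        assert rec.max_score >= 0.5

    def test_host_contig_emits_nothing(self, preset, models):
        rng = np.random.default_rng(13)
        ann = annotate(*simulate_contig(preset.profiles["eukaryote"], 8_000, rng, "h"))
        rec, preds = classify_contig(ann, models)
        assert rec.max_score < 0.5 or preds  # record always emitted
        assert isinstance(rec.length_bp, int)

    def test_zero_gene_contig_all_scores_zero(self, models):
        from viroscan.annotation_io import Contig, ContigAnnotation

        ann = ContigAnnotation(contig=Contig("bare", "A" * 3000), genes=[])
        rec, preds = classify_contig(ann, models)
        assert preds == []
        assert set(rec.scores.values()) == {0.0}
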