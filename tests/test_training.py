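"""Fragment sampling, set building, scaling, grid search and persistence."""

import numpy as np
import pytest
from sklearn.model_selection import ParameterGrid

from viroscan.features import feature_names
from viroscan.synthetic_data import annotate, load_preset, simulate_contig
from viroscan.training import (
    FRAGMENTS_PER_GENOME,
    PARAM_GRID,
    GroupSpec,
    MinMaxScaler,
    ModelLoadError,
    build_training_sets,
    generate_fragments,
    load_model,
    save_model,
    train_group_classifier,
)


@pytest.fixture(scope="module")
def genome():
    preset = load_preset("easy")
    rng = np.random.default_rng(3)
    return annotate(*simulate_contig(preset.profiles["dsDNAphage"], 40_000, rng, "g1"))


class TestGenerateFragments:
    def test_default_count_is_five(self, genome):
        frags = generate_fragments(genome, rng=np.random.default_rng(0))
        assert len(frags) == FRAGMENTS_PER_GENOME == 5

    def test_lengths_within_bounds(self, genome):
        for seed in range(5):
            for r in generate_fragments(genome, rng=np.random.default_rng(seed)):
                assert 1000 <= r.span_bp <= genome.contig.length

    def test_short_genome_skipped_with_warning(self, caplog):
        preset = load_preset("easy")
        short = annotate(*simulate_contig(preset.profiles["ssDNA"], 1000,
                                          np.random.default_rng(0), "tiny"))
        short.contig = type(short.contig)("tiny", short.contig.seq[:999])
        with caplog.at_level("WARNING"):
            assert generate_fragments(short, rng=np.random.default_rng(0)) == []
        assert "below" in caplog.text

    def test_seed_reproducibility(self, genome):
        a = generate_fragments(genome, rng=np.random.default_rng(9))
        b = generate_fragments(genome, rng=np.random.default_rng(9))
        assert a == b


def _corpus(n_viral=12, n_negative=4):
    preset = load_preset("easy")
    rng = np.random.default_rng(5)
    viral = {"dsDNAphage": [
        annotate(*simulate_contig(preset.profiles["dsDNAphage"], 30_000, rng, f"v{i}"))
        for i in range(n_viral)]}
    negatives = {s: [
        annotate(*simulate_contig(preset.profiles[s], 20_000, rng, f"{s}{i}"))
        for i in range(n)] for s, n in
        [("prokaryote", n_negative), ("eukaryote", n_negative + 2), ("plasmid", n_negative + 1)]}
    return viral, negatives


class TestBuildTrainingSets:
    def test_genome_level_nine_to_one_split(self):
        viral, negatives = _corpus(n_viral=10)
        rng = np.random.default_rng(1)
        sets = build_training_sets(viral, negatives, rng=rng)
        train_sources = {f.ann.contig.id for f in sets["dsDNAphage"].train if f.label == 1}
        test_sources = {f.ann.contig.id for f in sets["dsDNAphage"].test if f.label == 1}
        assert len(test_sources) == 1  # 10 genomes -> 9 train / 1 test
        assert not (train_sources & test_sources)

    def test_classes_balanced(self):
        viral, negatives = _corpus()
        sets = build_training_sets(viral, negatives, rng=np.random.default_rng(1))
        labels = [f.label for f in sets["dsDNAphage"].train]
        assert labels.count(1) == labels.count(0) > 0

    def test_negative_sources_contribute_equally(self):
        viral, negatives = _corpus(n_viral=30, n_negative=6)
        sets = build_training_sets(viral, negatives, rng=np.random.default_rng(1))
        neg = [f for f in sets["dsDNAphage"].train if f.label == 0]
        by_source = {s: sum(1 for f in neg if f.source == s)
                     for s in ("prokaryote", "eukaryote", "plasmid")}
        # balancing may subsample the combined pool, but sources stay within
        # one fragment of each other only if the pool itself was balanced;
        # check the stronger property on the pre-balance pool via totals
        assert max(by_source.values()) - min(by_source.values()) <= max(by_source.values()) // 3 + 1

    def test_empty_group_fatal(self):
        viral, negatives = _corpus()
        viral["empty_group"] = []
        with pytest.raises(ValueError, match="empty_group"):
            build_training_sets(viral, negatives, rng=np.random.default_rng(1))


class TestScaler:
    def test_linear_mapping(self):
        sc = MinMaxScaler.fit(np.array([[0.0], [100.0]]))
        assert sc.transform(np.array([[25.0]]))[0, 0] == pytest.approx(0.25)

    def test_no_clipping_above_train_max(self):
        sc = MinMaxScaler.fit(np.array([[0.0], [100.0]]))
        assert sc.transform(np.array([[150.0]]))[0, 0] == pytest.approx(1.5)

    def test_constant_feature_maps_to_zero(self):
        sc = MinMaxScaler.fit(np.array([[7.0, 1.0], [7.0, 2.0]]))
        out = sc.transform(np.array([[7.0, 1.5], [99.0, 2.0]]))
        assert out[:, 0].tolist() == [0.0, 0.0]

    def test_fitted_on_train_only(self):
        train = np.array([[0.0], [10.0]])
        sc = MinMaxScaler.fit(train)
        before = sc.transform(np.array([[5.0]]))[0, 0]
        # perturbing "test" data cannot move the scaler
        _ = sc.transform(np.array([[1e6]]))
        assert sc.transform(np.array([[5.0]]))[0, 0] == before == pytest.approx(0.5)


class TestTrainGroupClassifier:
    def test_grid_has_ten_cells(self):
        assert len(list(ParameterGrid(PARAM_GRID))) == 10

    def test_scores_are_probabilities_and_heldout_accuracy(self, trained):
        models, sets = trained
        model = models["dsDNAphage"]
        X, y = sets["dsDNAphage"].test_matrices()
        scores = model.score_matrix(X)
        assert np.all((scores >= 0) & (scores <= 1))
        acc = ((scores >= 0.5).astype(int) == y).mean()
        assert acc >= 0.95

    def test_heldout_f1_all_groups(self, trained):
        from viroscan.evaluation import prf

        models, sets = trained
        for g, model in models.items():
            X, y = sets[g].test_matrices()
            pred = (model.score_matrix(X) >= 0.5).astype(int)
            tp = int(((pred == 1) & (y == 1)).sum())
            fp = int(((pred == 1) & (y == 0)).sum())
            fn = int(((pred == 0) & (y == 1)).sum())
            assert prf(tp, fp, fn).f1 >= 0.9, g

    def test_single_class_fatal(self):
        viral, negatives = _corpus(n_viral=4)
        sets = build_training_sets(viral, negatives, rng=np.random.default_rng(1))
        ts = sets["dsDNAphage"]
        ts.train = [f for f in ts.train if f.label == 1]
        with pytest.raises(ValueError, match="single class"):
            train_group_classifier(ts, GroupSpec("dsDNAphage", 10_000), seed=0)

    def test_reproducible_with_same_seed(self):
        results = []
        for _ in range(2):
            viral, negatives = _corpus(n_viral=6)
            sets = build_training_sets(viral, negatives, rng=np.random.default_rng(2))
            m = train_group_classifier(sets["dsDNAphage"],
                                       GroupSpec("dsDNAphage", 10_000), seed=7)
            X, _y = sets["dsDNAphage"].test_matrices()
            results.append((m.training_meta["best_params"], m.score_matrix(X).tolist()))
        assert results[0] == results[1]


class TestPersistence:
    def test_round_trip_scores_bitwise_identical(self, trained, tmp_path):
        models, sets = trained
        model = models["dsDNAphage"]
        X, _ = sets["dsDNAphage"].test_matrices()
        before = model.score_matrix(X)
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        after = loaded.score_matrix(X)
        assert before.tolist() == after.tolist()
        assert loaded.spec == model.spec

    def test_feature_count_mismatch_fatal(self, trained, tmp_path):
        import yaml

        model = trained[0]["dsDNAphage"]
        save_model(model, tmp_path / "m")
        manifest = yaml.safe_load((tmp_path / "m" / "manifest.yaml").read_text())
        manifest["feature_order"] = manifest["feature_order"][:26]
        (tmp_path / "m" / "manifest.yaml").write_text(yaml.safe_dump(manifest))
        with pytest.raises(ModelLoadError, match="26 features"):
            load_model(tmp_path / "m")

    def test_corrupted_forest_fatal(self, trained, tmp_path):
        model = trained[0]["dsDNAphage"]
        save_model(model, tmp_path / "m")
        (tmp_path / "m" / "forest.joblib").write_bytes(b"not a model")
        with pytest.raises(ModelLoadError):
            load_model(tmp_path / "m")

    def test_missing_directory_fatal(self, tmp_path):
        with pytest.raises(ModelLoadError):
            load_model(tmp_path / "absent")


def test_feature_order_matches_module(trained):
    for model in trained[0].values():
        assert list(model.feature_order) == feature_names()
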