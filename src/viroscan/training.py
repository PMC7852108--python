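"""Per-group classifier training: fragment sampling, balancing, scaling, fitting.

One random forest is trained per viral group (defaults: dsDNAphage, NCLDV,
RNA, ssDNA, lavidaviridae). Training data are random genome fragments of at
least 1 kb: five per genome, starting at a uniform random position with
length uniform up to the distance to the 3' end. Genomes are split into
train/test at the genome level 9:1. The three negative sources (prokaryote,
eukaryote, plasmid) contribute equally — each subsampled to the smallest —
and per group the viral and negative classes are balanced to the smaller.
Features are min-max scaled on the training set only; hyperparameters
(tree count in {20, 50, 100, 150, 200} x split criterion in {gini, entropy})
are chosen by 5-fold cross-validated grid search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV

from viroscan.annotation_io import ContigAnnotation
from viroscan.features import (
    FEATURE_NAMES,
    Region,
    feature_names,
    features_for_regions,
    make_region,
)

logger = logging.getLogger(__name__)

#: Hyperparameter grid for the forest (10 cells).
PARAM_GRID = {
    "n_estimators": [20, 50, 100, 150, 200],
    "criterion": ["gini", "entropy"],
}

#: Cross-validation folds for the grid search.
CV_FOLDS = 5

#: Fragments drawn per training genome.
FRAGMENTS_PER_GENOME = 5

#: Minimum fragment length in bp.
MIN_FRAGMENT_BP = 1000

#: Default minimal sliding-window widths per group (bp). These stand in for
#: the minimal genome size of each group and are user-overridable; NCLDV
#: genomes are far larger than phage genomes, so their window is widest.
DEFAULT_MIN_WINDOW_BP = {
    "dsDNAphage": 10_000,
    "ssDNA": 1_000,
    "RNA": 1_000,
    "NCLDV": 100_000,
    "lavidaviridae": 15_000,
}

#: Canonical group order (used for deterministic tie-breaks and output columns).
DEFAULT_GROUPS = ("dsDNAphage", "NCLDV", "RNA", "ssDNA", "lavidaviridae")

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class GroupSpec:
    """Identity and window width of one viral group's classifier."""

    name: str
    min_window_bp: int
    hallmark_profile_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.min_window_bp < 1000:
            raise ValueError("min_window_bp must be >= 1000")


def default_group_specs() -> list[GroupSpec]:
    return [GroupSpec(name=g, min_window_bp=DEFAULT_MIN_WINDOW_BP[g]) for g in DEFAULT_GROUPS]


@dataclass
class MinMaxScaler:
    """Per-feature min-max scaling fitted on training data only.

    ``transform`` maps x to (x - min) / (max - min); a constant feature maps
    to 0 for every input. Values outside the training range scale beyond
    [0, 1] on purpose — forests are insensitive to monotone range excess and
    clipping would hide covariate shift.
    """

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler":
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit the scaler")
        return cls(mins=X.min(axis=0), maxs=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        span = self.maxs - self.mins
        out = np.zeros_like(X)
        nz = span != 0
        out[:, nz] = (X[:, nz] - self.mins[nz]) / span[nz]
        return out


def fit_scaler(X: np.ndarray) -> MinMaxScaler:
    return MinMaxScaler.fit(np.asarray(X, dtype=np.float64))


def apply_scaler(scaler: MinMaxScaler, X: np.ndarray) -> np.ndarray:
    return scaler.transform(X)


@dataclass
class GroupModel:
    """Scaler + random forest + window width for one viral group."""

    spec: GroupSpec
    scaler: MinMaxScaler
    forest: RandomForestClassifier
    feature_order: tuple[str, ...]
    training_meta: dict = field(default_factory=dict)

    @property
    def group(self) -> str:
        return self.spec.name

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Viral-class probability for each (unscaled) feature row."""
        Xs = self.scaler.transform(X)
        viral_col = int(np.where(self.forest.classes_ == 1)[0][0])
        return self.forest.predict_proba(Xs)[:, viral_col]

    def score_regions(self, ann: ContigAnnotation, regions: Sequence[Region]) -> np.ndarray:
        if not regions:
            return np.zeros(0)
        X = features_for_regions(ann, regions, self.group)
        return self.score_matrix(X)


@dataclass
class LabeledFragment:
    """A sampled genome fragment with its class label and provenance."""

    ann: ContigAnnotation
    region: Region
    label: int  # 1 viral, 0 nonviral
    source: str

    @property
    def length_bp(self) -> int:
        return self.region.span_bp


@dataclass
class TrainingSet:
    """Balanced training fragments and unbalanced test fragments for one group."""

    group: str
    train: list[LabeledFragment]
    test: list[LabeledFragment]

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        X = _fragment_features(self.train, self.group)
        y = np.array([f.label for f in self.train])
        return X, y

    def test_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        X = _fragment_features(self.test, self.group)
        y = np.array([f.label for f in self.test])
        return X, y


def _fragment_features(fragments: Sequence[LabeledFragment], group: str) -> np.ndarray:
    if not fragments:
        return np.zeros((0, len(FEATURE_NAMES)))
    return np.vstack(
        [features_for_regions(f.ann, [f.region], group) for f in fragments]
    )


def generate_fragments(
    genome: ContigAnnotation,
    n: int = FRAGMENTS_PER_GENOME,
    min_len: int = MIN_FRAGMENT_BP,
    rng: np.random.Generator | None = None,
    max_retries: int = 50,
) -> list[Region]:
    """Sample ``n`` random fragments of at least ``min_len`` bp from a genome.

    Each fragment starts at a uniform random position that leaves room for
    ``min_len`` bp, with length uniform between ``min_len`` and the distance
    to the 3' end. The fragment is snapped to the genes whose midpoint lies
    inside the bp window; draws whose snapped gene span is shorter than
    ``min_len`` (or empty) are redrawn a bounded number of times. Genomes
    shorter than ``min_len`` are skipped with a warning (empty list).
    """
    rng = rng or np.random.default_rng()
    L = genome.contig.length
    if L < min_len:
        logger.warning("genome %s (%d bp) below %d bp; skipped", genome.contig.id, L, min_len)
        return []
    if genome.n_genes == 0:
        logger.warning("genome %s has no genes; skipped", genome.contig.id)
        return []
    mids = np.array([(ga.gene.start + ga.gene.end) / 2.0 for ga in genome.genes])
    regions: list[Region] = []
    for _ in range(n):
        region = None
        for _try in range(max_retries):
            start = int(rng.integers(1, L - min_len + 2))
            length = int(rng.integers(min_len, L - start + 2))
            end = start + length - 1
            inside = np.nonzero((mids >= start) & (mids <= end))[0]
            if inside.size == 0:
                continue
            cand = make_region(genome, int(inside[0]), int(inside[-1]))
            if cand.span_bp >= min_len:
                region = cand
                break
        if region is not None:
            regions.append(region)
    return regions


def _split_genomes(
    genomes: Sequence[ContigAnnotation], split_ratio: float, rng: np.random.Generator
) -> tuple[list[ContigAnnotation], list[ContigAnnotation]]:
    n = len(genomes)
    order = rng.permutation(n)
    n_train = int(round(split_ratio * n))
    if n >= 2:
        n_train = min(max(n_train, 1), n - 1)
    train_idx = set(order[:n_train].tolist())
    train = [genomes[i] for i in sorted(train_idx)]
    test = [genomes[i] for i in range(n) if i not in train_idx]
    return train, test


def _fragments_for(
    genomes: Sequence[ContigAnnotation],
    label: int,
    source: str,
    rng: np.random.Generator,
    n_fragments: int,
    min_len: int,
) -> list[LabeledFragment]:
    out: list[LabeledFragment] = []
    for g in genomes:
        for region in generate_fragments(g, n=n_fragments, min_len=min_len, rng=rng):
            out.append(LabeledFragment(ann=g, region=region, label=label, source=source))
    return out


def _subsample(
    items: list, k: int, rng: np.random.Generator
) -> list:
    if k >= len(items):
        return list(items)
    idx = rng.choice(len(items), size=k, replace=False)
    return [items[i] for i in sorted(idx)]


def build_training_sets(
    viral_genomes: Mapping[str, Sequence[ContigAnnotation]],
    negative_genomes: Mapping[str, Sequence[ContigAnnotation]],
    split_ratio: float = 0.9,
    n_fragments: int = FRAGMENTS_PER_GENOME,
    min_len: int = MIN_FRAGMENT_BP,
    rng: np.random.Generator | None = None,
) -> dict[str, TrainingSet]:
    """Build one balanced train / held-out test fragment set per viral group.

    Genomes (not fragments) are split 9:1; negative fragments are subsampled
    so the three negative sources contribute equally; per group the viral
    and negative training fragments are balanced to the smaller class. Test
    fragments are left unbalanced. Any class left empty is a hard error.
    """
    rng = rng or np.random.default_rng()

    neg_train_pools: dict[str, list[LabeledFragment]] = {}
    neg_test_pools: dict[str, list[LabeledFragment]] = {}
    for source, genomes in negative_genomes.items():
        if not genomes:
            raise ValueError(f"negative source {source!r} is empty")
        tr, te = _split_genomes(list(genomes), split_ratio, rng)
        neg_train_pools[source] = _fragments_for(tr, 0, source, rng, n_fragments, min_len)
        neg_test_pools[source] = _fragments_for(te, 0, source, rng, n_fragments, min_len)

    if any(not v for v in neg_train_pools.values()):
        empty = [s for s, v in neg_train_pools.items() if not v]
        raise ValueError(f"no training fragments from negative source(s) {empty}")
    k = min(len(v) for v in neg_train_pools.values())
    neg_train = [f for source in sorted(neg_train_pools) for f in _subsample(neg_train_pools[source], k, rng)]
    neg_test = [f for source in sorted(neg_test_pools) for f in neg_test_pools[source]]

    sets: dict[str, TrainingSet] = {}
    for group, genomes in viral_genomes.items():
        if not genomes:
            raise ValueError(f"viral group {group!r} has no genomes")
        tr, te = _split_genomes(list(genomes), split_ratio, rng)
        viral_train = _fragments_for(tr, 1, group, rng, n_fragments, min_len)
        viral_test = _fragments_for(te, 1, group, rng, n_fragments, min_len)
        if not viral_train:
            raise ValueError(f"viral group {group!r} yielded no training fragments")
        m = min(len(viral_train), len(neg_train))
        train = _subsample(viral_train, m, rng) + _subsample(neg_train, m, rng)
        sets[group] = TrainingSet(group=group, train=train, test=viral_test + neg_test)
    return sets


def train_group_classifier(
    training_set: TrainingSet,
    spec: GroupSpec,
    seed: int,
    cv: int = CV_FOLDS,
) -> GroupModel:
    """Grid-search and fit the random forest for one group.

    The winning (n_estimators, criterion) pair is refitted on the full
    training set; the scaler is fitted on training features only.
    """
    X, y = training_set.matrices()
    if len(np.unique(y)) < 2:
        raise ValueError(f"group {spec.name}: training data has a single class")
    scaler = MinMaxScaler.fit(X)
    Xs = scaler.transform(X)
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed),
        PARAM_GRID,
        cv=cv,
        scoring="f1",
        n_jobs=1,
    )
    search.fit(Xs, y)
    meta = {
        "seed": int(seed),
        "n_train": int(len(y)),
        "n_viral": int(y.sum()),
        "best_params": {k: (int(v) if isinstance(v, (int, np.integer)) else str(v))
                        for k, v in search.best_params_.items()},
        "best_cv_f1": float(search.best_score_),
    }
    return GroupModel(
        spec=spec,
        scaler=scaler,
        forest=search.best_estimator_,
        feature_order=tuple(feature_names()),
        training_meta=meta,
    )


class ModelLoadError(RuntimeError):
    """A model directory is missing, corrupted, or feature-incompatible."""


def save_model(model: GroupModel, path: str | Path) -> None:
    """Persist a GroupModel as a directory: scaler TSV, forest, YAML manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "scaler.tsv", "w") as fh:
        fh.write("feature\tmin\tmax\n")
        for name, lo, hi in zip(model.feature_order, model.scaler.mins, model.scaler.maxs):
            fh.write(f"{name}\t{float(lo)!r}\t{float(hi)!r}\n")
    joblib.dump(model.forest, path / "forest.joblib")
    manifest = {
        "format_version": _MODEL_FORMAT_VERSION,
        "group": model.spec.name,
        "min_window_bp": int(model.spec.min_window_bp),
        "hallmark_profile_ids": sorted(model.spec.hallmark_profile_ids),
        "feature_order": list(model.feature_order),
        "training_meta": model.training_meta,
    }
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def load_model(path: str | Path) -> GroupModel:
    """Load a model directory; feature-order mismatch or corruption is fatal."""
    path = Path(path)
    try:
        with open(path / "manifest.yaml") as fh:
            manifest = yaml.safe_load(fh)
        rows: dict[str, tuple[float, float]] = {}
        with open(path / "scaler.tsv") as fh:
            next(fh)
            for line in fh:
                name, lo, hi = line.rstrip("\n").split("\t")
                rows[name] = (float(lo), float(hi))
    except (OSError, ValueError, KeyError, yaml.YAMLError) as exc:
        raise ModelLoadError(f"cannot load model at {path}: {exc}") from exc
    try:
        forest = joblib.load(path / "forest.joblib")
    except Exception as exc:  # joblib/pickle raise a zoo of corruption errors
        raise ModelLoadError(f"cannot load forest at {path}: {exc}") from exc
    if not isinstance(manifest, dict) or "feature_order" not in manifest:
        raise ModelLoadError(f"cannot load model at {path}: malformed manifest")
    order = tuple(manifest["feature_order"])
    if order != tuple(feature_names()):
        raise ModelLoadError(
            f"model at {path} was trained with {len(order)} features "
            f"{order[:3]}...; this build expects {len(feature_names())}"
        )
    if set(rows) != set(order):
        raise ModelLoadError(f"scaler at {path} does not cover the feature set")
    mins = np.array([rows[n][0] for n in order])
    maxs = np.array([rows[n][1] for n in order])
    spec = GroupSpec(
        name=manifest["group"],
        min_window_bp=int(manifest["min_window_bp"]),
        hallmark_profile_ids=frozenset(manifest.get("hallmark_profile_ids", [])),
    )
    return GroupModel(
        spec=spec,
        scaler=MinMaxScaler(mins=mins, maxs=maxs),
        forest=forest,
        feature_order=order,
        training_meta=manifest.get("training_meta", {}),
    )
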