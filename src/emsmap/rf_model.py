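"""Random-forest regression of per-base mutation probability.

The forest groups bases with similar chromatin features and sequence-context
baseline into leaves and predicts each base's per-strain mutation
probability as the mean training target of its leaf, averaged over trees:

    P(base) = alpha * (1/T) * sum_t f_t(x, P0)

``alpha`` is the mutagen-effectiveness scalar (1 for the training cohort by
the per-strain target encoding; see :mod:`emsmap.screen_stats` for batch
normalisation).  Production-scale defaults follow the published model: 600
trees, at most 70 % of features per split and a minimum leaf of 30,000
bases; desk-scale work on synthetic genomes typically uses 100 trees and a
minimum leaf of 200.

The "at most 70 % of the features" rule is read as a per-split cap, the
standard random-forest semantics; ``per_tree_subset=True`` implements the
alternative reading in which each tree sees a fixed random feature subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split as _sk_split
from sklearn.tree import DecisionTreeRegressor

from .chromatin_features import FeatureMatrix


@dataclass
class RandomForestModel:
    """A trained forest plus the metadata needed to apply it reproducibly."""

    forest: RandomForestRegressor | None
    trees: list[tuple[DecisionTreeRegressor, np.ndarray]] | None
    column_order: list[str]
    training_n_strains: int
    n_trees: int
    min_leaf: int
    max_feature_frac: float
    bootstrap_frac: float | None
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if self.forest is not None:
            return self.forest.predict(X)
        total = np.zeros(X.shape[0])
        for tree, cols in self.trees:
            total += tree.predict(X[:, cols])
        return total / len(self.trees)

    def iter_trees(self):
        if self.forest is not None:
            for est in self.forest.estimators_:
                yield est
        else:
            for tree, _ in self.trees:
                yield tree

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "RandomForestModel":
        return joblib.load(path)


def max_features_per_split(max_feature_frac: float, n_features: int) -> int:
    """floor(frac * n_features), at least 1."""
    return max(1, int(np.floor(max_feature_frac * n_features)))


def train_rf(
    matrix: FeatureMatrix,
    n_trees: int = 600,
    min_leaf: int = 30_000,
    max_feature_frac: float = 0.7,
    bootstrap: bool = True,
    bootstrap_frac: float | None = None,
    per_tree_subset: bool = False,
    seed: int = 0,
    n_jobs: int = 1,
) -> RandomForestModel:
    """Train the mutation-probability forest on a feature matrix.

    ``bootstrap_frac`` sets the per-tree row sample as a fraction of the
    training rows (sampling with replacement); ``None`` means full-size
    bootstrap.  ``min_leaf`` must be smaller than the row count.
    """
    if min_leaf >= matrix.n_rows:
        raise ValueError(
            f"min_leaf={min_leaf} must be smaller than the {matrix.n_rows} training rows"
        )
    mf = max_features_per_split(max_feature_frac, matrix.n_features)
    rng = np.random.default_rng(seed)
    if per_tree_subset:
        trees = []
        n_rows = matrix.n_rows
        samp = n_rows if bootstrap_frac is None else max(1, int(bootstrap_frac * n_rows))
        for _ in range(n_trees):
            cols = np.sort(rng.choice(matrix.n_features, size=mf, replace=False))
            rows = (
                rng.integers(0, n_rows, size=samp)
                if bootstrap
                else np.arange(n_rows)
            )
            tree = DecisionTreeRegressor(
                min_samples_leaf=min_leaf,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(matrix.X[rows][:, cols], matrix.y[rows])
            trees.append((tree, cols))
        forest = None
    else:
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            min_samples_leaf=min_leaf,
            max_features=mf,
            bootstrap=bootstrap,
            max_samples=bootstrap_frac if bootstrap else None,
            random_state=seed,
            n_jobs=n_jobs,
        )
        forest.fit(matrix.X, matrix.y)
        trees = None
    return RandomForestModel(
        forest=forest,
        trees=trees,
        column_order=list(matrix.column_order),
        training_n_strains=matrix.n_strains,
        n_trees=n_trees,
        min_leaf=min_leaf,
        max_feature_frac=max_feature_frac,
        bootstrap_frac=bootstrap_frac,
        seed=seed,
    )


def train_test_split(
    matrix: FeatureMatrix, test_frac: float = 0.2, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Random disjoint row partition into training and test matrices."""
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    idx = np.arange(matrix.n_rows)
    train_idx, test_idx = _sk_split(idx, test_size=test_frac, random_state=seed)
    return matrix.take(np.sort(train_idx)), matrix.take(np.sort(test_idx))


@dataclass
class MutProbMap:
    """Genome-wide per-base per-strain mutation probability.

    ``values[chrom][pos]`` is alpha times the model's per-strain probability;
    bases excluded from the feature matrix carry the flagged central-base
    fallback.  ``flags`` marks those fallback bases.
    """

    values: dict[str, np.ndarray]
    alpha: float = 1.0
    flags: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, v in self.values.items():
            if (np.asarray(v) < 0).any():
                raise ValueError(f"negative probability on {chrom}")

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.values[chrom]

    def rescaled(self, alpha: float) -> "MutProbMap":
        """The same map at a different effectiveness (values scale by
        alpha / current alpha)."""
        factor = alpha / self.alpha
        return MutProbMap(
            {c: v * factor for c, v in self.values.items()},
            alpha=alpha,
            flags=self.flags,
            provenance=self.provenance,
        )

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


def predict_map(
    model: RandomForestModel,
    matrix: FeatureMatrix,
    alpha: float = 1.0,
    column_order: list[str] | None = None,
) -> MutProbMap:
    """Predict the genome-wide probability map from a feature matrix.

    Retained bases get alpha times the forest prediction; flagged bases get
    alpha times the per-strain central-base baseline recorded in the matrix.
    """
    cols = column_order if column_order is not None else matrix.column_order
    if list(cols) != list(model.column_order):
        raise ValueError(
            f"feature columns {cols} do not match model columns {model.column_order}"
        )
    pred = np.clip(model.predict(matrix.X), 0.0, None)
    values = {}
    for ci, chrom in enumerate(matrix.chrom_names):
        v = matrix.baseline[chrom] * alpha
        rows = matrix.row_chrom == ci
        v = v.copy()
        v[matrix.row_pos[rows]] = pred[rows] * alpha
        values[chrom] = v
    return MutProbMap(
        values,
        alpha=alpha,
        flags=matrix.flags,
        provenance={
            "model_seed": model.seed,
            "n_trees": model.n_trees,
            "min_leaf": model.min_leaf,
            "columns": list(model.column_order),
        },
    )


def baseline_map(matrix: FeatureMatrix, alpha: float = 1.0) -> MutProbMap:
    """Probability map from the sequence-context baseline alone (no forest)."""
    return MutProbMap(
        {c: v * alpha for c, v in matrix.baseline.items()},
        alpha=alpha,
        flags=matrix.flags,
        provenance={"columns": ["P0"]},
    )
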