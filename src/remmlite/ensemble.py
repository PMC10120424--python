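"""Imbalance-aware hyper-ensemble of SMOTE-undersampled random forests.

The learning scheme (known in the field as hyperSMURF) targets datasets
where positives are outnumbered by three to five orders of magnitude, as in
noncoding pathogenic-variant training sets (hundreds of pathogenic SNVs
against ~14 million proxy-benign variants). It works as follows:

1. the minority class is oversampled with SMOTE: each original positive
   spawns ``oversample_factor`` synthetic points, each interpolated a
   uniform fraction of the way toward one of its k nearest minority
   neighbours (Euclidean distance on the imputed, unscaled features);
2. the majority class is shuffled and split into ``n_partitions``
   non-overlapping partitions; each partition is subsampled down to
   ``ratio`` x |original minority| points without replacement;
3. one random forest is trained per partition on
   (original minority + SMOTE synthetics) ∪ (subsampled partition);
4. the score of a variant is the arithmetic mean of the member forests'
   class-1 probability estimates — a value in [0, 1].

With the classic configuration (factor 2, ratio 3, 100 partitions) and a
minority of 406 variants, each member trains on 1,218 minority and 1,218
majority points, roughly 2,400 in total. Averaging over members recovers
coverage of the majority-class space that any single subsample lacks.

Randomness is controlled by a single master seed; a child stream is derived
per partition index so changing ``n_partitions`` does not perturb the
training sets of earlier partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from .datamodel import FeatureMatrix
from .imputation import ImputationPolicy, impute

__all__ = [
    "HyperSmurfConfig",
    "EnsembleModel",
    "smote_oversample",
    "partition_majority",
    "subsample_partition",
    "fit_ensemble",
    "gini_importance",
]


@dataclass(frozen=True)
class HyperSmurfConfig:
    """Sampling and forest hyperparameters of the ensemble.

    ``oversample_factor`` counts SMOTE synthetics generated per original
    positive (factor 2 turns 406 positives into a minority of 1,218);
    ``ratio`` sets the negatives drawn per partition as a multiple of the
    *original* minority size. Defaults follow the published configuration:
    100 partitions, factor 2, ratio 3, k = 5 SMOTE neighbours, 10 trees per
    member forest.
    """

    n_partitions: int = 100
    oversample_factor: int = 2
    ratio: int = 3
    smote_k: int = 5
    trees_per_forest: int = 10
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")
        if self.oversample_factor < 1:
            raise ValueError("oversample_factor must be >= 1")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if self.trees_per_forest < 1:
            raise ValueError("trees_per_forest must be >= 1")

    def with_seed(self, seed: int) -> "HyperSmurfConfig":
        return replace(self, seed=int(seed))


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def smote_oversample(
    minority: np.ndarray,
    factor: int,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate ``factor x |minority|`` synthetic minority vectors.

    Each synthetic point is ``x + u * (x_nn - x)`` for an original point x,
    one of its k Euclidean nearest minority neighbours x_nn (self excluded),
    and u ~ Uniform(0, 1). Deterministic given ``rng``.
    """
    minority = np.asarray(minority, dtype=float)
    n = minority.shape[0]
    if n < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    if k >= n:
        raise ValueError(
            f"smote_k={k} must be smaller than the minority size {n}; lower k"
        )
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    # column 0 is the point itself (or an exact duplicate; either way a
    # valid interpolation endpoint), drop it
    neigh = nn.kneighbors(minority, return_distance=False)[:, 1:]
    base = np.repeat(np.arange(n), factor)
    choice = rng.integers(0, k, size=base.size)
    partners = neigh[base, choice]
    u = rng.random(base.size)[:, None]
    return minority[base] + u * (minority[partners] - minority[base])


def partition_majority(
    indices: np.ndarray | Sequence[int],
    n_partitions: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Shuffle majority indices and split into non-overlapping partitions.

    Sizes differ by at most one; the first ``N mod n`` partitions carry the
    extra element.
    """
    indices = np.asarray(indices)
    if n_partitions > indices.size:
        raise ValueError(
            f"n_partitions={n_partitions} exceeds majority size {indices.size}"
        )
    shuffled = rng.permutation(indices)
    return list(np.array_split(shuffled, n_partitions))


def subsample_partition(
    partition: np.ndarray,
    ratio: int,
    minority_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform sample without replacement of ``ratio * minority_size`` indices.

    If the target exceeds the partition (degenerate small-data case) the
    whole partition is returned with a warning.
    """
    partition = np.asarray(partition)
    target = ratio * minority_size
    if target > partition.size:
        warnings.warn(
            f"subsample target {target} exceeds partition size {partition.size}; "
            "using the whole partition",
            stacklevel=2,
        )
        return partition.copy()
    return rng.choice(partition, size=target, replace=False)


@dataclass
class EnsembleModel:
    """Fitted partition-wise forests plus sampling metadata.

    ``partition_info`` records, per member, the majority indices it trained
    on and the minority/majority set sizes, for audit.
    """

    forests: list[RandomForestClassifier]
    config: HyperSmurfConfig
    feature_names: list[str]
    imputer: ImputationPolicy | None = None
    partition_info: list[dict] = field(default_factory=list)

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            if X.feature_names != self.feature_names:
                raise ValueError(
                    "feature names of the query matrix do not match the model"
                )
            if not X.is_imputed:
                if self.imputer is None:
                    raise ValueError(
                        "query matrix has missing values and the model stores "
                        "no imputation policy"
                    )
                X = impute(X, self.imputer)
            return X.values
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected a 2-D array with {len(self.feature_names)} features"
            )
        if np.isnan(X).any():
            raise ValueError("query array contains NaN; impute first")
        return X

    def predict(self, X) -> np.ndarray:
        """Pathogenicity score per row: mean of member class-1 probabilities."""
        arr = self._as_array(X)
        acc = np.zeros(arr.shape[0])
        for rf in self.forests:
            acc += rf.predict_proba(arr)[:, list(rf.classes_).index(1)]
        return acc / len(self.forests)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain an EnsembleModel")
        return model


def fit_ensemble(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray | Sequence[int],
    config: HyperSmurfConfig,
    imputer: ImputationPolicy | None = None,
    feature_names: Sequence[str] | None = None,
) -> EnsembleModel:
    """Train the partitioned ensemble on an imputed feature matrix.

    ``y`` is binary with 1 = minority/pathogenic. ``X`` must contain no
    missing values (impute first); a fitted ``imputer`` may be attached so
    the model can impute query matrices at scoring time. Fully reproducible
    from ``config.seed``.
    """
    if isinstance(X, FeatureMatrix):
        if not X.is_imputed:
            raise ValueError("feature matrix has missing values; run impute() first")
        feature_names = X.feature_names
        arr = X.values
    else:
        arr = np.asarray(X, dtype=float)
        if np.isnan(arr).any():
            raise ValueError("X contains NaN; run impute() first")
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(arr.shape[1])]
    y = np.asarray(y, dtype=int)
    if y.shape[0] != arr.shape[0]:
        raise ValueError("X and y lengths differ")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("y must contain both classes 0 and 1")

    minority_idx = np.flatnonzero(y == 1)
    majority_idx = np.flatnonzero(y == 0)
    minority = arr[minority_idx]

    part_rng = _child_rng(config.seed, 0)
    partitions = partition_majority(majority_idx, config.n_partitions, part_rng)

    forests: list[RandomForestClassifier] = []
    info: list[dict] = []
    for i, partition in enumerate(partitions):
        rng = _child_rng(config.seed, 1, i)
        synth = smote_oversample(
            minority, config.oversample_factor, config.smote_k, rng
        )
        neg = subsample_partition(partition, config.ratio, minority.shape[0], rng)
        X_tr = np.vstack([minority, synth, arr[neg]])
        y_tr = np.concatenate(
            [
                np.ones(minority.shape[0] + synth.shape[0], dtype=int),
                np.zeros(neg.size, dtype=int),
            ]
        )
        rf = RandomForestClassifier(
            n_estimators=config.trees_per_forest,
            max_features=config.max_features,
            max_depth=config.max_depth,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(X_tr, y_tr)
        forests.append(rf)
        info.append(
            {
                "partition": i,
                "n_minority": int(minority.shape[0]),
                "n_synthetic": int(synth.shape[0]),
                "n_majority": int(neg.size),
                "majority_indices": neg,
            }
        )
    return EnsembleModel(
        forests=forests,
        config=config,
        feature_names=list(feature_names),
        imputer=imputer,
        partition_info=info,
    )


def gini_importance(model: EnsembleModel) -> pd.DataFrame:
    """Mean impurity-decrease (Gini) importance across the member forests.

    Returns a DataFrame indexed by feature with columns ``importance`` (the
    per-forest Gini importances averaged over members) and ``rank``
    (1 = most important; ties share the smallest rank by order of
    appearance).
    """
    if not model.forests:
        raise ValueError("model has no fitted forests")
    imp = np.mean([rf.feature_importances_ for rf in model.forests], axis=0)
    order = np.argsort(-imp, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(imp) + 1)
    return pd.DataFrame(
        {"importance": imp, "rank": rank}, index=pd.Index(model.feature_names, name="feature")
    )
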