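"""Cytoband-aware stratified cross-validation.

Genomic annotations are locally correlated, and known pathogenic variants
cluster around well-studied loci; a variant-level random split therefore
leaks neighbourhood information and inflates held-out performance. The
remedy used here assigns whole cytogenetic bands to folds: every variant of
a band — pathogenic and proxy-benign alike — lands in the same fold, so a
model is never validated on a neighbourhood it trained on.

Fold assignment balances pathogenic counts across folds with a greedy
longest-processing-time heuristic: bands carrying positives are sorted by
descending count and each is placed on the currently lightest fold (ties to
the lowest fold index); bands without positives are assigned uniformly at
random from a dedicated child seed. The max-min spread of fold pathogenic
counts is then bounded by the largest single-band count.

``cross_validate`` trains one ensemble per fold on the other folds and
scores the held-out fold, so every training variant receives exactly one
unbiased score. ``make_final_track`` builds the release track: held-out CV
scores at training positions, general-model scores everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datamodel import CytobandMap, FeatureMatrix, ScoreTrack, VariantRecord
from .ensemble import EnsembleModel, HyperSmurfConfig, fit_ensemble
from .imputation import ImputationPolicy, fit_imputer, impute, policy_from_metadata
from .metrics import curve

__all__ = [
    "FoldAssignment",
    "CvResult",
    "assign_folds",
    "cross_validate",
    "cross_validate_raw_forest",
    "make_final_track",
    "repeat_cv",
]


@dataclass
class FoldAssignment:
    """Band -> fold map (folds numbered 1..n_folds)."""

    band_to_fold: dict[str, int]
    n_folds: int

    def fold_of(self, band: str) -> int:
        return self.band_to_fold[band]

    def to_table(self) -> list[tuple[str, int]]:
        return sorted(self.band_to_fold.items())


def assign_folds(
    bands: CytobandMap | Sequence[str],
    pathogenic_counts: Mapping[str, int],
    n_folds: int = 10,
    rng: np.random.Generator | int | None = None,
) -> FoldAssignment:
    """Assign every band to one of ``n_folds`` folds, balancing positives.

    ``pathogenic_counts`` maps band name -> pathogenic variant count (bands
    absent from the mapping count 0). Guarantees
    ``max - min fold count <= max single-band count``.
    """
    band_names = bands.band_names if isinstance(bands, CytobandMap) else list(bands)
    if not band_names:
        raise ValueError("empty band list")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    total = sum(pathogenic_counts.get(b, 0) for b in band_names)
    if total < n_folds:
        raise ValueError(
            f"only {total} pathogenic variants for {n_folds} folds; reduce n_folds"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    loaded = [(b, pathogenic_counts.get(b, 0)) for b in band_names]
    carrying = [bc for bc in loaded if bc[1] > 0]
    empty = [b for b, c in loaded if c == 0]

    # greedy LPT: heaviest band first, onto the lightest fold
    carrying.sort(key=lambda bc: -bc[1])
    fold_load = np.zeros(n_folds, dtype=int)
    assignment: dict[str, int] = {}
    for band, count in carrying:
        f = int(np.argmin(fold_load))  # argmin ties -> lowest index
        assignment[band] = f + 1
        fold_load[f] += count
    for band in empty:
        assignment[band] = int(rng.integers(1, n_folds + 1))
    return FoldAssignment(assignment, n_folds)


@dataclass
class CvResult:
    """Held-out scores and per-fold diagnostics of one CV run."""

    variants: list[VariantRecord]
    scores: np.ndarray
    fold_of_variant: np.ndarray
    assignment: FoldAssignment
    fold_models: dict[int, EnsembleModel]
    fold_metrics: dict[int, dict[str, float]]
    pooled_metrics: dict[str, float]

    def score_by_position(self) -> dict[tuple[str, int], float]:
        return {
            (v.chrom, v.pos): float(s) for v, s in zip(self.variants, self.scores)
        }


def _labels(variants: Sequence[VariantRecord]) -> np.ndarray:
    y = np.array([v.label for v in variants], dtype=object)
    if any(l is None for l in y):
        raise ValueError("all training variants must carry a 0/1 label")
    return y.astype(int)


def cross_validate(
    variants: Sequence[VariantRecord],
    features: FeatureMatrix,
    bands: CytobandMap,
    config: HyperSmurfConfig,
    n_folds: int = 10,
    assignment: FoldAssignment | None = None,
    keep_models: bool = True,
) -> CvResult:
    """Band-aware n-fold CV with one held-out score per training variant.

    Per fold: the imputer is fitted on the training portion only, the
    ensemble is trained with a fold-derived child seed, and the held-out
    fold is scored. A fold whose training portion lacks positives raises,
    naming the fold (reduce ``n_folds`` or merge bands).
    """
    if len(variants) != features.n_variants:
        raise ValueError("variants and feature matrix lengths differ")
    y = _labels(variants)
    band_of_variant = bands.bands_of(variants)
    if assignment is None:
        counts: dict[str, int] = {}
        for b, label in zip(band_of_variant, y):
            if label == 1:
                counts[b] = counts.get(b, 0) + 1
        assignment = assign_folds(
            bands,
            counts,
            n_folds=n_folds,
            rng=np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(10,))
            ),
        )
    fold_of_variant = np.array(
        [assignment.fold_of(b) for b in band_of_variant], dtype=int
    )

    scores = np.full(len(variants), np.nan)
    fold_models: dict[int, EnsembleModel] = {}
    fold_metrics: dict[int, dict[str, float]] = {}
    base_policy = policy_from_metadata(features.metadata)
    for f in range(1, assignment.n_folds + 1):
        test = fold_of_variant == f
        train = ~test
        if not test.any():
            continue
        if y[train].sum() == 0 or (y[train] == 0).sum() == 0:
            raise ValueError(
                f"fold {f}: training portion lacks a class; reduce n_folds "
                "or check the band assignment"
            )
        tr_matrix = FeatureMatrix(
            features.values[train], features.mask[train], features.metadata
        )
        te_matrix = FeatureMatrix(
            features.values[test], features.mask[test], features.metadata
        )
        imputer = fit_imputer(tr_matrix, base_policy)
        model = fit_ensemble(
            impute(tr_matrix, imputer),
            y[train],
            config.with_seed(
                np.random.SeedSequence(config.seed, spawn_key=(11, f)).generate_state(1)[0]
                % 2**31
            ),
            imputer=imputer,
        )
        fold_scores = model.predict(impute(te_matrix, imputer))
        scores[test] = fold_scores
        if keep_models:
            fold_models[f] = model
        if y[test].sum() > 0 and (y[test] == 0).sum() > 0:
            c = curve(fold_scores, y[test])
            fold_metrics[f] = {"auprc": c.auprc, "auroc": c.auroc}

    if np.isnan(scores).any():
        raise RuntimeError("some training variants received no held-out score")
    pooled = curve(scores, y)
    return CvResult(
        variants=list(variants),
        scores=scores,
        fold_of_variant=fold_of_variant,
        assignment=assignment,
        fold_models=fold_models,
        fold_metrics=fold_metrics,
        pooled_metrics={"auprc": pooled.auprc, "auroc": pooled.auroc},
    )


def cross_validate_raw_forest(
    variants: Sequence[VariantRecord],
    features: FeatureMatrix,
    bands: CytobandMap,
    config: HyperSmurfConfig,
    n_folds: int = 10,
    assignment: FoldAssignment | None = None,
) -> CvResult:
    """Baseline: one plain random forest per fold on the raw imbalanced data.

    The forest uses the ensemble's per-member hyperparameters
    (``trees_per_forest`` trees) but none of the SMOTE / partition /
    subsample machinery — the control arm for the imbalance-awareness
    comparison, evaluated on the same folds.
    """
    from sklearn.ensemble import RandomForestClassifier

    if len(variants) != features.n_variants:
        raise ValueError("variants and feature matrix lengths differ")
    y = _labels(variants)
    band_of_variant = bands.bands_of(variants)
    if assignment is None:
        counts: dict[str, int] = {}
        for b, label in zip(band_of_variant, y):
            if label == 1:
                counts[b] = counts.get(b, 0) + 1
        assignment = assign_folds(
            bands,
            counts,
            n_folds=n_folds,
            rng=np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(10,))
            ),
        )
    fold_of_variant = np.array(
        [assignment.fold_of(b) for b in band_of_variant], dtype=int
    )
    scores = np.full(len(variants), np.nan)
    base_policy = policy_from_metadata(features.metadata)
    fold_metrics: dict[int, dict[str, float]] = {}
    for f in range(1, assignment.n_folds + 1):
        test = fold_of_variant == f
        train = ~test
        if not test.any():
            continue
        tr_matrix = FeatureMatrix(
            features.values[train], features.mask[train], features.metadata
        )
        te_matrix = FeatureMatrix(
            features.values[test], features.mask[test], features.metadata
        )
        imputer = fit_imputer(tr_matrix, base_policy)
        rf = RandomForestClassifier(
            n_estimators=config.trees_per_forest,
            max_features=config.max_features,
            max_depth=config.max_depth,
            random_state=int(
                np.random.SeedSequence(config.seed, spawn_key=(12, f)).generate_state(1)[0]
                % 2**31
            ),
            n_jobs=1,
        )
        rf.fit(impute(tr_matrix, imputer).values, y[train])
        idx1 = list(rf.classes_).index(1)
        scores[test] = rf.predict_proba(impute(te_matrix, imputer).values)[:, idx1]
    if np.isnan(scores).any():
        raise RuntimeError("some training variants received no held-out score")
    pooled = curve(scores, y)
    return CvResult(
        variants=list(variants),
        scores=scores,
        fold_of_variant=fold_of_variant,
        assignment=assignment,
        fold_models={},
        fold_metrics=fold_metrics,
        pooled_metrics={"auprc": pooled.auprc, "auroc": pooled.auroc},
    )


def make_final_track(
    general_model: EnsembleModel,
    cv_result: CvResult,
    variants: Sequence[VariantRecord],
    features: FeatureMatrix,
) -> ScoreTrack:
    """Release score track with unbiased training-variant scores.

    Every position in ``variants`` is scored by the general model (trained
    on all data); positions belonging to the CV training set are then
    overwritten with their held-out CV score, so benchmarks against the
    track never see an optimistically biased value.
    """
    scores = general_model.predict(features)
    cv_by_pos = cv_result.score_by_position()
    if np.isnan(cv_result.scores).any():
        raise ValueError("CV result has training positions without a score")
    out = []
    for v, s in zip(variants, scores):
        key = (v.chrom, v.pos)
        out.append((v.chrom, v.pos, cv_by_pos.get(key, float(s))))
    return ScoreTrack.from_records(out)


def repeat_cv(
    variants: Sequence[VariantRecord],
    features: FeatureMatrix,
    bands: CytobandMap,
    config: HyperSmurfConfig,
    seeds: Sequence[int],
    n_folds: int = 10,
    pick: int | None = None,
) -> dict:
    """Repeat the CV with different master seeds and summarise AUPRC.

    Returns mean ± sd of pooled AUPRC over the runs and, when ``pick`` is
    given, retains that run's result as the representative model — the
    repeat-runs protocol behind reporting "AUPRC m ± s" and releasing one
    randomly picked model.
    """
    auprcs: list[float] = []
    results: list[CvResult] = []
    for s in seeds:
        res = cross_validate(
            variants, features, bands, config.with_seed(s), n_folds=n_folds,
            keep_models=False,
        )
        auprcs.append(res.pooled_metrics["auprc"])
        results.append(res)
    out = {
        "seeds": list(seeds),
        "auprc_per_seed": auprcs,
        "auprc_mean": float(np.mean(auprcs)),
        "auprc_sd": float(np.std(auprcs, ddof=1)) if len(auprcs) > 1 else 0.0,
    }
    if pick is not None:
        out["picked"] = results[pick]
    return out
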