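"""The imbalance-aware ensemble: SMOTE, partitioning, subsampling,
fitting, prediction, and Gini importance."""

import numpy as np
import pytest

import remmlite as r
from remmlite.ensemble import EnsembleModel


def brute_force_knn(points, k):
    """All-pairs Euclidean kNN oracle (self excluded)."""
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return np.argsort(d, axis=1, kind="stable")[:, :k]


class TestSmote:
    def test_count_is_factor_times_minority(self, rng):
        minority = rng.normal(size=(37, 4))
        synth = r.smote_oversample(minority, factor=2, k=5, rng=rng)
        assert synth.shape == (74, 4)

    def test_synthetics_lie_on_segment_to_a_true_nearest_neighbour(self, rng):
        """Every synthetic point must satisfy x + u(x_nn - x) for its base
        point x and one of x's k nearest neighbours, verified against a
        brute-force all-pairs kNN oracle."""
        minority = rng.normal(size=(60, 3))
        factor, k = 3, 5
        synth = r.smote_oversample(minority, factor=factor, k=k, rng=rng)
        neigh = brute_force_knn(minority, k)
        for s_idx in range(synth.shape[0]):
            base = s_idx // factor
            x = minority[base]
            ok = False
            for nb in neigh[base]:
                seg = minority[nb] - x
                denom = seg[np.argmax(np.abs(seg))]
                u = (synth[s_idx] - x)[np.argmax(np.abs(seg))] / denom
                if 0 <= u <= 1 and np.allclose(synth[s_idx], x + u * seg, atol=1e-9):
                    ok = True
                    break
            assert ok, f"synthetic {s_idx} is not on a segment to a kNN of its base"

    def test_synthetics_stay_in_componentwise_box(self, rng):
        minority = rng.normal(size=(40, 5))
        synth = r.smote_oversample(minority, factor=2, k=4, rng=rng)
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        assert (synth >= lo - 1e-12).all() and (synth <= hi + 1e-12).all()

    def test_identical_points_interpolate_to_themselves(self, rng):
        minority = np.ones((5, 3))
        synth = r.smote_oversample(minority, factor=2, k=2, rng=rng)
        np.testing.assert_array_equal(synth, np.ones((10, 3)))

    def test_k_too_large_instructs_to_lower_k(self, rng):
        with pytest.raises(ValueError, match="lower k"):
            r.smote_oversample(np.zeros((4, 2)), factor=1, k=4, rng=rng)


class TestPartitioning:
    def test_paper_scale_partition_sizes(self, rng):
        """13,911,061 majority indices into 100 partitions give 61 of
        size 139,111 and 39 of size 139,110."""
        parts = r.partition_majority(np.arange(13_911_061), 100, rng)
        sizes = sorted((len(p) for p in parts), reverse=True)
        assert sizes[:61] == [139_111] * 61
        assert sizes[61:] == [139_110] * 39

    def test_partitions_are_disjoint_and_cover(self, rng):
        idx = rng.choice(10_000, size=1000, replace=False)
        parts = r.partition_majority(idx, 7, rng)
        union = np.concatenate(parts)
        assert len(union) == len(idx)
        assert set(union.tolist()) == set(idx.tolist())
        assert max(len(p) for p in parts) - min(len(p) for p in parts) <= 1

    def test_single_partition_is_whole_input(self, rng):
        idx = np.arange(17)
        (part,) = r.partition_majority(idx, 1, rng)
        assert set(part.tolist()) == set(idx.tolist())

    def test_too_many_partitions_rejected(self, rng):
        with pytest.raises(ValueError):
            r.partition_majority(np.arange(5), 6, rng)


class TestSubsampling:
    def test_ratio_times_minority_without_replacement(self, rng):
        partition = np.arange(5000)
        sample = r.subsample_partition(partition, ratio=3, minority_size=406, rng=rng)
        assert len(sample) == 1218
        assert len(set(sample.tolist())) == 1218
        assert set(sample.tolist()) <= set(partition.tolist())

    def test_exact_fit_returns_whole_partition(self, rng):
        partition = np.arange(12)
        sample = r.subsample_partition(partition, ratio=3, minority_size=4, rng=rng)
        assert sorted(sample.tolist()) == list(range(12))

    def test_oversized_target_degrades_with_warning(self, rng):
        with pytest.warns(UserWarning, match="whole partition"):
            sample = r.subsample_partition(np.arange(10), 3, 6, rng)
        assert sorted(sample.tolist()) == list(range(10))


def separable_data(rng, n_pos=30, n_neg=600):
    X = np.vstack([rng.normal(5.0, 0.3, size=(n_pos, 4)), rng.normal(0.0, 0.3, size=(n_neg, 4))])
    y = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    return X, y


class TestFitPredict:
    def test_member_count_equals_n_partitions(self, rng):
        X, y = separable_data(rng)
        model = r.fit_ensemble(X, y, r.HyperSmurfConfig(n_partitions=6, seed=1))
        assert len(model.forests) == 6
        assert len(model.partition_info) == 6

    def test_partition_training_sets_disjoint_majority_shared_minority_size(self, rng):
        X, y = separable_data(rng)
        cfg = r.HyperSmurfConfig(n_partitions=5, oversample_factor=2, ratio=3, seed=2)
        model = r.fit_ensemble(X, y, cfg)
        maj_sets = [set(info["majority_indices"].tolist()) for info in model.partition_info]
        for i in range(len(maj_sets)):
            for j in range(i + 1, len(maj_sets)):
                assert not (maj_sets[i] & maj_sets[j])
        for info in model.partition_info:
            assert info["n_minority"] == 30
            assert info["n_synthetic"] == 60   # factor x minority
            assert info["n_majority"] == 90    # ratio x minority

    def test_same_seed_reproduces_scores_exactly(self, rng):
        X, y = separable_data(rng)
        probe = rng.normal(2.0, 2.0, size=(50, 4))
        cfg = r.HyperSmurfConfig(n_partitions=4, seed=9)
        s1 = r.fit_ensemble(X, y, cfg).predict(probe)
        s2 = r.fit_ensemble(X, y, cfg).predict(probe)
        np.testing.assert_array_equal(s1, s2)

    def test_separable_classes_reach_training_auprc(self, rng):
        X, y = separable_data(rng)
        model = r.fit_ensemble(X, y, r.HyperSmurfConfig(n_partitions=5, seed=3))
        c = r.curve(model.predict(X), y)
        assert c.auprc >= 0.99

    def test_single_class_and_nan_inputs_rejected(self, rng):
        X, y = separable_data(rng)
        with pytest.raises(ValueError, match="both classes"):
            r.fit_ensemble(X, np.zeros_like(y), r.HyperSmurfConfig(n_partitions=2))
        X_nan = X.copy()
        X_nan[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            r.fit_ensemble(X_nan, y, r.HyperSmurfConfig(n_partitions=2))

    def test_score_is_exact_mean_of_member_probabilities(self):
        class StubForest:
            classes_ = np.array([0, 1])

            def __init__(self, p):
                self.p = p

            def predict_proba(self, X):
                return np.column_stack([np.full(len(X), 1 - self.p), np.full(len(X), self.p)])

        model = EnsembleModel(
            forests=[StubForest(0.2)] * 50 + [StubForest(0.6)] * 50,
            config=r.HyperSmurfConfig(n_partitions=100),
            feature_names=["a", "b"],
        )
        scores = model.predict(np.zeros((3, 2)))
        np.testing.assert_allclose(scores, 0.4)
        model_ones = EnsembleModel(
            forests=[StubForest(1.0)] * 4,
            config=r.HyperSmurfConfig(n_partitions=4),
            feature_names=["a", "b"],
        )
        np.testing.assert_allclose(model_ones.predict(np.zeros((2, 2))), 1.0)

    def test_scores_bounded_in_unit_interval(self, rng):
        X, y = separable_data(rng)
        model = r.fit_ensemble(X, y, r.HyperSmurfConfig(n_partitions=3, seed=5))
        s = model.predict(rng.normal(size=(200, 4)))
        assert (s >= 0).all() and (s <= 1).all()

    def test_feature_name_mismatch_rejected(self, small_model, small_sim):
        wrong_meta = [
            r.FeatureMeta(m.name + "_x", m.category, m.imputation)
            for m in small_sim.features.metadata
        ]
        wrong = r.FeatureMatrix(
            small_sim.features.values[:5], small_sim.features.mask[:5], wrong_meta
        )
        with pytest.raises(ValueError, match="feature names"):
            small_model.predict(wrong)

    def test_model_save_load_round_trip(self, tmp_path, small_model, small_sim):
        path = tmp_path / "model.joblib"
        small_model.save(path)
        loaded = EnsembleModel.load(path)
        imputed = r.impute(small_sim.features, small_model.imputer)
        np.testing.assert_array_equal(loaded.predict(imputed), small_model.predict(imputed))


class TestGiniImportance:
    def test_vector_length_rank_and_nonnegativity(self, small_model):
        imp = r.gini_importance(small_model)
        assert len(imp) == 26
        assert (imp["importance"] >= 0).all() and np.isfinite(imp["importance"]).all()
        assert sorted(imp["rank"]) == list(range(1, 27))
        top = imp["importance"].idxmax()
        assert imp.loc[top, "rank"] == 1

    def test_planted_signal_feature_ranks_first(self):
        sim = r.simulate(
            r.SimConfig(
                n_pos=50, imbalance=60, n_bands=12, band_length=2000,
                effect_size={"cons_mammal": 2.5}, band_sd=0.3, seed=21,
            )
        )
        y = np.array([v.label for v in sim.variants])
        imputer = r.fit_imputer(sim.features, r.policy_from_metadata(sim.features.metadata))
        model = r.fit_ensemble(
            r.impute(sim.features, imputer), y, r.HyperSmurfConfig(n_partitions=8, seed=4)
        )
        report = r.planted_signal_check(sim, model)
        assert report["planted_feature"] == "cons_mammal"
        assert report["recovered"] and report["rank"] == 1
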