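from collections import Counter

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

from ddgcv import (
    GeneratorConfig,
    assign_kfold,
    assign_lopo,
    cross_validate,
    evaluate_subsets,
    generate_dataset,
    make_balanced,
    make_combined,
    make_unbalanced,
    pearson_r,
)
from ddgcv.evaluation import EvalTag, FoldScheme


class TestAssignKfold:
    def test_fold_sizes_within_one(self):
        folds = assign_kfold(2048, k=10, seed=0)
        sizes = Counter(folds.fold_of)
        assert sorted(sizes.values()) == [204, 204] + [205] * 8

    def test_singleton_folds_when_n_equals_k(self):
        folds = assign_kfold(7, k=7, seed=0)
        assert sorted(Counter(folds.fold_of).values()) == [1] * 7

    def test_seed_reproducibility_and_sensitivity(self):
        a = assign_kfold(2048, k=10, seed=1)
        b = assign_kfold(2048, k=10, seed=1)
        c = assign_kfold(2048, k=10, seed=2)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)
        assert (a.fold_of != c.fold_of).any()

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            assign_kfold(5, k=6, seed=0)
        with pytest.raises(ValueError):
            assign_kfold(5, k=1, seed=0)


class TestAssignLopo:
    def test_one_fold_per_protein(self, small_synthetic):
        ds, _ = small_synthetic
        folds = assign_lopo(ds)
        assert folds.k == len(ds.protein_ids)
        for rec, fold in zip(ds.records, folds.fold_of):
            assert fold == rec.protein_id

    def test_no_protein_straddles_a_split(self, small_synthetic):
        ds, _ = small_synthetic
        folds = assign_lopo(ds)
        pids = np.array([r.protein_id for r in ds.records])
        for fold in folds.labels:
            test_prots = set(pids[folds.fold_of == fold])
            train_prots = set(pids[folds.fold_of != fold])
            assert not (test_prots & train_prots)

    def test_single_protein_rejected(self, toy_dataset):
        toy_dataset.records = [r for r in toy_dataset.records
                               if r.protein_id == "TOY1"]
        with pytest.raises(ValueError, match="at least 2 proteins"):
            assign_lopo(toy_dataset)


def _linear_dataset(seed=0, n_proteins=10, m=12):
    """Synthetic data whose ΔΔG is an exact linear function of the features."""
    cfg = GeneratorConfig(
        n_proteins=n_proteins, mutations_per_protein=m,
        sequence_length=(40, 80), site_effect_sd=0.0, protein_effect_sd=0.0,
        noise_sd=0.0, skew_shift=0.0, seed=seed,
    )
    return generate_dataset(cfg)


class TestCrossValidate:
    def test_every_record_heldout_exactly_once(self, small_synthetic):
        ds, _ = small_synthetic
        var = make_unbalanced(ds)
        ps = cross_validate(var, assign_kfold(len(ds), 4, seed=0),
                            regressor=LinearRegression())
        held = ps.subset(EvalTag.HELDOUT)
        assert sorted(held["record_index"]) == list(range(len(ds)))

    def test_noiseless_linear_data_recovered_under_both_schemes(self):
        ds, _ = _linear_dataset()
        var = make_unbalanced(ds)
        for folds in (assign_kfold(len(ds), 10, seed=0), assign_lopo(var)):
            ps = cross_validate(var, folds, regressor=LinearRegression())
            held = ps.subset(EvalTag.HELDOUT)
            assert pearson_r(held["predicted"], held["observed"]) > 0.99

    def test_counterpart_predictions_pair_with_heldout(self, small_synthetic):
        ds, _ = small_synthetic
        var = make_unbalanced(ds)
        ps = cross_validate(var, assign_kfold(len(ds), 4, seed=0),
                            regressor=LinearRegression(), counterparts=True)
        held = ps.subset(EvalTag.HELDOUT)
        counter = ps.subset(EvalTag.COUNTERPART)
        assert len(counter) == len(held) == len(ds)
        merged = held.merge(counter, on="record_index",
                            suffixes=("_f", "_r"))
        # counterpart observed values are the exact negations (antisymmetry)
        np.testing.assert_allclose(merged["observed_f"], -merged["observed_r"])
        # counterpart predicted in the same fold as its forward record
        assert (merged["fold_f"] == merged["fold_r"]).all()

    def test_counterparts_refused_for_mixed_direction_data(self, small_synthetic):
        ds, _ = small_synthetic
        var = make_balanced(ds, seed=0)
        with pytest.raises(ValueError, match="all-forward"):
            cross_validate(var, assign_kfold(len(ds), 4, seed=0),
                           regressor=LinearRegression(), counterparts=True)

    def test_scaling_uses_training_fold_statistics_only(self, small_synthetic):
        """An extreme outlier in the test fold must not move the training
        transform: the training matrix the model sees stays standardized to
        the training rows alone."""
        ds, _ = small_synthetic
        var = make_unbalanced(ds)

        class SpyRegressor:
            # class-level store: survives the harness's per-fold cloning
            seen: list = []

            def get_params(self, deep=True):
                return {}

            def set_params(self, **kw):
                return self

            def fit(self, X, y):
                SpyRegressor.seen.append(X.copy())
                return self

            def predict(self, X):
                return np.zeros(len(X))

        from ddgcv.features import encode_dataset

        enc = encode_dataset(ds)
        folds = assign_kfold(len(ds), 4, seed=0)
        SpyRegressor.seen = []
        cross_validate(var, folds, regressor=SpyRegressor(), encoded=enc)
        baseline = [X.copy() for X in SpyRegressor.seen]

        # corrupt one held-out row of fold 0 with an absurd outlier
        enc_bad = encode_dataset(ds)
        test_idx = np.where(folds.fold_of == folds.labels[0])[0][0]
        enc_bad.X[test_idx] = 1e6
        SpyRegressor.seen = []
        cross_validate(var, folds, regressor=SpyRegressor(), encoded=enc_bad)
        # fold 0 trains without the corrupted row: identical training matrix
        np.testing.assert_array_equal(baseline[0], SpyRegressor.seen[0])

    def test_empty_training_fold_rejected(self, small_synthetic):
        ds, _ = small_synthetic
        var = make_unbalanced(ds)
        folds = assign_kfold(len(ds), 4, seed=0)
        one_fold = type(folds)(FoldScheme.KFOLD,
                               np.zeros(len(ds), dtype=object), k=1)
        with pytest.raises(ValueError, match="empty training set"):
            cross_validate(var, one_fold, regressor=LinearRegression())


class TestEvaluateSubsets:
    def test_unbalanced_forward_and_reverse_rows(self, small_synthetic):
        ds, _ = small_synthetic
        var = make_unbalanced(ds)
        ps = cross_validate(var, assign_kfold(len(ds), 4, seed=0),
                            regressor=LinearRegression(), counterparts=True)
        reports = {r.subset: r for r in evaluate_subsets(ps)}
        assert set(reports) == {"forward", "reverse"}
        assert reports["forward"].n == reports["reverse"].n == len(ds)

    def test_balanced_rows_split_by_direction(self, small_synthetic):
        ds, _ = small_synthetic
        var = make_balanced(ds, seed=1)
        ps = cross_validate(var, assign_kfold(len(ds), 4, seed=0),
                            regressor=LinearRegression())
        reports = {r.subset: r for r in evaluate_subsets(ps)}
        assert reports["forward"].n + reports["reverse"].n == len(ds)
        assert abs(reports["forward"].n - reports["reverse"].n) <= 1

    def test_combined_is_single_pooled_row(self, small_synthetic):
        ds, _ = small_synthetic
        var = make_combined(ds)
        ps = cross_validate(var, assign_kfold(len(var.dataset), 4, seed=0),
                            regressor=LinearRegression())
        reports = evaluate_subsets(ps)
        assert len(reports) == 1
        assert reports[0].subset == "all"
        assert reports[0].n == 2 * len(ds)
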