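import hashlib

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyClassifier, DummyRegressor

from crossclock.datasets import ValidationError
from crossclock.evaluate import (
    EvalConfig,
    compare_feature_sets,
    evaluate_classification,
    evaluate_regression,
    resample_split,
)
from crossclock.normalize import library_factors

from _oracles import regression_loop_bruteforce
from conftest import make_dataset


class _LookupRegressor:
    """Oracle: memorises the true target for every row ever seen."""

    def __init__(self, X_all, y_all):
        self.table = {X_all[i].tobytes(): y_all[i] for i in range(len(y_all))}

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.table[row.tobytes()] for row in np.asarray(X)])


class _LookupClassifier(_LookupRegressor):
    pass


def age_dataset(n=24, seed=0, unit="years"):
    rng = np.random.default_rng(seed)
    if unit == "years":
        ages = np.concatenate([rng.uniform(20, 28, n // 3), rng.uniform(35, 55, n // 3),
                               rng.uniform(65, 85, n - 2 * (n // 3))])
    else:
        ages = rng.integers(3, 50, n).astype(float)
    counts = rng.poisson(np.exp2(rng.uniform(3, 8, size=(40, 1))) * np.ones((1, n)))
    counts[0] = (ages * 10).astype(int)  # one informative gene
    return make_dataset(counts, ages, unit=unit)


class TestResampleSplit:
    def test_partition_sizes_and_disjointness(self):
        rng = np.random.default_rng(0)
        train, test = resample_split(8, 0.75, rng)
        assert len(train) == 6 and len(test) == 2
        assert set(train) | set(test) == set(range(8))
        assert set(train) & set(test) == set()

    def test_deterministic_given_rng_state(self):
        a = resample_split(20, 0.75, np.random.default_rng(1))
        b = resample_split(20, 0.75, np.random.default_rng(1))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        c = resample_split(20, 0.75, np.random.default_rng(2))
        assert not np.array_equal(a[0], c[0])

    def test_test_frequency_law_of_large_numbers(self):
        rng = np.random.default_rng(3)
        n, iters = 20, 1000
        in_test = np.zeros(n)
        for _ in range(iters):
            _, test = resample_split(n, 0.75, rng)
            in_test[test] += 1
        freq = in_test / iters
        se = np.sqrt(0.25 * 0.75 / iters)
        assert np.all(np.abs(freq - 0.25) < 5 * se)

    def test_stratified_keeps_every_class_in_train(self):
        rng = np.random.default_rng(4)
        strata = np.array([0] * 10 + [1] * 3 + [2] * 2)
        for _ in range(50):
            train, _ = resample_split(15, 0.75, rng, strata=strata)
            assert set(strata[train]) == {0, 1, 2}

    def test_stratified_impossible_errors_after_attempts(self):
        rng = np.random.default_rng(5)
        # train size 1 cannot contain both classes
        with pytest.raises(RuntimeError, match="100 attempts"):
            resample_split(4, 0.25, rng, strata=np.array([0, 0, 1, 1]))

    def test_bootstrap_mode_out_of_bag(self):
        rng = np.random.default_rng(6)
        train, test = resample_split(20, 0.75, rng, bootstrap=True)
        assert len(train) == 15
        assert set(train) & set(test) == set()
        assert set(test) == set(range(20)) - set(train)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            resample_split(3, 0.75, np.random.default_rng(0))


class TestRegressionHarness:
    def test_oracle_model_r2_one_every_iteration(self):
        ds = age_dataset()
        fac = library_factors(ds)
        from crossclock.evaluate import _feature_matrix

        X = _feature_matrix(ds, fac, ds.gene_ids, 0.5)
        cfg = EvalConfig(n_iterations=20, seed=0, model=_LookupRegressor(X, ds.ages))
        rep = evaluate_regression(ds, fac, ds.gene_ids, cfg)
        assert (rep.per_iteration["r2"] == 1.0).all()
        assert (rep.per_iteration["median_ae"] == 0.0).all()

    def test_train_mean_model_r2_nonpositive(self):
        # predicting the train mean can never beat the test mean
        ds = age_dataset(seed=1)
        fac = library_factors(ds)
        cfg = EvalConfig(n_iterations=30, seed=1, model=DummyRegressor(strategy="mean"))
        rep = evaluate_regression(ds, fac, ds.gene_ids, cfg)
        assert (rep.per_iteration["r2"] <= 1e-12).all()
        assert rep.summary["mean_r2"] <= 0

    def test_summary_is_exact_mean_and_percentile_ci(self):
        ds = age_dataset(seed=2)
        fac = library_factors(ds)
        cfg = EvalConfig(n_iterations=40, seed=2, model="linear")
        rep = evaluate_regression(ds, fac, ds.gene_ids, cfg)
        r2 = rep.per_iteration["r2"].to_numpy()
        assert rep.summary["mean_r2"] == np.mean(r2)
        assert rep.summary["mean_mse"] == np.mean(rep.per_iteration["mse"])
        assert rep.summary["r2_ci_low"] == np.percentile(r2, 2.5)
        assert rep.summary["r2_ci_high"] == np.percentile(r2, 97.5)
        assert rep.summary["r2_ci_low"] >= r2.min()
        assert rep.summary["r2_ci_high"] <= r2.max()

    def test_ci_narrows_with_more_iterations(self):
        ds = age_dataset(seed=3)
        fac = library_factors(ds)
        widths = []
        for iters in (30, 120):
            cfg = EvalConfig(n_iterations=iters, seed=3, model="linear")
            rep = evaluate_regression(ds, fac, ds.gene_ids, cfg)
            widths.append(rep.summary["r2_ci_high"] - rep.summary["r2_ci_low"])
        # percentile CI of a fixed distribution does not blow up; allow
        # mild sampling noise but no large widening
        assert widths[1] <= widths[0] * 1.25

    def test_unknown_feature_id_rejected(self):
        ds = age_dataset()
        with pytest.raises(ValidationError, match="nope"):
            evaluate_regression(ds, library_factors(ds), ["nope"], EvalConfig(n_iterations=2))

    def test_matches_independent_loop_oracle(self):
        # same seed derivation, independently coded split/metric loop
        ds = age_dataset(n=32, seed=4)
        fac = library_factors(ds)
        from crossclock.evaluate import _feature_matrix
        from crossclock.models import make_model

        feature_set = ds.gene_ids[:20]
        X = _feature_matrix(ds, fac, feature_set, 0.5)
        cfg = EvalConfig(n_iterations=100, seed=7, model="xgboost")
        rep = evaluate_regression(ds, fac, feature_set, cfg)
        expected = regression_loop_bruteforce(
            X, ds.ages, seed=7, n_iterations=100, train_fraction=0.75,
            make_model=lambda s: make_model("xgboost", "regression", s),
        )
        assert abs(rep.summary["mean_r2"] - expected.mean()) <= 0.05
        np.testing.assert_allclose(rep.per_iteration["r2"].to_numpy(), expected, atol=1e-9)

    def test_full_determinism(self):
        ds = age_dataset(seed=5)
        fac = library_factors(ds)
        cfg = EvalConfig(n_iterations=10, seed=9, model="xgboost")
        r1 = evaluate_regression(ds, fac, ds.gene_ids, cfg)
        r2 = evaluate_regression(ds, fac, ds.gene_ids, cfg)
        pd.testing.assert_frame_equal(r1.per_iteration, r2.per_iteration)
        assert r1.split_hashes == r2.split_hashes


class TestClassificationHarness:
    def test_oracle_classifier_perfect_and_diagonal(self):
        ds = age_dataset(seed=6)
        fac = library_factors(ds)
        from crossclock.evaluate import _age_codes, _feature_matrix

        X = _feature_matrix(ds, fac, ds.gene_ids, 0.5)
        cfg = EvalConfig(
            n_iterations=15, seed=0, task="classification",
            model=_LookupClassifier(X, _age_codes(ds)),
        )
        rep = evaluate_classification(ds, fac, ds.gene_ids, cfg)
        assert (rep.per_iteration["accuracy"] == 1.0).all()
        off_diag = rep.mean_confusion.to_numpy().sum() - np.trace(rep.mean_confusion.to_numpy())
        assert off_diag == 0.0

    def test_confusion_totals_equal_test_sizes(self):
        ds = age_dataset(seed=7)
        fac = library_factors(ds)
        cfg = EvalConfig(n_iterations=25, seed=1, task="classification", model="naive_bayes")
        rep = evaluate_classification(ds, fac, ds.gene_ids, cfg)
        assert rep.mean_confusion.to_numpy().sum() == pytest.approx(
            rep.per_iteration["test_size"].mean()
        )

    def test_single_class_classifier_is_chance_on_balanced_classes(self):
        # a classifier that always answers one class scores at chance on
        # balanced classes; note the train-majority class is slightly
        # *under*-represented in the complementary test split, so a
        # train-majority dummy scores below chance in a partition design
        ds = age_dataset(n=30, seed=8)  # 10 per age group by construction
        fac = library_factors(ds)
        cfg = EvalConfig(
            n_iterations=60, seed=2, task="classification",
            model=DummyClassifier(strategy="constant", constant=0),
        )
        rep = evaluate_classification(ds, fac, ds.gene_ids, cfg)
        assert rep.summary["mean_accuracy"] == pytest.approx(1 / 3, abs=0.1)
        cfg_maj = EvalConfig(
            n_iterations=60, seed=2, task="classification",
            model=DummyClassifier(strategy="most_frequent"),
        )
        rep_maj = evaluate_classification(ds, fac, ds.gene_ids, cfg_maj)
        assert rep_maj.summary["mean_accuracy"] <= 1 / 3 + 0.05

    def test_per_sample_misclassification_bookkeeping(self):
        ds = age_dataset(seed=9)
        fac = library_factors(ds)
        cfg = EvalConfig(n_iterations=30, seed=3, task="classification", model="naive_bayes")
        rep = evaluate_classification(ds, fac, ds.gene_ids, cfg)
        n_used = cfg.n_iterations - rep.n_skipped
        mean_off_diag = (
            rep.mean_confusion.to_numpy().sum()
            - np.trace(rep.mean_confusion.to_numpy())
        )
        assert rep.per_sample["n_misclassified"].sum() / n_used == pytest.approx(mean_off_diag)
        assert rep.per_sample["n_test"].sum() == rep.per_iteration["test_size"].sum()


class TestCompareFeatureSets:
    def test_identical_sets_identical_rows(self):
        ds = age_dataset(seed=10)
        fac = library_factors(ds)
        cfg = EvalConfig(n_iterations=10, seed=4, model="linear")
        out = compare_feature_sets(
            ds, fac, {"one": ds.gene_ids, "two": list(ds.gene_ids)}, cfg
        )
        a = out[out.feature_set == "one"].drop(columns="feature_set").reset_index(drop=True)
        b = out[out.feature_set == "two"].drop(columns="feature_set").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_rows_share_split_sequence(self):
        ds = age_dataset(seed=11)
        fac = library_factors(ds)
        cfg = EvalConfig(n_iterations=8, seed=5, model="linear")
        out = compare_feature_sets(
            ds, fac, {"all": ds.gene_ids, "one_gene": ds.gene_ids[:1]}, cfg
        )
        reports = out.attrs["reports"]
        assert reports["all"].split_hashes == reports["one_gene"].split_hashes
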