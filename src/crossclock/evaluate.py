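"""Resampled evaluation of age regression and age-group classification.

The protocol: for each of ``n_iterations`` (default 1000) draw an
independent random disjoint split of the samples into 75% training and
25% test, fit the model on the training log2-CPM features, score on the
held-out samples, and report the mean of each metric over iterations plus
a percentile 95% confidence interval for R².  Splits are partitions, not
bootstrap draws, so no sample leaks from train to test; a bootstrap mode
(sample-with-replacement training sets, out-of-bag test) is available
behind a flag.

Classification splits guarantee every age group is represented in the
training set (resampled internally up to 100 times), which matters under
the class imbalance typical of pooled public data.

``compare_feature_sets`` evaluates several gene lists against the *same*
sequence of splits and per-iteration model seeds, so rows are paired and
differences between feature sets are not confounded by split luck.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    mean_absolute_error,
    mean_squared_error,
    median_absolute_error,
    precision_recall_fscore_support,
    r2_score,
)

from .datasets import AGE_GROUP_LABELS, ConfigError, CountDataset, ValidationError
from .models import DEFAULT_MODEL, make_model
from .normalize import NormFactors, log_cpm

__all__ = [
    "ClassificationReport",
    "EvalConfig",
    "RegressionReport",
    "compare_feature_sets",
    "evaluate_classification",
    "evaluate_regression",
    "resample_split",
]

_CLASS_CODES = np.arange(len(AGE_GROUP_LABELS))


@dataclass
class EvalConfig:
    """Knobs of the resampled-evaluation protocol."""

    n_iterations: int = 1000
    train_fraction: float = 0.75
    seed: int = 0
    task: str = "regression"
    model: object = DEFAULT_MODEL  # registry name, factory(seed) or estimator
    model_params: dict = field(default_factory=dict)
    stratify: bool = True  # classification only
    bootstrap: bool = False
    pseudocount: float = 0.5

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must lie strictly between 0 and 1")
        if self.task not in ("regression", "classification"):
            raise ConfigError(f"task must be 'regression' or 'classification', got {self.task!r}")


def resample_split(
    n_samples: int,
    train_fraction: float,
    rng: np.random.Generator,
    *,
    strata=None,
    bootstrap: bool = False,
    max_attempts: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """One random train/test division of ``n_samples`` samples.

    Default mode returns a disjoint exhaustive partition with
    ``|train| = round(train_fraction * n)``.  With ``strata`` (per-sample
    labels) the draw is repeated until every label present in the data
    appears in the training set, erroring after ``max_attempts``.  With
    ``bootstrap`` the training set is drawn with replacement and the test
    set is the out-of-bag complement.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples to split")
    n_train = int(np.floor(train_fraction * n_samples + 0.5))
    n_train = min(max(n_train, 1), n_samples - 1)
    if bootstrap:
        train = np.sort(rng.choice(n_samples, size=n_train, replace=True))
        test = np.setdiff1d(np.arange(n_samples), np.unique(train))
        return train, test
    if strata is None:
        perm = rng.permutation(n_samples)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    strata = np.asarray(strata)
    needed = set(np.unique(strata).tolist())
    for _ in range(max_attempts):
        perm = rng.permutation(n_samples)
        train = perm[:n_train]
        if set(strata[train].tolist()) == needed:
            return np.sort(train), np.sort(perm[n_train:])
    raise RuntimeError(
        f"could not place every age group in the training set after {max_attempts} attempts"
    )


@dataclass
class RegressionReport:
    per_iteration: pd.DataFrame  # columns: r2, mse, mean_ae, median_ae
    summary: dict
    n_skipped: int
    split_hashes: list[str]

    def summary_row(self) -> dict:
        return dict(self.summary)


@dataclass
class ClassificationReport:
    per_iteration: pd.DataFrame  # columns: accuracy, f1, precision, recall, test_size
    mean_confusion: pd.DataFrame  # 3x3, rows = true group
    summary: dict
    per_sample: pd.DataFrame  # sample_id, n_test, n_misclassified
    n_skipped: int
    split_hashes: list[str]

    def summary_row(self) -> dict:
        return dict(self.summary)


# ---------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------


def _feature_matrix(
    ds: CountDataset, factors: NormFactors, feature_set, pseudocount: float
) -> np.ndarray:
    nm = log_cpm(ds, factors, pseudocount=pseudocount)
    features = [str(g) for g in feature_set]
    missing = [g for g in features if g not in nm.values.index]
    if missing:
        raise ValidationError(f"unknown feature id {missing[0]!r}")
    if len(set(features)) != len(features):
        raise ValidationError("feature set contains duplicate gene ids")
    return nm.values.loc[features].to_numpy().T  # samples x genes


def _split_hash(train: np.ndarray, test: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(train, dtype=np.int64).tobytes())
    h.update(b"|")
    h.update(np.asarray(test, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


def _draw_plan(cfg: EvalConfig, n: int, strata=None):
    """The shared split/seed sequence: one (split, model seed) per iteration.

    Drawn interleaved from a single generator seeded with ``cfg.seed`` so
    an identical configuration reproduces the identical plan.
    """
    rng = np.random.default_rng(cfg.seed)
    splits, seeds = [], []
    for _ in range(cfg.n_iterations):
        splits.append(
            resample_split(
                n, cfg.train_fraction, rng, strata=strata, bootstrap=cfg.bootstrap
            )
        )
        seeds.append(int(rng.integers(2**31)))
    return splits, seeds


def _instantiate(cfg: EvalConfig, seed: int):
    model = cfg.model
    if isinstance(model, str):
        return make_model(model, cfg.task, seed, **cfg.model_params)
    if callable(model) and not hasattr(model, "fit"):
        return model(seed)
    return copy.deepcopy(model)


def _run_regression(X, y, cfg, splits, seeds) -> RegressionReport:
    rows, hashes = [], []
    n_skipped = 0
    for (train, test), m_seed in zip(splits, seeds):
        y_test = y[test]
        if test.size < 2 or np.all(y_test == y_test[0]):
            n_skipped += 1
            continue
        model = _instantiate(cfg, m_seed)
        model.fit(X[train], y[train])
        pred = np.asarray(model.predict(X[test]), dtype=float)
        rows.append(
            {
                "r2": r2_score(y_test, pred),
                "mse": mean_squared_error(y_test, pred),
                "mean_ae": mean_absolute_error(y_test, pred),
                "median_ae": median_absolute_error(y_test, pred),
            }
        )
        hashes.append(_split_hash(train, test))
    per_iter = pd.DataFrame(rows, columns=["r2", "mse", "mean_ae", "median_ae"])
    if not len(per_iter):
        raise RuntimeError("every iteration was skipped; no metrics to report")
    r2 = per_iter["r2"].to_numpy()
    summary = {
        "mean_r2": float(np.mean(r2)),
        "mean_mse": float(np.mean(per_iter["mse"])),
        "mean_mae": float(np.mean(per_iter["mean_ae"])),
        "mean_median_ae": float(np.mean(per_iter["median_ae"])),
        "r2_ci_low": float(np.percentile(r2, 2.5)),
        "r2_ci_high": float(np.percentile(r2, 97.5)),
    }
    return RegressionReport(per_iter, summary, n_skipped, hashes)


def _run_classification(X, y_codes, sample_ids, cfg, splits, seeds) -> ClassificationReport:
    rows, hashes = [], []
    conf_sum = np.zeros((3, 3))
    n_test_by_sample = np.zeros(len(sample_ids), dtype=np.int64)
    n_miss_by_sample = np.zeros(len(sample_ids), dtype=np.int64)
    n_skipped = 0
    n_used = 0
    for (train, test), m_seed in zip(splits, seeds):
        if test.size < 1:
            n_skipped += 1
            continue
        model = _instantiate(cfg, m_seed)
        model.fit(X[train], y_codes[train])
        pred = np.asarray(model.predict(X[test]))
        y_test = y_codes[test]
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_test, pred, labels=_CLASS_CODES, average="macro", zero_division=0
        )
        cm = confusion_matrix(y_test, pred, labels=_CLASS_CODES)
        conf_sum += cm
        n_used += 1
        n_test_by_sample[test] += 1
        n_miss_by_sample[test[pred != y_test]] += 1
        rows.append(
            {
                "accuracy": accuracy_score(y_test, pred),
                "f1": f1,
                "precision": prec,
                "recall": rec,
                "test_size": int(test.size),
            }
        )
        hashes.append(_split_hash(train, test))
    per_iter = pd.DataFrame(
        rows, columns=["accuracy", "f1", "precision", "recall", "test_size"]
    )
    if not n_used:
        raise RuntimeError("every iteration was skipped; no metrics to report")
    mean_conf = pd.DataFrame(
        conf_sum / n_used, index=AGE_GROUP_LABELS, columns=AGE_GROUP_LABELS
    )
    summary = {
        "mean_accuracy": float(np.mean(per_iter["accuracy"])),
        "mean_f1": float(np.mean(per_iter["f1"])),
        "mean_precision": float(np.mean(per_iter["precision"])),
        "mean_recall": float(np.mean(per_iter["recall"])),
    }
    per_sample = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "n_test": n_test_by_sample,
            "n_misclassified": n_miss_by_sample,
        }
    )
    return ClassificationReport(per_iter, mean_conf, summary, per_sample, n_skipped, hashes)


# ---------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------


def evaluate_regression(
    ds: CountDataset, factors: NormFactors, feature_set, cfg: EvalConfig
) -> RegressionReport:
    """Resampled chronological-age regression for one gene list."""
    cfg.validate()
    X = _feature_matrix(ds, factors, feature_set, cfg.pseudocount)
    y = ds.ages
    if np.unique(y).size < 2:
        raise ValidationError("regression needs at least 2 distinct ages")
    splits, seeds = _draw_plan(cfg, ds.n_samples)
    return _run_regression(X, y, cfg, splits, seeds)


def _age_codes(ds: CountDataset) -> np.ndarray:
    groups = ds.age_groups()
    return np.asarray([AGE_GROUP_LABELS.index(g) for g in groups])


def evaluate_classification(
    ds: CountDataset, factors: NormFactors, feature_set, cfg: EvalConfig
) -> ClassificationReport:
    """Resampled Young/Middle/Old classification for one gene list."""
    cfg.validate()
    X = _feature_matrix(ds, factors, feature_set, cfg.pseudocount)
    y_codes = _age_codes(ds)
    strata = y_codes if cfg.stratify else None
    splits, seeds = _draw_plan(cfg, ds.n_samples, strata=strata)
    return _run_classification(X, y_codes, ds.sample_ids, cfg, splits, seeds)


def compare_feature_sets(
    ds: CountDataset, factors: NormFactors, sets: dict, cfg: EvalConfig
) -> pd.DataFrame:
    """Evaluate several named gene lists against identical splits.

    Returns one row per feature set with the summary metrics for
    ``cfg.task``; the split sequence and per-iteration model seeds are
    shared, so rows are paired.  The split hashes are attached as
    ``result.attrs["split_hashes"]``.
    """
    cfg.validate()
    if not sets:
        raise ConfigError("compare_feature_sets needs at least one feature set")
    if cfg.task == "classification":
        y_codes = _age_codes(ds)
        strata = y_codes if cfg.stratify else None
        splits, seeds = _draw_plan(cfg, ds.n_samples, strata=strata)
    else:
        y = ds.ages
        splits, seeds = _draw_plan(cfg, ds.n_samples)
    rows = []
    reports = {}
    hashes = None
    for name, feature_set in sets.items():
        X = _feature_matrix(ds, factors, feature_set, cfg.pseudocount)
        if cfg.task == "classification":
            rep = _run_classification(X, y_codes, ds.sample_ids, cfg, splits, seeds)
        else:
            rep = _run_regression(X, y, cfg, splits, seeds)
        reports[name] = rep
        hashes = rep.split_hashes
        rows.append({"feature_set": name, "n_genes": len(list(feature_set)), **rep.summary})
    out = pd.DataFrame(rows)
    out.attrs["split_hashes"] = hashes
    out.attrs["reports"] = reports
    return out
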