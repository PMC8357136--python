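"""Within-species age-correlation ranking and top-k gene lists.

Each gene's normalized log expression is correlated with chronological age
across samples (Pearson by default; Spearman optional), genes are ranked by
the absolute coefficient (signed optional) and the strongest ``k`` (the
top-1000 convention) feed the cross-species intersection.  Ranking by |r|
lets genes whose expression falls with age enter the list alongside those
that rise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import ConfigError
from .normalize import NormalizedMatrix

__all__ = ["AgeCorrelationSelector", "correlate_with_age", "top_k"]

_KEYS = ("absolute", "signed")
_METHODS = ("pearson", "spearman")


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of X (features x samples) against y.

    Zero-variance rows get r = 0 by convention (a flat gene carries no
    age information).
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc**2))
    if sy == 0:
        raise ValueError("age has zero variance; correlation undefined")
    sx = np.sqrt(np.sum(Xc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[sx == 0] = 0.0
    return np.clip(r, -1.0, 1.0)


def _rank_order(gene_ids: np.ndarray, key_vals: np.ndarray) -> np.ndarray:
    """Indices sorting genes by key descending, ties by gene id ascending."""
    return np.lexsort((gene_ids, -key_vals))


class AgeCorrelationSelector(TransformerMixin, BaseEstimator):
    """Select the k genes most correlated with age (scikit-learn style).

    ``fit(X, y)`` takes samples x genes expression and per-sample ages;
    ``transform`` keeps the top-``k`` columns in their original order.

    Parameters
    ----------
    k : int
        Number of genes to keep (truncated with a warning when larger
        than the gene count).
    key : {"absolute", "signed"}
        Ranking key: |r| (default) or signed r descending.
    method : {"pearson", "spearman"}
        Correlation flavour; Spearman rank-transforms expression and age
        first.

    Attributes
    ----------
    correlations_ : ndarray, per-gene correlation with age.
    ranks_ : ndarray, 1 = strongest under the configured key.
    support_ : boolean mask of selected genes.
    """

    def __init__(self, k: int = 1000, key: str = "absolute", method: str = "pearson"):
        self.k = k
        self.key = key
        self.method = method

    def fit(self, X, y):
        if self.key not in _KEYS:
            raise ConfigError(f"key must be one of {_KEYS}, got {self.key!r}")
        if self.method not in _METHODS:
            raise ConfigError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if isinstance(X, pd.DataFrame):
            gene_ids = np.asarray([str(c) for c in X.columns])
            vals = X.to_numpy(dtype=float)
        else:
            vals = np.asarray(X, dtype=float)
            gene_ids = np.asarray([f"g{j}" for j in range(vals.shape[1])])
        y = np.asarray(y, dtype=float)
        if vals.shape[0] < 3:
            raise ValueError("need at least 3 samples to correlate with age")
        if y.size != vals.shape[0]:
            raise ValueError("y must hold one age per sample")
        Xf = vals.T  # genes x samples
        if self.method == "spearman":
            Xf = np.apply_along_axis(stats.rankdata, 1, Xf)
            y = stats.rankdata(y)
        r = _pearson_rows(Xf, y)
        key_vals = np.abs(r) if self.key == "absolute" else r
        order = _rank_order(gene_ids, key_vals)
        ranks = np.empty(r.size, dtype=np.int64)
        ranks[order] = np.arange(1, r.size + 1)
        k = self.k
        if k > r.size:
            warnings.warn(
                f"k={k} exceeds the {r.size} available genes; keeping all", stacklevel=2
            )
            k = r.size
        self.n_features_in_ = r.size
        self.gene_ids_ = gene_ids
        self.correlations_ = r
        self.ranks_ = ranks
        self.support_ = ranks <= k
        self.k_effective_ = k
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def top_genes(self) -> list[str]:
        """Selected gene ids ordered by rank (1 first)."""
        check_is_fitted(self, "support_")
        order = np.argsort(self.ranks_, kind="stable")
        return [str(g) for g in self.gene_ids_[order][: self.k_effective_]]

    def to_table(self) -> pd.DataFrame:
        """Per-gene (r, abs_r, rank) table sorted by rank."""
        check_is_fitted(self, "support_")
        tbl = pd.DataFrame(
            {
                "gene_id": self.gene_ids_,
                "r": self.correlations_,
                "abs_r": np.abs(self.correlations_),
                "rank": self.ranks_,
            }
        )
        return tbl.sort_values("rank", kind="stable").reset_index(drop=True)


def correlate_with_age(
    nm: NormalizedMatrix, ages, key: str = "absolute", method: str = "pearson"
) -> pd.DataFrame:
    """Per-gene correlation of normalized expression with age.

    Returns a table with columns ``gene_id``, ``r``, ``abs_r``, ``rank``
    sorted by rank (1 = strongest under ``key``, ties broken by gene id).
    """
    sel = AgeCorrelationSelector(k=nm.values.shape[0], key=key, method=method)
    sel.fit(nm.values.T, np.asarray(ages, dtype=float))
    return sel.to_table()


def top_k(tbl: pd.DataFrame, k: int = 1000, key: str = "absolute") -> list[str]:
    """First ``k`` gene ids by ``key`` (|r| default), ties by gene id.

    Recomputes the ordering from the stored coefficients so the result is
    independent of how the table was ranked at construction.
    """
    if key not in _KEYS:
        raise ConfigError(f"key must be one of {_KEYS}, got {key!r}")
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    gene_ids = tbl["gene_id"].to_numpy(dtype=object).astype(str)
    key_vals = tbl["abs_r"].to_numpy() if key == "absolute" else tbl["r"].to_numpy()
    if k > len(gene_ids):
        warnings.warn(f"k={k} exceeds the {len(gene_ids)} available genes; keeping all",
                      stacklevel=2)
        k = len(gene_ids)
    order = _rank_order(gene_ids, key_vals)
    return [str(g) for g in gene_ids[order][:k]]
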