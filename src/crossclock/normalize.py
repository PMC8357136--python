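"""Library-size normalization: TMM and RLE scaling factors, log2-CPM.

Between-study differences in sequencing depth and protocol shift whole
count distributions; before cross-study modelling a per-sample scaling
factor must absorb them.  Two estimators are provided:

``TMM`` (trimmed mean of M-values)
    For each sample against a reference sample, gene-wise log2 fold
    changes ``M_g`` are doubly trimmed (by ``M`` and by average abundance
    ``A``) and combined in a precision-weighted mean; the factor is
    ``2**mean``.  Factors are rescaled to geometric mean 1.

``RLE`` (relative log expression / median-of-ratios)
    A per-gene pseudo-reference is the geometric mean across samples over
    genes positive everywhere; the raw size factor is the median ratio of
    a sample's counts to the pseudo-reference.

Both are reported on a common "scaling factor given library size"
convention: the effective library size of sample ``k`` is ``N_k * f_k``
with ``geomean(f) = 1``, so the two methods are interchangeable
downstream.  For RLE this divides the raw median-of-ratios size factor by
the library size before rescaling.

Normalized expression is ``log2((count + pseudocount) / (N_k * f_k) * 1e6)``
(log2 counts-per-million with a pseudocount, default 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import ConfigError, CountDataset

__all__ = [
    "CountNormalizer",
    "NormFactors",
    "NormalizationError",
    "NormalizedMatrix",
    "library_factors",
    "log_counts",
    "log_cpm",
    "normalize_dataset",
    "rle_factors",
    "rle_size_factors",
    "study_effect_score",
    "tmm_factors",
]


class NormalizationError(ValueError):
    pass


@dataclass
class NormFactors:
    """Per-sample library sizes and scaling factors for one method."""

    sample_ids: list[str]
    lib_size: np.ndarray
    factors: np.ndarray
    method: str  # "TMM" | "RLE" | "none"

    def __post_init__(self) -> None:
        self.lib_size = np.asarray(self.lib_size, dtype=float)
        self.factors = np.asarray(self.factors, dtype=float)
        if len(self.sample_ids) != self.lib_size.size or self.lib_size.size != self.factors.size:
            raise NormalizationError("sample_ids, lib_size and factors must align")
        if not np.all(self.factors > 0):
            raise NormalizationError("scaling factors must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "lib_size": self.lib_size,
                "factor": self.factors,
                "method": self.method,
            }
        )


@dataclass
class NormalizedMatrix:
    """log2-CPM expression with provenance of the scaling that produced it."""

    values: pd.DataFrame  # genes x samples, real
    method: str
    pseudocount: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise NormalizationError("normalized matrix contains non-finite entries")


# ---------------------------------------------------------------------
# core factor computations (counts arrays are genes x samples)
# ---------------------------------------------------------------------


def _tmm_reference_index(counts: np.ndarray, lib_size: np.ndarray) -> int:
    """Sample whose upper-quartile CPM is closest to the mean upper quartile."""
    cpm = counts / lib_size[None, :] * 1e6
    uq = np.quantile(cpm, 0.75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))

def _trim_mask(key: np.ndarray, gene_ids: np.ndarray, trim_fraction: float) -> np.ndarray:
    """Boolean mask keeping the central genes after a two-tailed trim.

    ``floor(trim_fraction * n)`` genes are removed from each tail of a
    stable sort by ``key`` with ties broken by gene id, so the result is
    deterministic across platforms.
    """
    n = key.size
    t = int(np.floor(trim_fraction * n))
    order = np.lexsort((gene_ids, key))
    keep = np.zeros(n, dtype=bool)
    if n - 2 * t > 0:
        keep[order[t : n - t]] = True
    return keep


def _tmm_factor_vs_ref(
    y_k: np.ndarray,
    y_r: np.ndarray,
    N_k: float,
    N_r: float,
    gene_ids: np.ndarray,
    logratio_trim: float,
    abs_trim: float,
    sample_id: str,
) -> float:
    pos = (y_k > 0) & (y_r > 0)
    if not pos.any():
        raise NormalizationError(
            f"sample {sample_id!r} shares no positively expressed gene with the reference"
        )
    yk, yr, ids = y_k[pos].astype(float), y_r[pos].astype(float), gene_ids[pos]
    pk, pr = yk / N_k, yr / N_r
    M = np.log2(pk / pr)
    A = 0.5 * np.log2(pk * pr)
    keep = _trim_mask(M, ids, logratio_trim) & _trim_mask(A, ids, abs_trim)
    # asymptotic (delta-method) variance of M_g; the weighted mean uses 1/w
    w = (N_k - yk) / (N_k * yk) + (N_r - yr) / (N_r * yr)
    keep &= w > 0
    if not keep.any():
        warnings.warn(
            f"TMM trimming removed every gene for sample {sample_id!r}; factor set to 1",
            stacklevel=2,
        )
        return 1.0
    inv_w = 1.0 / w[keep]
    return float(2.0 ** (np.sum(inv_w * M[keep]) / np.sum(inv_w)))


def _tmm_factors_arr(
    counts: np.ndarray,
    gene_ids: np.ndarray,
    sample_ids: list[str],
    logratio_trim: float,
    abs_trim: float,
    ref_sample: int | None,
) -> tuple[np.ndarray, np.ndarray, int]:
    if counts.shape[1] < 2:
        raise NormalizationError("TMM requires at least 2 samples")
    lib_size = counts.sum(axis=0).astype(float)
    if not np.all(lib_size > 0):
        bad = sample_ids[int(np.argmin(lib_size))]
        raise NormalizationError(f"sample {bad!r} has zero library size")
    r = _tmm_reference_index(counts, lib_size) if ref_sample is None else int(ref_sample)
    f = np.ones(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == r:
            continue
        f[k] = _tmm_factor_vs_ref(
            counts[:, k], counts[:, r], lib_size[k], lib_size[r],
            gene_ids, logratio_trim, abs_trim, sample_ids[k],
        )
    f /= np.exp(np.mean(np.log(f)))
    return f, lib_size, r


def _rle_size_factors_arr(counts: np.ndarray) -> np.ndarray:
    pos_all = (counts > 0).all(axis=1)
    if not pos_all.any():
        raise NormalizationError("RLE requires at least one gene positive in every sample")
    y = counts[pos_all].astype(float)
    ref = np.exp(np.mean(np.log(y), axis=1))  # per-gene geometric mean
    return np.median(y / ref[:, None], axis=0)


# ---------------------------------------------------------------------
# sklearn-style transformer
# ---------------------------------------------------------------------


class CountNormalizer(TransformerMixin, BaseEstimator):
    """Scale raw counts to log2-CPM with TMM, RLE or library-size-only factors.

    Follows the scikit-learn sample-major convention: ``X`` is
    samples x genes.  ``fit`` estimates per-sample library sizes and
    scaling factors; ``transform`` returns the log2-CPM matrix for the
    same samples.

    Parameters
    ----------
    method : {"tmm", "rle", "none"}
        Scaling-factor estimator; ``"none"`` uses library size alone
        (all factors 1).
    logratio_trim, abs_trim : float
        TMM two-tailed trim fractions on the log-fold-change and average
        abundance axes (the original method's published defaults).
    pseudocount : float
        Added to counts before the log2 transform.
    ref_sample : int or None
        TMM reference column; ``None`` selects the sample whose
        upper-quartile CPM is closest to the mean upper quartile.

    Attributes
    ----------
    lib_size_ : ndarray of per-sample total counts.
    scale_factors_ : ndarray, geometric-mean-1 scaling factors.
    reference_index_ : int, TMM reference sample (-1 for other methods).
    """

    def __init__(
        self,
        method: str = "tmm",
        logratio_trim: float = 0.3,
        abs_trim: float = 0.05,
        pseudocount: float = 0.5,
        ref_sample: int | None = None,
    ):
        self.method = method
        self.logratio_trim = logratio_trim
        self.abs_trim = abs_trim
        self.pseudocount = pseudocount
        self.ref_sample = ref_sample

    def _as_array(self, X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(), np.asarray([str(c) for c in X.columns]), [str(i) for i in X.index]
        X = np.asarray(X)
        return (
            X,
            np.asarray([f"g{j}" for j in range(X.shape[1])]),
            [f"s{i}" for i in range(X.shape[0])],
        )

    def fit(self, X, y=None):
        vals, gene_ids, sample_ids = self._as_array(X)
        if vals.ndim != 2:
            raise ValueError("X must be 2-D (samples x genes)")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        counts = vals.T  # genes x samples internally
        method = str(self.method).lower()
        if method == "tmm":
            f, N, r = _tmm_factors_arr(
                counts, gene_ids, sample_ids, self.logratio_trim, self.abs_trim, self.ref_sample
            )
        elif method == "rle":
            N = counts.sum(axis=0).astype(float)
            if not np.all(N > 0):
                raise NormalizationError("every sample needs a positive library size")
            s = _rle_size_factors_arr(counts)
            f = s / N
            f = f / np.exp(np.mean(np.log(f)))
            r = -1
        elif method == "none":
            N = counts.sum(axis=0).astype(float)
            if not np.all(N > 0):
                raise NormalizationError("every sample needs a positive library size")
            f = np.ones(counts.shape[1])
            r = -1
        else:
            raise ConfigError(f"method must be 'tmm', 'rle' or 'none', got {self.method!r}")
        self.n_features_in_ = counts.shape[0]
        self.lib_size_ = N
        self.scale_factors_ = f
        self.reference_index_ = r
        self.sample_ids_ = sample_ids
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_factors_")
        vals, _, _ = self._as_array(X)
        if vals.shape[0] != self.scale_factors_.size:
            raise NormalizationError(
                f"X has {vals.shape[0]} samples but factors were fitted for "
                f"{self.scale_factors_.size}"
            )
        eff = self.lib_size_ * self.scale_factors_
        out = np.log2((vals + self.pseudocount) / eff[:, None] * 1e6)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    def norm_factors(self) -> NormFactors:
        check_is_fitted(self, "scale_factors_")
        method = {"tmm": "TMM", "rle": "RLE"}.get(str(self.method).lower(), "none")
        return NormFactors(
            sample_ids=list(self.sample_ids_),
            lib_size=self.lib_size_,
            factors=self.scale_factors_,
            method=method,
        )


# ---------------------------------------------------------------------
# dataset-level wrappers
# ---------------------------------------------------------------------


def tmm_factors(
    ds: CountDataset,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
    ref_sample: int | None = None,
) -> NormFactors:
    """TMM scaling factors for a :class:`CountDataset` (geometric mean 1)."""
    est = CountNormalizer(
        method="tmm", logratio_trim=logratio_trim, abs_trim=abs_trim, ref_sample=ref_sample
    ).fit(ds.counts.T)
    return est.norm_factors()


def rle_size_factors(ds: CountDataset) -> np.ndarray:
    """Raw RLE (median-of-ratios) size factors, one per sample."""
    return _rle_size_factors_arr(ds.counts.to_numpy())


def rle_factors(ds: CountDataset) -> NormFactors:
    """RLE factors on the TMM convention (factor multiplies library size)."""
    est = CountNormalizer(method="rle").fit(ds.counts.T)
    return est.norm_factors()


def library_factors(ds: CountDataset) -> NormFactors:
    """Library-size-only normalization (all scaling factors 1)."""
    est = CountNormalizer(method="none").fit(ds.counts.T)
    return est.norm_factors()


def log_cpm(ds: CountDataset, factors: NormFactors, pseudocount: float = 0.5) -> NormalizedMatrix:
    """log2 counts-per-million using effective library sizes ``N_k * f_k``."""
    if list(factors.sample_ids) != ds.sample_ids:
        raise NormalizationError("factors are not aligned to the dataset's samples")
    if pseudocount <= 0:
        raise ConfigError(f"pseudocount must be positive, got {pseudocount}")
    eff = factors.lib_size * factors.factors
    vals = np.log2((ds.counts.to_numpy() + pseudocount) / eff[None, :] * 1e6)
    return NormalizedMatrix(
        values=pd.DataFrame(vals, index=ds.counts.index, columns=ds.counts.columns),
        method=factors.method,
        pseudocount=pseudocount,
    )


def log_counts(ds: CountDataset, pseudocount: float = 0.5) -> NormalizedMatrix:
    """Unnormalized ``log2(count + pseudocount)`` — the 'before' picture.

    Between-study histogram separation is assessed on this matrix: raw
    log counts carry the full sequencing-depth study effect, whereas any
    per-million scaling already absorbs most of it.
    """
    if pseudocount <= 0:
        raise ConfigError(f"pseudocount must be positive, got {pseudocount}")
    vals = np.log2(ds.counts.to_numpy() + pseudocount)
    return NormalizedMatrix(
        values=pd.DataFrame(vals, index=ds.counts.index, columns=ds.counts.columns),
        method="raw",
        pseudocount=pseudocount,
    )


def normalize_dataset(
    ds: CountDataset, method: str = "tmm", pseudocount: float = 0.5, **kwargs
) -> tuple[NormFactors, NormalizedMatrix]:
    """One-call convenience: factors plus log2-CPM for a dataset."""
    method_l = str(method).lower()
    if method_l == "tmm":
        factors = tmm_factors(ds, **kwargs)
    elif method_l == "rle":
        factors = rle_factors(ds)
    elif method_l == "none":
        factors = library_factors(ds)
    else:
        raise ConfigError(f"method must be 'tmm', 'rle' or 'none', got {method!r}")
    return factors, log_cpm(ds, factors, pseudocount=pseudocount)


def study_effect_score(nm: NormalizedMatrix, metadata: pd.DataFrame) -> float:
    """Variance across studies of the per-study mean log expression.

    A scalar summary of between-study histogram separation: 0 when every
    study's mean log expression coincides, larger when study effects
    remain.  Requires at least two studies.
    """
    studies = metadata["study_id"]
    uniq = studies.unique()
    if len(uniq) < 2:
        raise NormalizationError("study_effect_score requires at least 2 studies")
    vals = nm.values
    means = [float(vals.loc[:, metadata.index[studies == s]].to_numpy().mean()) for s in uniq]
    return float(np.var(means))
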