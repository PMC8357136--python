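"""Count-matrix containers, validation, age groups and the expression filter.

A :class:`CountDataset` couples a genes x samples matrix of non-negative
integer read counts (the output of a gene-level quantifier such as STAR
``--quantMode GeneCounts``) with per-sample metadata: the study of origin,
the chronological age with its unit (``years`` for human, ``days`` for fly)
and a species tag.  All downstream stages (normalization, ranking,
evaluation) consume this container.

Age groups follow fixed chronological cutoffs per species:

* years — Young ``< 30``, Middle ``30–60`` inclusive, Old ``> 60``;
* days  — Young ``<= 10``, Middle ``(10, 29]``, Old ``> 29``.

The day-scale boundaries are chosen so the three groups partition the
positive reals; day 30 falls in Old, the first age beyond the Middle range.
Both boundary pairs are configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUP_LABELS",
    "AgeGroup",
    "ConfigError",
    "CountDataset",
    "ValidationError",
    "assign_age_group",
    "assign_age_groups",
    "filter_expressed",
    "read_count_dataset",
]

AGE_UNITS = ("years", "days")

METADATA_COLUMNS = ("sample_id", "study_id", "age", "age_unit", "species")


class ValidationError(ValueError):
    """Input data violates a :class:`CountDataset` invariant."""


class ConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


class AgeGroup(str, Enum):
    YOUNG = "Young"
    MIDDLE = "Middle"
    OLD = "Old"


AGE_GROUP_LABELS = [g.value for g in AgeGroup]


def assign_age_group(
    age: float,
    unit: str,
    *,
    year_bounds: tuple[float, float] = (30.0, 60.0),
    day_bounds: tuple[float, float] = (10.0, 29.0),
) -> AgeGroup:
    """Assign a chronological age to the Young / Middle / Old group.

    Parameters
    ----------
    age : positive age in ``unit``.
    unit : ``"years"`` or ``"days"``.
    year_bounds : (young_below, old_above) for year-scale ages; Young is
        strictly below the first bound, Old strictly above the second,
        Middle the closed interval between them.
    day_bounds : (young_max, middle_max) for day-scale ages; Young is
        ``<= young_max``, Middle ``(young_max, middle_max]``, Old above.
    """
    if unit not in AGE_UNITS:
        raise ValidationError(f"unknown age unit {unit!r}; expected one of {AGE_UNITS}")
    if not (age > 0) or not math.isfinite(age):
        raise ValidationError(f"age must be a positive finite number, got {age!r}")
    if unit == "years":
        lo, hi = year_bounds
        if age < lo:
            return AgeGroup.YOUNG
        if age <= hi:
            return AgeGroup.MIDDLE
        return AgeGroup.OLD
    lo, hi = day_bounds
    if age <= lo:
        return AgeGroup.YOUNG
    if age <= hi:
        return AgeGroup.MIDDLE
    return AgeGroup.OLD


def assign_age_groups(ages, unit: str, **kwargs) -> pd.Series:
    """Vectorised :func:`assign_age_group`; returns labels as a Series."""
    ages = pd.Series(ages)
    return ages.map(lambda a: assign_age_group(float(a), unit, **kwargs).value)


@dataclass
class CountDataset:
    """Genes x samples integer counts plus aligned per-sample metadata.

    ``counts`` is indexed by gene id with one column per sample id;
    ``metadata`` is indexed by sample id with columns ``study_id``, ``age``,
    ``age_unit`` and ``species`` (``sex`` optional).  Column order of
    ``counts`` always equals the metadata row order.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    warnings_: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------

    def validate(self) -> None:
        counts, meta = self.counts, self.metadata
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if meta.index.has_duplicates:
            dup = meta.index[meta.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in metadata")
        missing = meta.index.difference(counts.columns)
        if len(missing):
            raise ValidationError(
                f"sample {missing[0]!r} listed in metadata but absent from the count matrix"
            )
        extra = counts.columns.difference(meta.index)
        if len(extra):
            raise ValidationError(
                f"sample {extra[0]!r} present in the count matrix but absent from metadata"
            )
        # sample order follows metadata
        if list(counts.columns) != list(meta.index):
            self.counts = counts = counts.loc[:, meta.index]
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or not np.all(vals == np.floor(vals)):
                raise ValidationError(
                    "counts must be integers; use read_count_dataset(..., allow_noninteger=True) "
                    "for expected-count matrices"
                )
            self.counts = counts = counts.astype(np.int64)
            vals = counts.to_numpy()
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count for gene {counts.index[g]!r} in sample {counts.columns[s]!r}"
            )
        for col in ("study_id", "age", "age_unit", "species"):
            if col not in meta.columns:
                raise ValidationError(f"metadata is missing required column {col!r}")
        units = set(meta["age_unit"])
        if len(units) != 1:
            raise ValidationError(f"a dataset must use a single age unit, got {sorted(units)}")
        (unit,) = units
        if unit not in AGE_UNITS:
            raise ValidationError(f"unknown age unit {unit!r}; expected one of {AGE_UNITS}")
        ages = meta["age"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ages)) or not np.all(ages > 0):
            bad = meta.index[~(np.isfinite(ages) & (ages > 0))][0]
            raise ValidationError(f"non-positive or non-finite age for sample {bad!r}")
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None
        self.metadata.index.name = "sample_id"

    # -- convenience --------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def ages(self) -> np.ndarray:
        return self.metadata["age"].to_numpy(dtype=float)

    @property
    def age_unit(self) -> str:
        return str(self.metadata["age_unit"].iloc[0])

    @property
    def species(self) -> str:
        return str(self.metadata["species"].iloc[0])

    def age_groups(self, **kwargs) -> pd.Series:
        return assign_age_groups(self.metadata["age"], self.age_unit, **kwargs)

    def library_sizes(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=0).astype(float)

    def write(self, counts_path, metadata_path) -> None:
        """Write the tab-delimited matrix and metadata files."""
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id", lineterminator="\n")
        # %.17g keeps float ages bit-exact through a write/read cycle
        self.metadata.to_csv(
            metadata_path,
            sep="\t",
            index_label="sample_id",
            lineterminator="\n",
            float_format="%.17g",
        )


def read_count_dataset(
    counts_path,
    metadata_path,
    *,
    allow_noninteger: bool = False,
) -> CountDataset:
    """Read a tab-delimited count matrix and its sample metadata.

    The matrix has a header row of sample ids and gene ids in the first
    column; metadata has columns ``sample_id``, ``study_id``, ``age``,
    ``age_unit``, ``species`` (extra columns are carried through).  With
    ``allow_noninteger`` real-valued expected counts are floor-rounded,
    accommodating quantifiers that emit fractional counts.
    """
    counts_path, metadata_path = Path(counts_path), Path(metadata_path)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    # round_trip parsing keeps float ages bit-exact through write/read
    meta = pd.read_csv(metadata_path, sep="\t", float_precision="round_trip")
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata is missing required column 'sample_id'")
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta = meta.set_index("sample_id")
    if allow_noninteger:
        vals = counts.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("counts contain non-finite values")
        counts = pd.DataFrame(
            np.floor(vals).astype(np.int64), index=counts.index, columns=counts.columns
        )
    return CountDataset(counts=counts, metadata=meta)


def filter_expressed(
    ds: CountDataset, min_count: int = 10, min_fraction: float = 0.5
) -> CountDataset:
    """Keep genes with counts strictly above ``min_count`` in enough samples.

    A gene is retained iff the number of samples with ``count > min_count``
    is at least ``ceil(min_fraction * n_samples)``.  Sample set and gene
    order are unchanged.  An empty result is returned with a warning, not
    an error.
    """
    if not 0 < min_fraction <= 1:
        raise ConfigError(f"min_fraction must be in (0, 1], got {min_fraction}")
    need = math.ceil(min_fraction * ds.n_samples)
    keep = (ds.counts.to_numpy() > min_count).sum(axis=1) >= need
    out = CountDataset(counts=ds.counts.loc[keep], metadata=ds.metadata.copy())
    if not keep.any():
        msg = "expression filter removed every gene"
        warnings.warn(msg, stacklevel=2)
        out.warnings_.append(msg)
    return out
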