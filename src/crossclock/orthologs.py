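"""Ortholog best-match resolution and cross-species conserved gene sets.

An ortholog prediction aggregator (DIOPT-style) emits a scored
many-to-many table of candidate pairs between two species.  Resolution to
a one-to-one "best match" is greedy: rows are visited from highest to
lowest score (ties broken lexicographically by the two gene ids) and a
row is accepted only if neither gene is already matched.  Greedy-by-score
mirrors the keep-the-highest-ranked-homolog convention; a maximum-weight
bipartite matching would silently produce a different gene set.

The conserved set is the intersection stage: best-match pairs whose two
members both sit inside their species' top-k age-correlation list.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ValidationError

__all__ = [
    "intersect_conserved",
    "read_ortholog_table",
    "resolve_best_match",
    "validate_ortholog_table",
    "write_ortholog_table",
]

ORTHOLOG_COLUMNS = ["gene_id_a", "gene_id_b", "score"]


def validate_ortholog_table(tbl: pd.DataFrame) -> pd.DataFrame:
    """Check the (gene_id_a, gene_id_b, score) invariants; returns a copy."""
    for col in ORTHOLOG_COLUMNS:
        if col not in tbl.columns:
            raise ValidationError(f"ortholog table is missing column {col!r}")
    out = tbl[ORTHOLOG_COLUMNS].copy()
    out["gene_id_a"] = out["gene_id_a"].astype(str)
    out["gene_id_b"] = out["gene_id_b"].astype(str)
    out["score"] = out["score"].astype(float)
    if out.duplicated(["gene_id_a", "gene_id_b"]).any():
        dup = out[out.duplicated(["gene_id_a", "gene_id_b"])].iloc[0]
        raise ValidationError(
            f"duplicate ortholog pair ({dup['gene_id_a']!r}, {dup['gene_id_b']!r})"
        )
    scores = out["score"].to_numpy()
    if not np.all(np.isfinite(scores)) or (scores < 0).any():
        raise ValidationError("ortholog scores must be finite and non-negative")
    return out


def read_ortholog_table(path) -> pd.DataFrame:
    return validate_ortholog_table(pd.read_csv(Path(path), sep="\t"))


def write_ortholog_table(tbl: pd.DataFrame, path) -> None:
    validate_ortholog_table(tbl).to_csv(path, sep="\t", index=False, lineterminator="\n")


def resolve_best_match(tbl: pd.DataFrame) -> pd.DataFrame:
    """Greedy one-to-one resolution of a scored many-to-many table.

    Rows are sorted by (score desc, gene_id_a asc, gene_id_b asc) and a
    row is kept iff neither id has been matched yet.  The result is a
    table with the same three columns in acceptance order; each id on
    either side appears at most once.  An empty table yields an empty map.
    """
    tbl = validate_ortholog_table(tbl)
    ordered = tbl.sort_values(
        ["score", "gene_id_a", "gene_id_b"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    used_a: set[str] = set()
    used_b: set[str] = set()
    keep_rows = []
    for row in ordered.itertuples(index=False):
        if row.gene_id_a in used_a or row.gene_id_b in used_b:
            continue
        used_a.add(row.gene_id_a)
        used_b.add(row.gene_id_b)
        keep_rows.append(row)
    return pd.DataFrame(keep_rows, columns=ORTHOLOG_COLUMNS)


def intersect_conserved(
    top_a: list[str],
    top_b: list[str],
    best_match: pd.DataFrame,
    corr_a: pd.DataFrame | None = None,
    corr_b: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Best-match pairs with both members in their species' top-k list.

    ``top_a`` / ``top_b`` are rank-ordered gene lists (index 0 = rank 1).
    Pairs are ordered by ``min(rank_a, rank_b)`` then ``gene_id_a`` and
    carry both species' correlation coefficients when the per-gene tables
    (columns ``gene_id``, ``r``) are supplied.
    """
    rank_a = {g: i + 1 for i, g in enumerate(top_a)}
    rank_b = {g: i + 1 for i, g in enumerate(top_b)}
    rows = []
    for row in best_match.itertuples(index=False):
        ra, rb = rank_a.get(row.gene_id_a), rank_b.get(row.gene_id_b)
        if ra is None or rb is None:
            continue
        rows.append((row.gene_id_a, row.gene_id_b, ra, rb, row.score))
    out = pd.DataFrame(
        rows, columns=["gene_id_a", "gene_id_b", "rank_a", "rank_b", "score"]
    )
    if len(out):
        out["min_rank"] = out[["rank_a", "rank_b"]].min(axis=1)
        out = (
            out.sort_values(["min_rank", "gene_id_a"], kind="mergesort")
            .drop(columns="min_rank")
            .reset_index(drop=True)
        )
    for name, corr, col in (("gene_id_a", corr_a, "r_a"), ("gene_id_b", corr_b, "r_b")):
        if corr is not None:
            lookup = dict(zip(corr["gene_id"].astype(str), corr["r"].astype(float)))
            out[col] = [lookup.get(g, np.nan) for g in out[name]] if len(out) else []
        else:
            out[col] = pd.Series([], dtype=float) if not len(out) else np.nan
    return out[["gene_id_a", "gene_id_b", "r_a", "r_b", "rank_a", "rank_b", "score"]]
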