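"""Overrepresentation analysis and cell-type marker-set derivation.

Gene lists emerging from the association stage are tested for
overrepresentation of annotated gene sets (GO/REACTOME/KEGG-style
collections in GMT format, or cell-type marker sets) with a one-sided
Fisher's exact test against a declared background universe — here the
cortex-expressed genes.  Marker sets are derived from a cell-type
mean-expression (FPKM) table: a gene marks a cell type when its expression
there exceeds 2.5 FPKM and is at least 3.0 times the mean over the other
cell types.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import AbstractSet, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr

__all__ = [
    "fisher_ora",
    "derive_marker_sets",
    "read_gmt",
    "write_gmt",
]

logger = logging.getLogger(__name__)


def fisher_ora(
    gene_list: AbstractSet[str],
    collection: Mapping[str, AbstractSet[str]],
    background: AbstractSet[str],
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation of ``gene_list`` in each set.

    Genes outside ``background`` are dropped from the list (their count is
    logged) and every set is intersected with the background before
    testing.  Per set the 2x2 table is

        a = |list ∩ set|      b = |list \\ set|
        c = |set \\ list|     d = |background \\ (list ∪ set)|

    with p the upper hypergeometric tail (enrichment only) and the sample
    odds ratio ``a d / (b c)``; 0.5 is added to every cell iff any cell is
    zero (Haldane correction).  q-values are Benjamini–Hochberg across the
    whole collection.

    Raises
    ------
    ValueError
        If the background is empty.
    """
    background = set(background)
    if not background:
        raise ValueError("background must be nonempty")
    gene_list = set(gene_list)
    dropped = len(gene_list - background)
    if dropped:
        logger.info("dropping %d list genes outside the background", dropped)
        gene_list &= background
    n_bg = len(background)
    n_list = len(gene_list)

    rows = []
    for name, members in collection.items():
        gset = set(members) & background
        a = len(gene_list & gset)
        b = n_list - a
        c = len(gset) - a
        d = n_bg - n_list - c
        # P(X >= a) for X ~ Hypergeom(N=n_bg, K=|set|, n=|list|)
        p = float(stats.hypergeom.sf(a - 1, n_bg, len(gset), n_list))
        if min(a, b, c, d) == 0:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            aa, bb, cc, dd = a, b, c, d
        rows.append(
            {
                "set_name": name,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": (aa * dd) / (bb * cc),
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def derive_marker_sets(
    mean_expr: pd.DataFrame,
    fpkm_min: float = 2.5,
    enr_min: float = 3.0,
) -> dict[str, frozenset]:
    """Cell-type marker sets from a genes x cell-types mean-FPKM table.

    Gene g marks cell type T iff FPKM(g, T) > ``fpkm_min`` (strict) and
    FPKM(g, T) / mean over the other types >= ``enr_min`` (inclusive).
    A zero mean over the other types counts as infinitely enriched.

    Raises
    ------
    ValueError
        With fewer than two cell types (the non-target mean is undefined)
        or negative FPKM values.
    """
    if mean_expr.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    vals = mean_expr.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("FPKM values must be nonnegative")
    n_types = vals.shape[1]
    totals = vals.sum(axis=1, keepdims=True)
    other_mean = (totals - vals) / (n_types - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = np.where(other_mean > 0, vals / np.where(other_mean > 0, other_mean, 1.0), np.inf)
    marker = (vals > fpkm_min) & (enrich >= enr_min)
    return {
        ct: frozenset(mean_expr.index[marker[:, j]])
        for j, ct in enumerate(mean_expr.columns)
    }


def read_gmt(path) -> dict[str, frozenset]:
    """Read a GMT gene-set file (name, description, members per tab-split line)."""
    sets: dict[str, frozenset] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, AbstractSet[str] | Sequence[str]], path) -> None:
    """Write gene sets in GMT format (description column left as 'na')."""
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")
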