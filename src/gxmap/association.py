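"""Spatially-adjusted rank association of expression with atrophy.

For one donor, one atrophy map and one probe, the analysis approximates the
Spearman correlation between the sampled atrophy t-value and the probe's
expression by regressing the *ranks* of the t-values on the *ranks* of the
expression values.  Because both fields are spatially smooth, the residuals
of that regression are typically autocorrelated, which inflates the nominal
test; the model is therefore extended with Moran eigenvector maps (spatial
eigenvector filtering): if Moran's I flags the residuals (p < 0.05), leading
eigenvectors of the donor's 10-NN weight graph are added as covariates —
first one, then in steps of five, up to 150 — until the residuals look
spatially unstructured or the cap is reached.

Donor-level two-sided p-values for the expression coefficient are combined
across donors with Stouffer's weighted-Z method, weights restricted to ±1 so
that each donor contributes only its direction of association (donors with
more samples are not up-weighted).  Meta p-values are corrected per map with
Benjamini–Hochberg FDR, gene lists are formed by the any-probe rule, and
consensus lists intersect the per-map lists across the three maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .spatial import DegenerateInputError, EigenvectorBasis, SpatialGraph, build_knn_graph, compute_mem, moran_i
from .synthetic import ExpressionBundle

__all__ = [
    "SevmFit",
    "GeneLists",
    "AssociationResult",
    "rank_transform",
    "default_schedule",
    "fit_with_sevm",
    "stouffer_combine",
    "bh_fdr",
    "probe_to_gene_lists",
    "consensus_lists",
    "run_association",
]

logger = logging.getLogger(__name__)

#: Clamping bounds applied to donor p-values before normal-quantile inversion.
P_CLAMP = (1e-300, 1.0 - 1e-16)


class RankDeficientError(ValueError):
    """The design matrix lost rank (predictor collinear with covariates)."""


@dataclass(frozen=True)
class SevmFit:
    """One probe x donor x map fit after spatial-eigenvector escalation."""

    coef_t: float
    p: float
    n_eigenvectors: int
    residual_moran_p: float
    beta: float


@dataclass(frozen=True)
class GeneLists:
    """Signed significant gene lists for one atrophy map."""

    positive: frozenset
    negative: frozenset


@dataclass
class AssociationResult:
    """Full output of :func:`run_association`.

    ``probe_results``: one row per (map, probe) with combined statistics.
    ``donor_results``: one row per (map, donor, probe) with the per-donor fit.
    ``eigenvector_summary``: min/median/IQR/max of the per-fit eigenvector
    counts, per map.
    """

    probe_results: pd.DataFrame
    donor_results: pd.DataFrame
    eigenvector_summary: pd.DataFrame

    def gene_lists(
        self, probe_gene_map: Mapping[str, str], threshold: float = 0.05
    ) -> dict[str, GeneLists]:
        return {
            map_id: probe_to_gene_lists(sub, probe_gene_map, threshold)
            for map_id, sub in self.probe_results.groupby("map_id", sort=False)
        }


def rank_transform(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by their average rank."""
    return stats.rankdata(np.asarray(x, dtype=float))


def default_schedule(cap: int = 150) -> list[int]:
    """Eigenvector-count escalation: none, then one, then multiples of five."""
    return [0, 1] + list(range(5, cap + 1, 5))


def _moran_p_safe(resid: np.ndarray, g: SpatialGraph) -> float:
    # A numerically constant residual carries no spatial signal.
    try:
        return moran_i(resid, g).p
    except DegenerateInputError:
        return 1.0


def fit_with_sevm(
    t_vals: np.ndarray,
    expr: np.ndarray,
    basis: EigenvectorBasis,
    g: SpatialGraph,
    alpha: float = 0.05,
    cap: int = 150,
    schedule: Sequence[int] | None = None,
) -> SevmFit:
    """Rank regression of atrophy on expression with eigenvector escalation.

    Regresses ``rank(t_vals)`` on ``rank(expr)`` plus the first m Moran
    eigenvectors, starting at m = 0.  After each fit the residuals are
    tested with Moran's I; while the test rejects (p < ``alpha``) m advances
    along the schedule (default 0, 1, 5, 10, ..., ``cap``).  The escalation
    also stops when the schedule is exhausted, the basis runs out of
    vectors, or the residual degrees of freedom would vanish; the final
    residual Moran p is reported as-is in that case.

    Because the eigenvector basis is orthonormal and centered, each fit is
    computed by projecting both ranked variables off the first m
    eigenvectors (Frisch–Waugh), which reproduces the full OLS coefficient,
    t-statistic (df = n - 2 - m) and residuals exactly.

    Raises
    ------
    RankDeficientError
        If the expression ranks are (numerically) in the span of the
        intercept and eigenvectors at some step m.
    """
    y = rank_transform(t_vals)
    x = rank_transform(expr)
    n = y.size
    if x.size != n:
        raise ValueError("t_vals and expr must have equal length")
    yc = y - y.mean()
    xc = x - x.mean()
    sxx_total = float(xc @ xc)
    if sxx_total <= 0:
        raise RankDeficientError("expression is constant (m=0)")

    E = basis.vectors
    if schedule is None:
        schedule = default_schedule(cap)
    ms = [m for m in schedule if m <= min(cap, E.shape[1], n - 3)]

    fit: SevmFit | None = None
    for m in ms:
        if m == 0:
            xr, yr = xc, yc
        else:
            Em = E[:, :m]
            xr = xc - Em @ (Em.T @ xc)
            yr = yc - Em @ (Em.T @ yc)
        sxx = float(xr @ xr)
        if sxx <= 1e-12 * sxx_total:
            raise RankDeficientError(
                f"expression ranks collinear with the first {m} eigenvectors (m={m})"
            )
        beta = float(xr @ yr) / sxx
        resid = yr - beta * xr
        dof = n - 2 - m
        sigma2 = float(resid @ resid) / dof
        if sigma2 <= 0:
            coef_t, p = np.inf * np.sign(beta), 0.0
        else:
            coef_t = beta / np.sqrt(sigma2 / sxx)
            p = 2.0 * float(stats.t.sf(abs(coef_t), dof))
        moran_p = _moran_p_safe(resid, g)
        fit = SevmFit(
            coef_t=float(coef_t),
            p=float(p),
            n_eigenvectors=m,
            residual_moran_p=float(moran_p),
            beta=beta,
        )
        if moran_p >= alpha:
            break
    assert fit is not None
    return fit


def stouffer_combine(
    p_values: Sequence[float], signs: Sequence[float]
) -> tuple[float, float]:
    """Direction-weighted Stouffer combination of two-sided donor p-values.

    Each donor contributes Z_i = Phi^-1(1 - p_i/2) (the magnitude implied by
    its two-sided p) with weight w_i = sign of its association;
    z_meta = sum(w_i Z_i) / sqrt(sum w_i^2) and p_meta is two-sided normal.
    p-values are clamped to [1e-300, 1 - 1e-16] before inversion.

    Raises
    ------
    ValueError
        With fewer than 2 donors, or p-values outside (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    w = np.sign(np.asarray(signs, dtype=float))
    if p.size < 2:
        raise ValueError("Stouffer combination needs at least 2 donors")
    if p.size != w.size:
        raise ValueError("p_values and signs must have equal length")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    p = np.clip(p, *P_CLAMP)
    z = stats.norm.isf(p / 2.0)
    denom = np.sqrt(float((w**2).sum()))
    if denom == 0:
        return 0.0, 1.0
    z_meta = float((w * z).sum() / denom)
    p_meta = 2.0 * float(stats.norm.sf(abs(z_meta)))
    return z_meta, min(p_meta, 1.0)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR q-values.

    Raises
    ------
    ValueError
        If any p lies outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def probe_to_gene_lists(
    assocs: pd.DataFrame,
    probe_gene_map: Mapping[str, str],
    threshold: float = 0.05,
) -> GeneLists:
    """Collapse probe-level calls to signed gene lists by the any-probe rule.

    A gene is positive iff *any* of its probes has q < ``threshold`` and
    z_meta > 0; negative likewise with z_meta < 0.  A gene with discordant
    significant probes appears in both lists.

    Raises
    ------
    ValueError
        If a probe has no gene mapping.
    """
    missing = [pid for pid in assocs["probe_id"] if pid not in probe_gene_map]
    if missing:
        raise ValueError(f"probes without gene mapping: {missing[:5]}")
    sig = assocs.loc[assocs["q"] < threshold]
    pos = frozenset(probe_gene_map[p] for p in sig.loc[sig["z_meta"] > 0, "probe_id"])
    neg = frozenset(probe_gene_map[p] for p in sig.loc[sig["z_meta"] < 0, "probe_id"])
    return GeneLists(positive=pos, negative=neg)


def consensus_lists(per_map: Mapping[str, GeneLists]) -> tuple[frozenset, frozenset]:
    """Intersect per-map signed gene lists across exactly three maps."""
    if len(per_map) != 3:
        raise ValueError(f"consensus is defined over exactly 3 maps, got {len(per_map)}")
    lists = list(per_map.values())
    pos = lists[0].positive & lists[1].positive & lists[2].positive
    neg = lists[0].negative & lists[1].negative & lists[2].negative
    return pos, neg


def _summarise_counts(counts: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(counts, [25, 50, 75])
    return {
        "min": float(counts.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(counts.max()),
    }


def run_association(
    bundles: Sequence[ExpressionBundle],
    atrophy_tables: Mapping[str, pd.DataFrame],
    k: int = 10,
    alpha: float = 0.05,
    cap: int = 150,
    min_donors: int = 2,
    schedule: Sequence[int] | None = None,
) -> AssociationResult:
    """Run the per-donor SEVM fits and cross-donor combination for all maps.

    Parameters
    ----------
    bundles : donor expression bundles (each with its own geometry).
    atrophy_tables : donor_id -> samples x maps table of sampled t-values,
        indexed by sample_id and aligned (by id) with the bundle's samples.
    k, alpha, cap, schedule : spatial-graph and escalation settings.
    min_donors : minimum donors with a valid fit for a probe to be combined.

    Probes with zero expression variance in a donor are skipped for that
    donor; combination then runs over the remaining donors.  FDR correction
    is applied per map across all combined probes of that map.
    """
    # per-donor spatial structure, built once
    graphs: dict[str, SpatialGraph] = {}
    bases: dict[str, EigenvectorBasis] = {}
    for b in bundles:
        graphs[b.donor_id] = build_knn_graph(b.pairwise_dist(), k=k)
        bases[b.donor_id] = compute_mem(graphs[b.donor_id])

    donor_rows: list[dict] = []
    map_ids = list(next(iter(atrophy_tables.values())).columns)
    for map_id in map_ids:
        for b in bundles:
            tab = atrophy_tables[b.donor_id]
            t_vals = tab.loc[b.samples["sample_id"], map_id].to_numpy(dtype=float)
            expr = b.expression.to_numpy(dtype=float)
            ranked_y = rank_transform(t_vals)
            for pid, row in zip(b.expression.index, expr):
                if np.ptp(row) == 0.0:
                    continue  # constant probe in this donor
                fit = fit_with_sevm(
                    ranked_y, row, bases[b.donor_id], graphs[b.donor_id],
                    alpha=alpha, cap=cap, schedule=schedule,
                )
                donor_rows.append(
                    {
                        "map_id": map_id,
                        "donor_id": b.donor_id,
                        "probe_id": pid,
                        "coef_t": fit.coef_t,
                        "p": fit.p,
                        "n_eigenvectors": fit.n_eigenvectors,
                        "residual_moran_p": fit.residual_moran_p,
                    }
                )
    donor_results = pd.DataFrame(donor_rows)

    probe_rows: list[dict] = []
    for (map_id, pid), sub in donor_results.groupby(["map_id", "probe_id"], sort=False):
        if len(sub) < min_donors:
            continue
        z_meta, p_meta = stouffer_combine(sub["p"].to_numpy(), sub["coef_t"].to_numpy())
        probe_rows.append(
            {
                "map_id": map_id,
                "probe_id": pid,
                "n_donors": len(sub),
                "z_meta": z_meta,
                "p_meta": p_meta,
            }
        )
    probe_results = pd.DataFrame(probe_rows)
    if len(probe_results):
        qs = []
        for map_id, sub in probe_results.groupby("map_id", sort=False):
            qs.append(pd.Series(bh_fdr(sub["p_meta"].to_numpy()), index=sub.index))
        probe_results["q"] = pd.concat(qs).sort_index()
        probe_results["direction"] = np.sign(probe_results["z_meta"]).astype(int)

    summaries = []
    for map_id, sub in donor_results.groupby("map_id", sort=False):
        s = _summarise_counts(sub["n_eigenvectors"].to_numpy())
        s["map_id"] = map_id
        summaries.append(s)
        logger.info(
            "map %s: eigenvectors per fit min=%g median=%g IQR=(%g, %g) max=%g",
            map_id, s["min"], s["median"], s["q1"], s["q3"], s["max"],
        )
    eigen_summary = pd.DataFrame(summaries)
    return AssociationResult(
        probe_results=probe_results,
        donor_results=donor_results,
        eigenvector_summary=eigen_summary,
    )
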