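"""Synthetic donors: geometry, expression, atrophy maps and annotation fixtures.

Real inputs to the pipeline — donor microarray bundles and voxel-wise
atrophy t-maps — are large external downloads.  This module generates
structurally faithful stand-ins so every downstream stage runs and can be
validated end to end:

* donor geometries: samples scattered on a curved 2-D sheet embedded in 3-D
  (cortex-like), with graph-shortest-path distances along a dense neighbour
  mesh standing in for geodesic distances along the cortical surface;
* expression: per-gene latent fields drawn from a Gaussian process over the
  geodesic surrogate (squared-exponential covariance), plus white noise and
  per-probe noise; selected genes receive a planted monotone association
  with an atrophy field, calibrated on the Spearman scale;
* atrophy volumes: smooth radial t-statistic bumps on a voxel grid with a
  proper voxel-to-world affine;
* probe annotation tables, cell-type mean-expression (FPKM) tables with
  designated markers, and gene-set collections.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import cKDTree

from .volumes import AtrophyVolume, sample_volume_at

__all__ = [
    "DonorGeometry",
    "GroundTruth",
    "ExpressionBundle",
    "generate_geometry",
    "generate_expression",
    "generate_atrophy_volume",
    "atrophy_for_geometry",
    "generate_probe_annotation",
    "generate_marker_table",
    "generate_gene_sets",
    "write_expression_bundle",
    "read_expression_bundle",
]

#: Standard deviation of independent per-probe noise around the gene latent.
PROBE_NOISE_SD = 0.25
#: Quantile of a probe's own values above which it is flagged "expressed".
EXPRESSED_QUANTILE = 0.25
#: Side length of the synthetic cortical sheet, mm.
SHEET_EXTENT_MM = 60.0


@dataclass(frozen=True)
class DonorGeometry:
    """Sample coordinates of one donor plus a geodesic-surrogate distance matrix.

    ``pairwise_dist`` holds shortest-path lengths over a dense neighbour mesh
    on the sheet the samples were drawn from; any externally supplied
    symmetric distance matrix (e.g. true surface geodesics) is equally valid.
    """

    donor_id: str
    coords: np.ndarray
    pairwise_dist: np.ndarray

    def __post_init__(self) -> None:
        d = self.pairwise_dist
        if d.shape[0] != d.shape[1] or d.shape[0] != self.coords.shape[0]:
            raise ValueError("distance matrix does not match coordinates")
        if not np.allclose(d, d.T, atol=1e-8) or not np.allclose(np.diag(d), 0):
            raise ValueError("pairwise_dist must be symmetric with zero diagonal")

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic expression dataset.

    ``effect_rho`` maps each planted gene to its target |Spearman| with the
    atrophy field (in (0, 1]); ``directions`` optionally flips the sign of
    the association per gene.  ``confound_genes`` are spatially
    autocorrelated but carry no atrophy link, emulating the smooth
    expression gradients that confound naive correlation.
    """

    effect_rho: Mapping[str, float]
    confound_genes: frozenset = frozenset()
    directions: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.effect_rho) & set(self.confound_genes):
            raise ValueError("assoc_genes and confound_genes must be disjoint")
        for g, r in self.effect_rho.items():
            if not 0.0 < r <= 1.0:
                raise ValueError(f"effect_rho for {g} must be in (0, 1], got {r}")
        for g, s in self.directions.items():
            if s not in (-1, 1):
                raise ValueError(f"direction for {g} must be +/-1")

    @property
    def assoc_genes(self) -> frozenset:
        return frozenset(self.effect_rho)

    def direction(self, gene: str) -> int:
        return self.directions.get(gene, 1)


@dataclass
class ExpressionBundle:
    """One donor's worth of pipeline input.

    ``samples``: sample annotation (sample_id, donor_id, MNI coordinates,
    slab type, structure label, hemisphere, distance to cortical ROI).
    ``probes``: probe annotation (probe_id, gene_symbol, mapping_status).
    ``expression``: probes x samples values; ``expressed``: same-shape
    boolean presence calls.  ``distances`` optionally carries the donor's
    geodesic-surrogate matrix (Euclidean distances are derived from the
    coordinates when absent).
    """

    donor_id: str
    samples: pd.DataFrame
    probes: pd.DataFrame
    expression: pd.DataFrame
    expressed: pd.DataFrame
    distances: np.ndarray | None = None

    def sample_coords(self) -> np.ndarray:
        return self.samples[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)

    def pairwise_dist(self) -> np.ndarray:
        if self.distances is not None:
            return self.distances
        c = self.sample_coords()
        diff = c[:, None, :] - c[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))


# ---------------------------------------------------------------------------
# geometry


def _sheet_points(n: int, rng: np.random.Generator) -> np.ndarray:
    """Points on a gently curved sheet: z = a sin(u/s) cos(v/s)."""
    u = rng.uniform(0.0, SHEET_EXTENT_MM, size=n)
    v = rng.uniform(0.0, SHEET_EXTENT_MM, size=n)
    z = 12.0 * np.sin(u / 15.0) * np.cos(v / 15.0)
    return np.column_stack([u, v, z])


def _mesh_geodesics(coords: np.ndarray, k_mesh: int = 8) -> np.ndarray:
    """Shortest-path lengths over a k-NN mesh with Euclidean edge weights.

    The mesh density is increased until the graph is connected, so every
    pairwise distance is finite.
    """
    n = coords.shape[0]
    tree = cKDTree(coords)
    k = min(k_mesh, n - 1)
    while True:
        d, j = tree.query(coords, k=k + 1)
        rows = np.repeat(np.arange(n), k)
        cols = j[:, 1:].ravel()
        vals = d[:, 1:].ravel()
        graph = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        graph = graph.maximum(graph.T)
        ncomp, _ = connected_components(graph, directed=False)
        if ncomp == 1 or k >= n - 1:
            break
        k = min(2 * k, n - 1)
    dist = shortest_path(graph, method="D", directed=False)
    return 0.5 * (dist + dist.T)


def generate_geometry(n_donors: int, n_samples: int, seed: int) -> list[DonorGeometry]:
    """Generate donor geometries on independent curved sheets.

    Each donor's samples are drawn uniformly over the sheet; the pairwise
    distance matrix holds graph-geodesics along a dense neighbour mesh.
    Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If ``n_samples`` < 20 (too few points for a meaningful mesh and the
        downstream 10-NN graph).
    """
    if n_samples < 20:
        raise ValueError(f"n_samples must be >= 20, got {n_samples}")
    out = []
    for i in range(n_donors):
        rng = np.random.default_rng([seed, i])
        coords = _sheet_points(n_samples, rng)
        dist = _mesh_geodesics(coords)
        out.append(DonorGeometry(donor_id=f"donor{i + 1}", coords=coords, pairwise_dist=dist))
    return out


# ---------------------------------------------------------------------------
# expression


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (van der Waerden scores)."""
    r = stats.rankdata(x)
    return stats.norm.ppf((r - 0.5) / len(x))


def generate_expression(
    geom: DonorGeometry,
    n_genes: int,
    probes_per_gene: int,
    truth: GroundTruth,
    atrophy_t: np.ndarray,
    range_mm: float = 15.0,
    noise_sd: float = 1.5,
    seed: int = 0,
    gene_names: Sequence[str] | None = None,
) -> ExpressionBundle:
    """Spatially autocorrelated expression with planted atrophy associations.

    Each gene's latent profile is a unit-variance Gaussian-process draw with
    squared-exponential covariance ``exp(-d^2 / (2 range_mm^2))`` over the
    donor's geodesic-surrogate distances, plus white noise of standard
    deviation ``noise_sd``.  For planted genes the latent is mixed with the
    normal scores of the atrophy field's ranks — a monotone transform of the
    atrophy values — with mixing weight ``2 sin(pi rho / 6)`` so that the
    marginal *Spearman* correlation targets ``rho``.  Probes add independent
    noise around their gene's latent, and a probe is flagged "expressed"
    where its value exceeds its own 25th percentile.

    Raises
    ------
    ValueError
        If ``atrophy_t`` does not have one value per sample.
    """
    n = geom.n_samples
    atrophy_t = np.asarray(atrophy_t, dtype=float).ravel()
    if atrophy_t.size != n:
        raise ValueError(f"atrophy_t has {atrophy_t.size} values for {n} samples")
    if gene_names is None:
        gene_names = [f"G{i + 1:05d}" for i in range(n_genes)]
    elif len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")

    rng = np.random.default_rng([seed, truth.seed])
    if range_mm > 0:
        cov = np.exp(-(geom.pairwise_dist**2) / (2.0 * range_mm**2))
        # Squared-exponential over *geodesic* distances need not be positive
        # semi-definite; clip negative eigenvalues and rescale to unit
        # marginal variance.
        evals, evecs = np.linalg.eigh(cov)
        chol = evecs * np.sqrt(np.clip(evals, 0.0, None))
        marg = np.sqrt((chol**2).sum(axis=1))
        chol /= marg[:, None]
    else:
        chol = np.eye(n)
    z_atrophy = _normal_scores(atrophy_t)

    latent = np.empty((n_genes, n))
    for i, gene in enumerate(gene_names):
        gp = chol @ rng.standard_normal(n)
        base = (gp + noise_sd * rng.standard_normal(n)) / np.sqrt(1.0 + noise_sd**2)
        rho = truth.effect_rho.get(gene)
        if rho is None:
            latent[i] = base
        else:
            # Pearson weight reproducing a Spearman of rho for Gaussian pairs.
            a = truth.direction(gene) * 2.0 * np.sin(np.pi * rho / 6.0)
            latent[i] = a * z_atrophy + np.sqrt(1.0 - a * a) * base

    probe_ids, gene_of_probe = [], []
    values = np.empty((n_genes * probes_per_gene, n))
    for i, gene in enumerate(gene_names):
        for j in range(probes_per_gene):
            row = i * probes_per_gene + j
            values[row] = latent[i] + PROBE_NOISE_SD * rng.standard_normal(n)
            probe_ids.append(f"{gene}_p{j + 1}")
            gene_of_probe.append(gene)

    sample_ids = [f"{geom.donor_id}_s{i + 1:04d}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor_id": geom.donor_id,
            "mni_x": geom.coords[:, 0],
            "mni_y": geom.coords[:, 1],
            "mni_z": geom.coords[:, 2],
            "slab_type": "cortex",
            "structure_label": "synthetic cortex",
            "hemisphere": "left",
            "dist_to_cortex_roi": 0.0,
        }
    )
    probes = pd.DataFrame(
        {"probe_id": probe_ids, "gene_symbol": gene_of_probe, "mapping_status": "unique"}
    )
    expression = pd.DataFrame(
        values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids
    )
    thresh = expression.quantile(EXPRESSED_QUANTILE, axis=1)
    expressed = expression.gt(thresh, axis=0)
    return ExpressionBundle(
        donor_id=geom.donor_id,
        samples=samples,
        probes=probes,
        expression=expression,
        expressed=expressed,
        distances=geom.pairwise_dist,
    )


# ---------------------------------------------------------------------------
# atrophy volumes


def generate_atrophy_volume(
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
    focus_center: Sequence[float],
    focus_scale: float,
    peak_t: float,
    map_id: str = "map",
) -> AtrophyVolume:
    """A smooth radial atrophy bump on a voxel grid.

    ``t(v) = peak_t * exp(-||world(v) - focus_center||^2 / (2 focus_scale^2))``
    evaluated at every voxel's world coordinate.
    """
    affine = np.asarray(affine, dtype=float)
    if any(s <= 0 for s in grid_shape):
        raise ValueError("grid_shape must be positive")
    idx = np.indices(grid_shape).reshape(3, -1)
    hom = np.vstack([idx, np.ones(idx.shape[1])])
    world = (affine @ hom)[:3]
    d2 = ((world - np.asarray(focus_center, dtype=float)[:, None]) ** 2).sum(axis=0)
    grid = (peak_t * np.exp(-d2 / (2.0 * focus_scale**2))).reshape(grid_shape)
    return AtrophyVolume(grid=grid, affine=affine, map_id=map_id)


def atrophy_for_geometry(
    geom: DonorGeometry,
    focus_center: Sequence[float] | None = None,
    focus_scale: float = 20.0,
    peak_t: float = 6.0,
    voxel_mm: float = 2.0,
    margin_mm: float = 6.0,
    map_id: str = "map",
) -> tuple[AtrophyVolume, np.ndarray]:
    """Build an atrophy volume covering a geometry and sample it at its points.

    Convenience for end-to-end synthetic runs: the grid spans the geometry's
    bounding box (plus a margin) at ``voxel_mm`` resolution, and the returned
    vector is the nearest-voxel lookup at the sample coordinates — the same
    code path real volumes go through.
    """
    lo = geom.coords.min(axis=0) - margin_mm
    hi = geom.coords.max(axis=0) + margin_mm
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / voxel_mm)) + 1 for i in range(3))
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = lo
    if focus_center is None:
        focus_center = geom.coords.mean(axis=0) + 0.25 * (hi - lo)
    vol = generate_atrophy_volume(shape, affine, focus_center, focus_scale, peak_t, map_id)
    return vol, sample_volume_at(geom.coords, vol)


# ---------------------------------------------------------------------------
# annotation fixtures


def generate_probe_annotation(
    n_total: int,
    n_multi: int,
    n_intergenic: int,
    n_unmapped: int,
    n_genes: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Probe annotation table with exact per-category counts.

    The ``n_total - n_multi - n_intergenic - n_unmapped`` remaining probes
    are uniquely mapped onto exactly ``n_genes`` gene symbols (every gene
    covered by at least one probe).  Rows are shuffled deterministically.
    """
    n_unique = n_total - n_multi - n_intergenic - n_unmapped
    if n_unique < 0:
        raise ValueError("excluded-category counts exceed n_total")
    if n_unique > 0 and not 0 < n_genes <= n_unique:
        raise ValueError(f"need 0 < n_genes <= {n_unique} uniquely mapped probes")
    rng = np.random.default_rng(seed)
    status = np.array(
        ["unique"] * n_unique
        + ["multi_gene"] * n_multi
        + ["intergenic"] * n_intergenic
        + ["unmapped"] * n_unmapped
    )
    genes = np.full(n_total, "", dtype=object)
    if n_unique > 0:
        names = np.array([f"G{i + 1:05d}" for i in range(n_genes)], dtype=object)
        # every gene gets one probe; the surplus is assigned uniformly
        assign = np.concatenate(
            [np.arange(n_genes), rng.integers(0, n_genes, size=n_unique - n_genes)]
        )
        genes[:n_unique] = names[rng.permutation(assign)]
    perm = rng.permutation(n_total)
    return pd.DataFrame(
        {
            "probe_id": [f"P{i + 1:06d}" for i in range(n_total)],
            "mapping_status": status[perm],
            "gene_symbol": genes[perm],
        }
    )


def generate_marker_table(
    n_genes: int,
    cell_types: Sequence[str],
    seed: int = 0,
    markers_per_type: int = 5,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Cell-type mean-expression (FPKM) table with designated marker blocks.

    Returns the genes x cell-types table and the designated markers per
    type.  Designated markers have high FPKM in their target type (>= 3x the
    mean of the other types and > 2.5) and low values elsewhere; remaining
    genes get unstructured log-normal values.

    Raises
    ------
    ValueError
        If ``cell_types`` is empty or the marker blocks do not fit.
    """
    if not cell_types:
        raise ValueError("cell_types must be nonempty")
    if markers_per_type * len(cell_types) > n_genes:
        raise ValueError("marker blocks exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    table = pd.DataFrame(
        rng.lognormal(mean=0.0, sigma=1.0, size=(n_genes, len(cell_types))),
        index=pd.Index(genes, name="gene"),
        columns=list(cell_types),
    )
    designated: dict[str, list[str]] = {}
    row = 0
    for ct in cell_types:
        block = genes[row : row + markers_per_type]
        designated[ct] = block
        table.loc[block, :] = rng.uniform(0.1, 1.0, size=(markers_per_type, len(cell_types)))
        table.loc[block, ct] = rng.uniform(10.0, 40.0, size=markers_per_type)
        row += markers_per_type
    return table, designated


def generate_gene_sets(
    n_sets: int,
    set_sizes: tuple[int, int],
    universe: Sequence[str],
    seed: int = 0,
) -> dict[str, frozenset]:
    """Random gene sets drawn from ``universe`` (sizes uniform in the range)."""
    universe = list(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    lo, hi = set_sizes
    if not 0 < lo <= hi <= len(universe):
        raise ValueError("set sizes must satisfy 0 < lo <= hi <= |universe|")
    rng = np.random.default_rng(seed)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"SET_{i + 1:04d}"] = frozenset(universe[j] for j in members)
    return sets


# ---------------------------------------------------------------------------
# bundle I/O (the file dialect the pipeline reads)


def write_expression_bundle(bundle: ExpressionBundle, directory) -> None:
    """Write a donor bundle as plain CSVs (annotation, probes, values, calls)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.samples.to_csv(d / "SampleAnnot.csv", index=False)
    bundle.probes.to_csv(d / "Probes.csv", index=False)
    bundle.expression.to_csv(d / "Expression.csv", index_label="probe_id")
    bundle.expressed.astype(int).to_csv(d / "PACall.csv", index_label="probe_id")
    if bundle.distances is not None:
        np.savetxt(d / "Distances.csv", bundle.distances, delimiter=",")


def read_expression_bundle(directory) -> ExpressionBundle:
    """Read a donor bundle written by :func:`write_expression_bundle`."""
    d = Path(directory)
    samples = pd.read_csv(d / "SampleAnnot.csv")
    probes = pd.read_csv(d / "Probes.csv")
    expression = pd.read_csv(d / "Expression.csv", index_col="probe_id")
    expressed = pd.read_csv(d / "PACall.csv", index_col="probe_id").astype(bool)
    dist_path = d / "Distances.csv"
    distances = np.loadtxt(dist_path, delimiter=",") if dist_path.exists() else None
    donor = str(samples["donor_id"].iloc[0]) if len(samples) else d.name
    return ExpressionBundle(
        donor_id=donor,
        samples=samples,
        probes=probes,
        expression=expression,
        expressed=expressed,
        distances=distances,
    )
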