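"""Nearest-voxel lookup of statistical brain maps at world-space coordinates.

Atrophy enters the analysis as voxel-wise t-statistic volumes (one per
genetic group) in the same millimetre space as the tissue-sample
coordinates.  Each sample is assigned the value of the voxel containing it:
the world coordinate is mapped through the inverse affine and rounded to the
nearest voxel index — a lookup, not an interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtrophyVolume",
    "sample_volume_at",
    "build_sample_atrophy_table",
]

SAMPLE_COORD_COLUMNS = ("mni_x", "mni_y", "mni_z")


class OutOfBoundsError(ValueError):
    """A world coordinate maps to a voxel index outside the grid."""


@dataclass
class AtrophyVolume:
    """A 3-D statistical map with its voxel-index -> world-mm affine.

    Attributes
    ----------
    grid : (i, j, k) array of t-statistics.
    affine : (4, 4) array mapping homogeneous voxel indices to world mm.
    map_id : label for the map (e.g. the genetic group it contrasts).
    """

    grid: np.ndarray
    affine: np.ndarray
    map_id: str = "map"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @classmethod
    def from_nifti(cls, path, map_id: str | None = None) -> "AtrophyVolume":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        name = map_id if map_id is not None else str(path)
        return cls(grid=data, affine=np.asarray(img.affine), map_id=name)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.grid.astype(np.float32), self.affine), str(path))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # numpy's round() is banker's rounding; the convention here is half away
    # from zero, applied per axis (configurable at the call sites that care).
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def sample_volume_at(
    coords: np.ndarray | Sequence[Sequence[float]],
    vol: AtrophyVolume,
    rounding: str = "half-away",
) -> np.ndarray:
    """Value of the voxel containing each world-space coordinate.

    The voxel index is ``round(affine^-1 @ coord)`` with the rounding
    convention ``"half-away"`` (default, half away from zero) or
    ``"half-even"`` (numpy banker's rounding).

    Raises
    ------
    OutOfBoundsError
        If any rounded index falls outside the grid; the message names the
        offending coordinate.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] != 3:
        raise ValueError("coords must be world 3-vectors")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")

    inv = np.linalg.inv(vol.affine)
    hom = np.hstack([coords, np.ones((coords.shape[0], 1))])
    vox = (inv @ hom.T).T[:, :3]
    if rounding == "half-away":
        idx = _round_half_away(vox).astype(int)
    elif rounding == "half-even":
        idx = np.round(vox).astype(int)
    else:
        raise ValueError(f"unknown rounding convention: {rounding!r}")

    shape = np.array(vol.grid.shape)
    bad = np.any((idx < 0) | (idx >= shape), axis=1)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise OutOfBoundsError(
            f"coordinate {tuple(coords[i])} maps to voxel {tuple(idx[i])} "
            f"outside grid of shape {tuple(shape)} for map {vol.map_id!r}"
        )
    return vol.grid[idx[:, 0], idx[:, 1], idx[:, 2]]


def build_sample_atrophy_table(
    samples: pd.DataFrame,
    volumes: Iterable[AtrophyVolume],
    rounding: str = "half-away",
) -> pd.DataFrame:
    """Link every sample to one t-value per map: a |samples| x |maps| table.

    ``samples`` needs columns ``mni_x, mni_y, mni_z`` (world mm) and is
    indexed by sample id (or carries a ``sample_id`` column).  Out-of-bounds
    coordinates propagate as :class:`OutOfBoundsError`.
    """
    volumes = list(volumes)
    index = (
        pd.Index(samples["sample_id"], name="sample_id")
        if "sample_id" in samples.columns
        else samples.index
    )
    if len(samples) == 0:
        return pd.DataFrame(index=index, columns=[v.map_id for v in volumes], dtype=float)
    coords = samples.loc[:, list(SAMPLE_COORD_COLUMNS)].to_numpy(dtype=float)
    data = {v.map_id: sample_volume_at(coords, v, rounding=rounding) for v in volumes}
    return pd.DataFrame(data, index=index)
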