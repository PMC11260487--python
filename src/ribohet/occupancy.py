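"""Block-occupancy scoring of density volumes against a segmented model.

The occupancy of a block in a volume is the fraction of the block's atoms
whose interpolated, z-normalized density reaches a threshold (default 1.5 sd
above the volume mean). Scoring every block in every volume yields the
volumes × blocks matrix that drives conformational classification.

Volumes are z-normalized per volume, not jointly, so ensembles whose members
carry arbitrary absolute scale (e.g. decoder-generated maps) are comparable.
Atoms that fall outside the grid are counted as unoccupied and tallied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .blocks import BlockLibrary, extract_block_coords
from .errors import DegenerateVolumeError, GeometryError, ValidationError
from .io_formats import AtomicModel, DensityVolume

__all__ = [
    "DEFAULT_THRESHOLD",
    "normalize_volume",
    "trilinear_sample",
    "block_occupancy",
    "occupancy_matrix",
    "save_occupancy_matrix",
    "load_occupancy_matrix",
]

DEFAULT_THRESHOLD = 1.5  # sd units above the per-volume mean

_ID_COLUMNS = ["volume_id", "particle_count"]


def normalize_volume(volume: DensityVolume) -> DensityVolume:
    """Z-normalize densities to zero mean, unit sd over all voxels."""
    sd = float(volume.data.std())
    if sd == 0.0:
        raise DegenerateVolumeError(
            f"volume {volume.label!r} is constant; z-normalization undefined"
        )
    data = (volume.data - volume.data.mean()) / sd
    return DensityVolume(
        data=data.astype(np.float32),
        voxel_size=volume.voxel_size,
        origin=volume.origin,
        label=volume.label,
    )


def trilinear_sample(
    volume: DensityVolume, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of the density at Å coordinates.

    Returns ``(values, outside)`` where ``outside`` marks points beyond the
    grid; their values are NaN sentinels rather than extrapolations.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    origin = np.asarray(volume.origin)
    voxel = np.asarray(volume.voxel_size)
    idx = (points - origin) / voxel  # fractional voxel coordinates
    shape = np.asarray(volume.grid_shape)
    outside = np.any((idx < 0) | (idx > shape - 1), axis=1)
    values = map_coordinates(
        volume.data.astype(float), idx.T, order=1, mode="constant", cval=0.0
    )
    values[outside] = np.nan
    return values, outside


def block_occupancy(
    volume: DensityVolume, coords: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> float:
    """Fraction of atoms whose sampled density >= threshold (sd units).

    Expects a z-normalized volume. Atoms outside the grid count as below
    threshold. Raises for an empty coordinate set, where the fraction is
    undefined.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.shape[0] == 0:
        raise ValidationError("occupancy undefined for an empty coordinate set")
    values, outside = trilinear_sample(volume, coords)
    hit = np.where(outside, False, values >= threshold)
    return float(hit.mean())


def occupancy_matrix(
    volumes: list[DensityVolume],
    model: AtomicModel,
    library: BlockLibrary,
    threshold: float = DEFAULT_THRESHOLD,
    counts: list[int] | None = None,
    normalized: bool = False,
) -> pd.DataFrame:
    """Score every block in every volume.

    Returns a DataFrame with one row per volume: ``volume_id``,
    ``particle_count``, then one column per block in library order.
    ``attrs`` records the threshold and normalization convention.

    All volumes must share grid shape, voxel size and origin; resampling
    belongs upstream.
    """
    if not volumes:
        raise GeometryError("no volumes given")
    ref = volumes[0]
    for v in volumes[1:]:
        if (
            v.grid_shape != ref.grid_shape
            or v.voxel_size != ref.voxel_size
            or v.origin != ref.origin
        ):
            raise GeometryError(
                f"volume {v.label!r} geometry differs from {ref.label!r}"
            )
    if counts is None:
        counts = [1] * len(volumes)
    if len(counts) != len(volumes):
        raise GeometryError("counts must match volumes one-to-one")
    block_coords = [extract_block_coords(model, b) for b in library.blocks]
    rows = []
    for vol, count in zip(volumes, counts):
        nvol = vol if normalized else normalize_volume(vol)
        row: dict[str, object] = {
            "volume_id": vol.label,
            "particle_count": int(count),
        }
        for block, coords in zip(library.blocks, block_coords):
            row[block.name] = (
                np.nan if coords.shape[0] == 0 else block_occupancy(nvol, coords, threshold)
            )
        rows.append(row)
    matrix = pd.DataFrame(rows, columns=_ID_COLUMNS + library.names)
    matrix.attrs["threshold"] = float(threshold)
    matrix.attrs["normalization"] = "per-volume z-score"
    return matrix


def occupancy_values(matrix: pd.DataFrame) -> np.ndarray:
    """The volumes × blocks value array of an occupancy matrix DataFrame."""
    return matrix.drop(columns=_ID_COLUMNS).to_numpy(dtype=float)


def save_occupancy_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=False)


def load_occupancy_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t")
    missing = [c for c in _ID_COLUMNS if c not in matrix.columns]
    if missing:
        raise ValidationError(f"{path}: occupancy table lacks columns {missing}")
    return matrix
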