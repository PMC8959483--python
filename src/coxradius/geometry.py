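"""Signed distance fields and 1-mm annulus labelling around a binary mask.

Distances are exact Euclidean distances in millimetres, honouring
anisotropic voxel spacing, measured voxel-centre to voxel-centre against
the mask *border* (mask voxels with at least one non-mask face
neighbour).  Values are negative strictly inside the mask, zero on the
border, positive outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "SignedDistanceMap",
    "AnnulusLabels",
    "signed_distance_map",
    "annulus_labels",
]

#: label assigned to voxels outside the annulus window
OUT_OF_WINDOW = -1

_ANNULUS_MM = 1.0  # annulus width is fixed at 1 mm


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D voxel lattice with per-axis physical spacing (mm)."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or len(self.spacing) != 3:
            raise ValueError("grid requires 3 dims and 3 spacings")
        if any(d < 1 for d in self.dims):
            raise ValueError("all dims must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be > 0")

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def diagonal_mm(self) -> float:
        """Physical length of the grid diagonal in mm."""
        ext = [d * s for d, s in zip(self.dims, self.spacing)]
        return float(np.sqrt(sum(e * e for e in ext)))

    def check_field(self, arr: np.ndarray, name: str = "field") -> None:
        if tuple(arr.shape) != tuple(self.dims):
            raise ValueError(
                f"{name} shape {arr.shape} does not match grid dims {self.dims}"
            )


@dataclass(frozen=True)
class SignedDistanceMap:
    """Distance (mm) to the nearest mask-border voxel, signed by side."""

    values: np.ndarray
    grid: VoxelGrid
    source_mask_id: str = "mask"

    def __post_init__(self) -> None:
        self.grid.check_field(self.values, "distance map")


@dataclass(frozen=True)
class AnnulusLabels:
    """Integer annulus index per voxel for a half-open radial window.

    Voxel with signed distance ``d`` (mm) in ``[d_min, d_max)`` receives
    label ``floor((d - d_min) / 1 mm)``; everything else gets
    :data:`OUT_OF_WINDOW`.  The window is stored in cm.
    """

    labels: np.ndarray
    grid: VoxelGrid
    window_cm: tuple[float, float]
    sentinel: int = field(default=OUT_OF_WINDOW)

    def __post_init__(self) -> None:
        self.grid.check_field(self.labels, "labels")

    @property
    def n_annuli(self) -> int:
        lo, hi = self.window_cm
        return int(round((hi - lo) * 10.0 / _ANNULUS_MM))

    @property
    def centres_cm(self) -> np.ndarray:
        """Annulus centre distances in cm, one per annulus."""
        lo = self.window_cm[0]
        return lo + (np.arange(self.n_annuli) + 0.5) * (_ANNULUS_MM / 10.0)


def mask_border(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one non-mask face (6-connected) neighbour."""
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def signed_distance_map(
    mask: np.ndarray, grid: VoxelGrid, source_mask_id: str = "mask"
) -> SignedDistanceMap:
    """Exact anisotropic signed Euclidean distance to the mask border.

    Parameters
    ----------
    mask:
        Binary field on ``grid``; must be non-empty and must not fill
        the whole grid.
    grid:
        Voxel lattice providing the physical spacing in mm.

    Returns
    -------
    SignedDistanceMap
        Negative strictly inside the mask, zero on border voxels,
        positive outside.
    """
    mask = np.asarray(mask, dtype=bool)
    grid.check_field(mask, "mask")
    if not mask.any():
        raise ValueError("no tumour: mask is empty")
    if mask.all():
        raise ValueError("no exterior: mask covers the whole grid")

    border = mask_border(mask)
    # EDT gives distance from each voxel to the nearest border voxel,
    # centre-to-centre, scaled by the per-axis spacing.
    dist = ndimage.distance_transform_edt(~border, sampling=grid.spacing)
    values = np.where(mask & ~border, -dist, dist)
    return SignedDistanceMap(values=values, grid=grid, source_mask_id=source_mask_id)


def annulus_labels(
    sdm: SignedDistanceMap, window_cm: tuple[float, float]
) -> AnnulusLabels:
    """Assign 1-mm annulus indices over a half-open radial window.

    ``window_cm`` is ``(d_min, d_max)`` in cm; its width must be a
    positive multiple of 1 mm.  Distances in ``[d_min, d_max)`` map to
    ``floor((d - d_min)/1mm)``; outside the window the sentinel is used.
    """
    lo_cm, hi_cm = window_cm
    if hi_cm <= lo_cm:
        raise ValueError("window must be ordered (d_min < d_max)")
    width_mm = (hi_cm - lo_cm) * 10.0
    if width_mm < _ANNULUS_MM - 1e-9:
        raise ValueError("window width must be at least 1 mm")
    if abs(width_mm - round(width_mm)) > 1e-6:
        raise ValueError("window width must be a multiple of 1 mm")

    lo_mm = lo_cm * 10.0
    hi_mm = hi_cm * 10.0
    d = sdm.values
    inside = (d >= lo_mm) & (d < hi_mm)
    labels = np.full(d.shape, OUT_OF_WINDOW, dtype=np.int32)
    raw = np.floor((d[inside] - lo_mm) / _ANNULUS_MM).astype(np.int32)
    # guard against float round-off pushing d_max-epsilon into a new bin
    np.clip(raw, 0, int(round(width_mm)) - 1, out=raw)
    labels[inside] = raw
    return AnnulusLabels(labels=labels, grid=sdm.grid, window_cm=(lo_cm, hi_cm))
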