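"""Radial cross-histograms: tissue volume per (value bin x 1-mm annulus).

Each in-window voxel that falls inside the restriction mask contributes
its physical volume (mm^3) to the cell addressed by its value bin and
its annulus.  Column sums therefore equal the physical volume of the
restricted annulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .geometry import OUT_OF_WINDOW, AnnulusLabels, VoxelGrid

__all__ = ["RadialHistogram", "build_radial_histogram", "crop_histogram"]


@dataclass(frozen=True)
class RadialHistogram:
    """2D mass table over (value bin, annulus), mass in mm^3.

    ``mass`` has shape ``(n_bins, n_annuli)`` with rows ordered by
    ``value_bin_edges`` and columns by increasing annulus distance over
    ``window_cm``.
    """

    mass: np.ndarray
    value_bin_edges: np.ndarray
    window_cm: tuple[float, float]
    restrict_mask_id: str = "restrict"

    def __post_init__(self) -> None:
        if self.mass.ndim != 2:
            raise ValueError("mass must be 2D (bins x annuli)")
        if len(self.value_bin_edges) != self.mass.shape[0] + 1:
            raise ValueError("value_bin_edges must have n_bins + 1 entries")

    @property
    def n_annuli(self) -> int:
        return self.mass.shape[1]

    @property
    def bin_centres(self) -> np.ndarray:
        edges = np.asarray(self.value_bin_edges, dtype=float)
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def annulus_centres_cm(self) -> np.ndarray:
        lo = self.window_cm[0]
        return lo + (np.arange(self.n_annuli) + 0.5) * 0.1

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    def column(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(mass, bin_centres)`` for annulus ``j``."""
        return self.mass[:, j], self.bin_centres


def build_radial_histogram(
    image: np.ndarray,
    labels: AnnulusLabels,
    restrict: np.ndarray,
    value_bin_edges: np.ndarray,
    grid: VoxelGrid,
    restrict_mask_id: str = "restrict",
) -> RadialHistogram:
    """Tally voxel volume into (value bin, annulus) cells.

    Values outside the bin-edge range are clamped into the end bins.
    An empty restrict-window intersection produces an all-zero table
    with a warning.
    """
    image = np.asarray(image, dtype=float)
    restrict = np.asarray(restrict, dtype=bool)
    grid.check_field(image, "image")
    grid.check_field(restrict, "restrict mask")
    if tuple(labels.labels.shape) != tuple(grid.dims):
        raise ValueError("labels grid does not match image grid")
    edges = np.asarray(value_bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("need at least 2 value bin edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("value bin edges must be strictly increasing")

    n_bins = edges.size - 1
    n_ann = labels.n_annuli
    sel = (labels.labels != labels.sentinel) & restrict
    mass = np.zeros((n_bins, n_ann), dtype=float)
    if not sel.any():
        warnings.warn(
            "restriction mask is empty inside the radial window; "
            "histogram is all zero",
            stacklevel=2,
        )
        return RadialHistogram(mass, edges, labels.window_cm, restrict_mask_id)

    vals = image[sel]
    ann = labels.labels[sel].astype(np.int64)
    # half-open bins [e_k, e_{k+1}); out-of-range values clamp to end bins
    bins = np.searchsorted(edges, vals, side="right") - 1
    np.clip(bins, 0, n_bins - 1, out=bins)
    flat = np.bincount(ann * n_bins + bins, minlength=n_ann * n_bins)
    mass = flat.reshape(n_ann, n_bins).T.astype(float) * grid.voxel_volume
    return RadialHistogram(mass, edges, labels.window_cm, restrict_mask_id)


def crop_histogram(
    h: RadialHistogram, window_cm: tuple[float, float]
) -> RadialHistogram:
    """Drop annulus columns outside ``window_cm`` (must nest in ``h.window_cm``)."""
    lo, hi = window_cm
    if hi <= lo:
        raise ValueError("crop window must be ordered")
    cur_lo, cur_hi = h.window_cm
    if lo < cur_lo - 1e-9 or hi > cur_hi + 1e-9:
        raise ValueError(
            f"crop window {window_cm} outside histogram window {h.window_cm}"
        )
    start = int(round((lo - cur_lo) * 10.0))
    count = int(round((hi - lo) * 10.0))
    if count < 1:
        raise ValueError("crop window narrower than one annulus")
    return replace(
        h, mass=h.mass[:, start : start + count], window_cm=(lo, hi)
    )
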