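"""Post-processing of significance maps into candidate rectangular regions.

Pipeline: threshold -> 8-connected components -> iterative removal of
thin rows/columns -> mean-extent box -> size screen.  A separate
near-zero-variance screen rejects regions whose extracted per-patient
values are effectively constant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import measure

from .cox import InteractionMap

__all__ = [
    "MapRegion",
    "significant_cells",
    "connected_regions",
    "prune_thin",
    "box_and_screen",
    "near_zero_variance",
    "postprocess_map",
]

MIN_THICKNESS_CELLS = 3  # 1 cell = 1 mm on both map axes
MIN_BOX_MM = 3.0


@dataclass(frozen=True)
class MapRegion:
    """A connected set of significant map cells plus its derived box.

    ``cells`` is an (k, 2) array of (density index, dose index) pairs.
    ``box_density_cm``/``box_dose_cm`` are closed intervals centred on
    the pruned region's centroid with the mean row/column extents as
    side lengths.
    """

    cells: np.ndarray
    density_window_cm: tuple[float, float]
    dose_window_cm: tuple[float, float]
    status: str = "raw"
    box_density_cm: tuple[float, float] | None = None
    box_dose_cm: tuple[float, float] | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(len(self.cells))

    def to_grid(self, shape: tuple[int, int]) -> np.ndarray:
        grid = np.zeros(shape, dtype=bool)
        if self.n_cells:
            grid[self.cells[:, 0], self.cells[:, 1]] = True
        return grid


def significant_cells(imap: InteractionMap, alpha: float = 0.05) -> np.ndarray:
    """Boolean grid of non-missing cells with p < alpha."""
    p = imap.p_values
    return np.isfinite(p) & (p < alpha)


def connected_regions(
    binary: np.ndarray,
    density_window_cm: tuple[float, float] = (0.0, 0.0),
    dose_window_cm: tuple[float, float] = (0.0, 0.0),
) -> list[MapRegion]:
    """8-connected components of a significance grid, as raw regions."""
    labelled = measure.label(np.asarray(binary, dtype=bool), connectivity=2)
    regions = []
    for lab in range(1, labelled.max() + 1):
        cells = np.argwhere(labelled == lab)
        regions.append(
            MapRegion(
                cells=cells,
                density_window_cm=density_window_cm,
                dose_window_cm=dose_window_cm,
                status="raw",
            )
        )
    return regions


def _max_run(line: np.ndarray) -> int:
    """Longest contiguous run of True in a 1D boolean array."""
    best = run = 0
    for v in line:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def prune_thin(
    region: MapRegion,
    grid_shape: tuple[int, int],
    min_thickness: int = MIN_THICKNESS_CELLS,
) -> MapRegion:
    """Iteratively delete rows/columns whose longest cell run is too short.

    A row (density index) or column (dose index) of the region is
    removed when its maximal contiguous run of region cells is below
    ``min_thickness``; removal repeats until stable.  May empty the
    region.
    """
    grid = region.to_grid(grid_shape)
    while True:
        rows = np.flatnonzero(grid.any(axis=1))
        cols = np.flatnonzero(grid.any(axis=0))
        drop_rows = [r for r in rows if _max_run(grid[r, :]) < min_thickness]
        drop_cols = [c for c in cols if _max_run(grid[:, c]) < min_thickness]
        if not drop_rows and not drop_cols:
            break
        grid[drop_rows, :] = False
        grid[:, drop_cols] = False
    return replace(region, cells=np.argwhere(grid), status="pruned")


def box_and_screen(region: MapRegion, min_box_mm: float = MIN_BOX_MM) -> MapRegion:
    """Average the pruned region into a centred box; reject if too small.

    Box centre is the cell centroid; the side along the density axis is
    the mean span of occupied dose-columns, and along the dose axis the
    mean span of occupied density-rows (occupied rows/columns only).
    Either side below ``min_box_mm`` rejects the region.
    """
    if region.n_cells == 0:
        return replace(region, status="rejected_size")
    cells = region.cells
    centroid = cells.mean(axis=0)  # (density idx, dose idx)

    rows = np.unique(cells[:, 0])
    cols = np.unique(cells[:, 1])
    # span of the region within each occupied row/column, in cells (= mm)
    row_spans = [
        cells[cells[:, 0] == r, 1].max() - cells[cells[:, 0] == r, 1].min() + 1
        for r in rows
    ]
    col_spans = [
        cells[cells[:, 1] == c, 0].max() - cells[cells[:, 1] == c, 0].min() + 1
        for c in cols
    ]
    density_extent_mm = float(np.mean(col_spans))  # extent along density axis
    dose_extent_mm = float(np.mean(row_spans))  # extent along dose axis

    d_lo = region.density_window_cm[0]
    z_lo = region.dose_window_cm[0]
    centre_density_cm = d_lo + (centroid[0] + 0.5) * 0.1
    centre_dose_cm = z_lo + (centroid[1] + 0.5) * 0.1
    # the box cannot exceed the map window (values only exist inside it)
    box_density = (
        max(centre_density_cm - density_extent_mm / 20.0, d_lo),
        min(centre_density_cm + density_extent_mm / 20.0,
            region.density_window_cm[1]),
    )
    box_dose = (
        max(centre_dose_cm - dose_extent_mm / 20.0, z_lo),
        min(centre_dose_cm + dose_extent_mm / 20.0, region.dose_window_cm[1]),
    )
    status = (
        "rejected_size"
        if density_extent_mm < min_box_mm or dose_extent_mm < min_box_mm
        else "boxed"
    )
    return replace(
        region,
        status=status,
        box_density_cm=box_density,
        box_dose_cm=box_dose,
        diagnostics={
            **region.diagnostics,
            "density_extent_mm": density_extent_mm,
            "dose_extent_mm": dose_extent_mm,
        },
    )


def near_zero_variance(
    values: np.ndarray,
    granularity: float,
    unique_cut: float = 0.10,
    freq_cut: float = 19.0,
) -> bool:
    """True when values are effectively constant after rounding.

    Values are rounded to ``granularity``; the flag is raised when the
    fraction of unique values is below ``unique_cut`` AND the ratio of
    the most common to second most common value exceeds ``freq_cut``.
    Identical values always raise the flag (infinite ratio).
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("near-zero-variance screen needs at least 2 values")
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    rounded = np.round(vals / granularity) * granularity
    counts = Counter(rounded.tolist())
    if len(counts) == 1:
        return True
    unique_fraction = len(counts) / vals.size
    top = counts.most_common(2)
    ratio = top[0][1] / top[1][1]
    return (unique_fraction < unique_cut) and (ratio > freq_cut)


def postprocess_map(
    imap: InteractionMap,
    alpha: float = 0.05,
    min_thickness: int = MIN_THICKNESS_CELLS,
    min_box_mm: float = MIN_BOX_MM,
) -> list[MapRegion]:
    """Threshold, label, prune and box one map; returns all regions with status."""
    binary = significant_cells(imap, alpha=alpha)
    regions = connected_regions(
        binary, imap.density_window_cm, imap.dose_window_cm
    )
    out = []
    for region in regions:
        pruned = prune_thin(region, binary.shape, min_thickness=min_thickness)
        out.append(box_and_screen(pruned, min_box_mm=min_box_mm))
    return out
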