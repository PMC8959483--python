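import numpy as np
import pytest

from coxradius.config import RunConfig
from coxradius.geometry import VoxelGrid
from coxradius.simulate import CohortConfig


@pytest.fixture
def iso_grid():
    return VoxelGrid((9, 9, 9), (1.0, 1.0, 1.0))


@pytest.fixture
def aniso_grid():
    return VoxelGrid((13, 13, 5), (1.0, 1.0, 3.0))


@pytest.fixture
def fast_run_config():
    """Reduced windows and coarse bins for statistically meaningful but
    quick cohort-level tests."""
    return RunConfig(
        density_window_cm=(-0.5, 0.5),
        dose_window_cm=(2.5, 3.5),
        density_bins=(-1024.0, 200.0, 4.0),
        dose_bins=(0.0, 150.0, 0.5),
        density_stats=("mean",),
        dose_stats=("dose_sd",),
        min_events_per_cell=10,
    )


@pytest.fixture
def fast_cohort_config():
    return CohortConfig(
        n_patients=60,
        seed=0,
        grid_dims=(48, 48, 24),
        spacing_mm=(2.0, 2.0, 3.0),
        n_phases=1,
    )


def brute_force_signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Exhaustive all-pairs distance to the 6-connected mask border.

    Independent oracle: O(n^2) loop over voxels x border voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    sp = np.asarray(spacing, dtype=float)
    border = []
    dims = mask.shape
    for idx in np.argwhere(mask):
        i, j, k = idx
        is_border = False
        for axis, delta in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
            nb = idx.copy()
            nb[axis] += delta
            if (nb < 0).any() or (nb >= dims).any() or not mask[tuple(nb)]:
                is_border = True
                break
        if is_border:
            border.append(idx)
    border = np.asarray(border, dtype=float)
    out = np.empty(mask.shape)
    for idx in np.ndindex(mask.shape):
        diffs = (border - np.asarray(idx, dtype=float)) * sp
        dist = np.sqrt((diffs**2).sum(axis=1)).min()
        inside = mask[idx] and not any(
            np.array_equal(b, np.asarray(idx, dtype=float)) for b in border
        )
        out[idx] = -dist if inside else dist
    return out
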