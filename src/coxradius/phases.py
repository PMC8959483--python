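"""Optimal respiratory-phase selection by structural similarity of histograms.

Each phase's cropped radial histogram is compared to its cyclic
neighbours with a mean structural similarity index; the phase maximising
the summed neighbour similarity wins (ties break to the lowest index).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .histograms import RadialHistogram

__all__ = ["PhaseScore", "ssim", "phase_scores", "select_optimal_phase"]

# canonical SSIM constants: 11-tap Gaussian window (sigma 1.5, truncate 3.5)
_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5
_K1 = 0.01
_K2 = 0.03


@dataclass(frozen=True)
class PhaseScore:
    phase_index: int
    ssim_prev: float
    ssim_next: float

    @property
    def ssim_total(self) -> float:
        return self.ssim_prev + self.ssim_next


def _ssim_mean(x: np.ndarray, y: np.ndarray, data_range: float) -> float:
    """Mean SSIM over local Gaussian-weighted windows (reflect boundary)."""
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2

    def g(a: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(
            a, sigma=_SSIM_SIGMA, truncate=_SSIM_TRUNCATE, mode="reflect"
        )

    mu_x, mu_y = g(x), g(y)
    var_x = g(x * x) - mu_x * mu_x
    var_y = g(y * y) - mu_y * mu_y
    cov = g(x * y) - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x * mu_x + mu_y * mu_y + c1) * (var_x + var_y + c2)
    return float(np.mean(num / den))


def ssim(a: RadialHistogram, b: RadialHistogram) -> float:
    """Mean structural similarity of two radial histograms in [0, 1].

    The tables are jointly min-max normalised (so the SSIM data range is
    well defined) before applying the standard formula with an 11-point
    Gaussian window and constants K1=0.01, K2=0.03.  Identical inputs
    score exactly 1.
    """
    if a.mass.shape != b.mass.shape:
        raise ValueError("histograms must share one shape")
    if not np.array_equal(a.value_bin_edges, b.value_bin_edges):
        raise ValueError("histograms must share value bin edges")
    x = np.asarray(a.mass, dtype=float)
    y = np.asarray(b.mass, dtype=float)
    if np.array_equal(x, y):
        return 1.0
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if hi <= lo:  # both constant and equal was handled above
        return 1.0
    x = (x - lo) / (hi - lo)
    y = (y - lo) / (hi - lo)
    value = _ssim_mean(x, y, data_range=1.0)
    # reported on the 0..1 scale
    return float(np.clip(value, 0.0, 1.0))


def phase_scores(histograms: Sequence[RadialHistogram]) -> list[PhaseScore]:
    """Score every phase against its cyclic neighbours."""
    n = len(histograms)
    if n < 3:
        raise ValueError("phase selection requires at least 3 phases")
    scores = []
    for p in range(n):
        prev_h = histograms[(p - 1) % n]
        next_h = histograms[(p + 1) % n]
        scores.append(
            PhaseScore(
                phase_index=p,
                ssim_prev=ssim(histograms[p], prev_h),
                ssim_next=ssim(histograms[p], next_h),
            )
        )
    return scores


def select_optimal_phase(histograms: Sequence[RadialHistogram]) -> PhaseScore:
    """Return the phase with maximal summed neighbour SSIM.

    Ties break to the lowest phase index.
    """
    scores = phase_scores(histograms)
    best = max(scores, key=lambda s: (s.ssim_total, -s.phase_index))
    return best
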