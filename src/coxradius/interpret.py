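"""Interpretation aids: contrast curves, rank-correlation confounding checks,
and grouped mean curves."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFit
from .curves import SummaryCurve

__all__ = [
    "ContrastCurve",
    "contrast_curve",
    "spearman",
    "confounding_report",
    "group_mean_curves",
]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class ContrastCurve:
    """ln(hazard ratio) vs density at a fixed dose level, relative to the
    cohort mean density (where ln(HR) is exactly 0)."""

    density_grid: np.ndarray
    dose_level: str
    dose_value: float
    ln_hr: np.ndarray
    ci_lo: np.ndarray | None
    ci_hi: np.ndarray | None


def contrast_curve(
    fit: CoxFit,
    density_grid: np.ndarray,
    dose_value: float,
    density_mean: float,
    dose_level: str = "median",
    density_name: str = "density",
    interaction_name: str = "density_x_dose",
) -> ContrastCurve:
    """ln(HR) = (b2 + b3*dose) * (density - mean) with delta-method 95% CI.

    Pointwise variance is
    ``(density - mean)^2 * [var(b2) + dose^2 var(b3) + 2 dose cov(b2,b3)]``.
    """
    grid = np.asarray(density_grid, dtype=float)
    b2 = fit.coef(density_name)
    b3 = fit.coef(interaction_name)
    delta = grid - density_mean
    ln_hr = (b2 + b3 * dose_value) * delta
    try:
        var = (
            fit.var(density_name)
            + dose_value**2 * fit.var(interaction_name)
            + 2.0 * dose_value * fit.covariance(density_name, interaction_name)
        )
        sd = np.abs(delta) * np.sqrt(max(var, 0.0))
        ci_lo, ci_hi = ln_hr - Z95 * sd, ln_hr + Z95 * sd
    except (ValueError, IndexError):
        warnings.warn("coefficient covariance missing; CI omitted", stacklevel=2)
        ci_lo = ci_hi = None
    return ContrastCurve(
        density_grid=grid,
        dose_level=dose_level,
        dose_value=float(dose_value),
        ln_hr=ln_hr,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
    )


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs at least 3 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def confounding_report(
    region_values: Mapping[str, Mapping[str, np.ndarray]],
    tumour_volume: np.ndarray,
    motion_amplitude: np.ndarray,
    mean_gtv_dose: np.ndarray,
) -> pd.DataFrame:
    """Spearman rho of each region's metrics against the usual confounders.

    ``region_values`` maps region name -> {"density": values, "dose": values}.
    Dose metrics are checked against mean GTV dose, motion, and volume;
    density metrics against volume and motion.
    """
    rows = []
    for name, vals in region_values.items():
        dose_v = np.asarray(vals["dose"], dtype=float)
        dens_v = np.asarray(vals["density"], dtype=float)
        rows.append(
            {
                "region": name,
                "dose_vs_mean_gtv_dose": spearman(dose_v, mean_gtv_dose),
                "dose_vs_motion": spearman(dose_v, motion_amplitude),
                "dose_vs_volume": spearman(dose_v, tumour_volume),
                "density_vs_volume": spearman(dens_v, tumour_volume),
                "density_vs_motion": spearman(dens_v, motion_amplitude),
            }
        )
    return pd.DataFrame(rows).set_index("region")


def group_mean_curves(
    curves: Sequence[SummaryCurve], groups: Sequence[str]
) -> pd.DataFrame:
    """Pointwise per-group mean curve with a normal-approximation 95% CI.

    Singleton groups get a mean without a CI.  Returns long-format rows
    (group, distance_cm, mean, ci_lo, ci_hi, n).
    """
    if len(curves) != len(groups):
        raise ValueError("one group label per curve required")
    rows = []
    for g in sorted(set(groups)):
        members = [c for c, gg in zip(curves, groups) if gg == g]
        dist = members[0].distances_cm
        vals = np.stack([np.where(c.valid, c.values, np.nan) for c in members])
        for j, d in enumerate(dist):
            col = vals[:, j]
            col = col[np.isfinite(col)]
            if col.size == 0:
                continue
            mean = float(col.mean())
            if col.size > 1:
                sem = float(col.std(ddof=1) / np.sqrt(col.size))
                lo, hi = mean - Z95 * sem, mean + Z95 * sem
            else:
                lo = hi = float("nan")
            rows.append(
                {
                    "group": g,
                    "distance_cm": float(d),
                    "mean": mean,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "n": int(col.size),
                }
            )
    return pd.DataFrame(rows)
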