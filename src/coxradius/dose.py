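"""Dose-field preparation and per-annulus dose metrics.

Covers motion blurring of the planned dose, conversion to EQD2 under
the linear-quadratic iso-effect model, and the three annulus summaries:
mass-weighted SD, generalised (power) mean, and fraction of volume
below a dose threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .geometry import VoxelGrid
from .histograms import RadialHistogram

__all__ = [
    "DoseField",
    "MotionModel",
    "blur_dose_for_motion",
    "to_eqd2",
    "generalised_mean",
    "sd_dose",
    "fraction_below",
    "exponent_diagnostic",
]


@dataclass(frozen=True)
class DoseField:
    """A scalar dose field (Gy) plus its fractionation bookkeeping."""

    values: np.ndarray
    grid: VoxelGrid
    kind: str = "physical"  # "physical" or "eqd2"
    n_fractions: int = 5
    alpha_beta: float = 10.0

    def __post_init__(self) -> None:
        self.grid.check_field(self.values, "dose")
        if self.kind not in ("physical", "eqd2"):
            raise ValueError("kind must be 'physical' or 'eqd2'")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")


@dataclass(frozen=True)
class MotionModel:
    """Per-phase rigid translations (mm) relative to the reference phase."""

    translations: np.ndarray  # (n_phases, 3) mm
    weights: np.ndarray | None = None
    reference_phase: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.translations, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("translations must be (n_phases, 3)")
        if not np.allclose(t[self.reference_phase], 0.0, atol=1e-9):
            raise ValueError("reference phase translation must be zero")

    @property
    def n_phases(self) -> int:
        return np.asarray(self.translations).shape[0]

    def normalised_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.n_phases, 1.0 / self.n_phases)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.n_phases,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        return w / w.sum()


def blur_dose_for_motion(dose: DoseField, motion: MotionModel) -> DoseField:
    """Motion-blur a physical dose by weight-averaged translated resampling.

    Output voxel value is ``sum_p w_p * dose(x + t_p)`` with trilinear
    interpolation; samples outside the grid take the nearest in-grid
    value.
    """
    if dose.kind != "physical":
        raise ValueError("blur must be applied to the physical dose")
    t = np.asarray(motion.translations, dtype=float)
    w = motion.normalised_weights()
    if np.allclose(t, 0.0):
        return dose
    spacing = np.asarray(dose.grid.spacing, dtype=float)
    idx = np.indices(dose.grid.dims, dtype=float)
    out = np.zeros(dose.grid.dims, dtype=float)
    for p in range(motion.n_phases):
        shift_vox = t[p] / spacing
        coords = [idx[ax] + shift_vox[ax] for ax in range(3)]
        out += w[p] * ndimage.map_coordinates(
            dose.values, coords, order=1, mode="nearest"
        )
    out = np.maximum(out, 0.0)
    return DoseField(out, dose.grid, "physical", dose.n_fractions, dose.alpha_beta)


def to_eqd2(dose: DoseField) -> DoseField:
    """Convert total physical dose to EQD2 per voxel.

    With per-fraction dose ``d = D / n``:  ``EQD2 = D * (d + a/b) / (2 + a/b)``.
    Identity exactly at 2 Gy per fraction.
    """
    if dose.kind != "physical":
        raise ValueError("dose already converted")
    if dose.n_fractions <= 0:
        raise ValueError("n_fractions must be positive")
    if dose.alpha_beta <= 0:
        raise ValueError("alpha_beta must be positive")
    d = dose.values / dose.n_fractions
    eqd2 = dose.values * (d + dose.alpha_beta) / (2.0 + dose.alpha_beta)
    return DoseField(eqd2, dose.grid, "eqd2", dose.n_fractions, dose.alpha_beta)


def _column_weights(mass: np.ndarray, centres: np.ndarray):
    mass = np.asarray(mass, dtype=float)
    centres = np.asarray(centres, dtype=float)
    total = mass.sum()
    if total <= 0:
        return None, None
    keep = mass > 0
    return mass[keep] / total, centres[keep]


def generalised_mean(mass: np.ndarray, centres: np.ndarray, a: float) -> float:
    """Power mean ``(sum v_i D_i^a)^(1/a)`` with mass-normalised weights.

    Returns NaN for an empty annulus.  Negative exponents require
    strictly positive doses wherever mass is present.
    """
    if a == 0:
        raise ValueError("exponent a must be non-zero")
    v, d = _column_weights(mass, centres)
    if v is None:
        return float("nan")
    if a < 0 and np.any(d <= 0):
        raise ValueError("generalised mean undefined for non-positive dose at a < 0")
    # work in log space for robustness at large |a|
    if np.any(d <= 0):
        return float(np.sum(v * d**a) ** (1.0 / a))
    logs = a * np.log(d)
    m = logs.max()
    return float(np.exp((m + np.log(np.sum(v * np.exp(logs - m)))) / a))


def sd_dose(mass: np.ndarray, centres: np.ndarray) -> float:
    """Mass-weighted standard deviation of dose over bin centres (NaN if empty)."""
    v, d = _column_weights(mass, centres)
    if v is None:
        return float("nan")
    mean = np.sum(v * d)
    return float(np.sqrt(np.sum(v * (d - mean) ** 2)))


def fraction_below(
    mass: np.ndarray, centres: np.ndarray, threshold: float = 30.0
) -> float:
    """Mass fraction in bins whose centre is below ``threshold`` (NaN if empty)."""
    v, d = _column_weights(mass, centres)
    if v is None:
        return float("nan")
    return float(np.sum(v[d < threshold]))


def exponent_diagnostic(
    annulus_columns: list[tuple[np.ndarray, np.ndarray]],
    a_candidates: tuple[int, ...] = (-1, -2, -3, -4, -5),
    skew_bound: float = 3.0,
) -> pd.DataFrame:
    """Cohort skewness of the generalised mean for candidate exponents.

    ``annulus_columns`` holds one ``(mass, centres)`` dose-annulus
    column per patient.  Returns one row per candidate exponent with the
    adjusted Fisher-Pearson sample skewness of the cohort's generalised
    means; the recommended exponent is the most negative one whose
    |skewness| stays within ``skew_bound``.
    """
    if len(annulus_columns) < 3:
        raise ValueError("diagnostic requires at least 3 patients")
    rows = []
    for a in a_candidates:
        vals = np.array(
            [generalised_mean(m, c, a) for m, c in annulus_columns], dtype=float
        )
        vals = vals[np.isfinite(vals)]
        if vals.size < 3 or np.allclose(vals, vals[0]):
            skew = 0.0
            degenerate = True
        else:
            skew = float(stats.skew(vals, bias=False))
            degenerate = False
        rows.append({"a": a, "skewness": skew, "degenerate": degenerate})
    table = pd.DataFrame(rows)
    ok = table[np.abs(table["skewness"]) <= skew_bound]
    recommended = int(ok["a"].min()) if len(ok) else int(max(a_candidates))
    table.attrs["recommended_a"] = recommended
    return table


_DOSE_STATS = {
    "dose_sd": lambda m, c, cfg: sd_dose(m, c),
    "gen_mean": lambda m, c, cfg: generalised_mean(m, c, cfg.get("a", -3)),
    "fraction_below": lambda m, c, cfg: fraction_below(
        m, c, cfg.get("threshold", 30.0)
    ),
}


def dose_curve(h: RadialHistogram, statistic: str, **cfg):
    """Per-annulus dose summary as a :class:`~coxradius.curves.SummaryCurve`."""
    from .curves import SummaryCurve

    if statistic not in _DOSE_STATS:
        raise ValueError(f"unknown dose statistic {statistic!r}")
    fn = _DOSE_STATS[statistic]
    centres = h.bin_centres
    values = np.array([fn(h.mass[:, j], centres, cfg) for j in range(h.n_annuli)])
    valid = np.isfinite(values)
    return SummaryCurve(
        statistic=statistic,
        distances_cm=h.annulus_centres_cm,
        values=np.where(valid, values, np.nan),
        valid=valid,
    )
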