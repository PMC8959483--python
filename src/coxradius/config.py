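"""Run configuration with the published default parameter set."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig"]


def _hu_edges(width: float = 1.0, lo: float = -1024.0, hi: float = 3071.0):
    return (float(lo), float(hi), float(width))


@dataclass
class RunConfig:
    """All tunables of the radial mapping workflow, with literature defaults.

    Windows are in cm, smoothing and box sizes in mm, doses in Gy.
    """

    density_window_cm: tuple[float, float] = (-0.5, 2.0)
    dose_window_cm: tuple[float, float] = (0.5, 4.0)
    smoothing_sigma_mm: float = 1.5
    alpha_beta: float = 10.0
    dose_threshold_gy: float = 30.0
    gen_mean_a: int = -3
    alpha: float = 0.05
    min_thickness_mm: int = 3
    min_box_mm: float = 3.0
    nzv_unique_cut: float = 0.10
    nzv_freq_cut: float = 19.0
    n_bootstrap: int = 500
    skew_bound: float = 3.0
    min_events_per_cell: int = 10
    availability_threshold: float = 0.90
    seed: int = 0

    density_stats: tuple[str, ...] = ("mean", "sd", "p90")
    dose_stats: tuple[str, ...] = ("dose_sd", "gen_mean", "fraction_below")

    # (lo, hi, bin width): 1-HU density bins, 0.1-Gy EQD2 dose bins
    density_bins: tuple[float, float, float] = (-1024.0, 3071.0, 1.0)
    dose_bins: tuple[float, float, float] = (0.0, 200.0, 0.1)

    covariates: tuple[str, ...] = (
        "age",
        "sex",
        "volume_cc",
        "lobe_upper",
        "motion_amplitude",
    )

    def density_bin_edges(self) -> np.ndarray:
        lo, hi, w = self.density_bins
        return np.arange(lo, hi + w / 2, w)

    def dose_bin_edges(self) -> np.ndarray:
        lo, hi, w = self.dose_bins
        return np.arange(lo, hi + w / 2, w)

    @property
    def n_density_annuli(self) -> int:
        lo, hi = self.density_window_cm
        return int(round((hi - lo) * 10))

    @property
    def n_dose_annuli(self) -> int:
        lo, hi = self.dose_window_cm
        return int(round((hi - lo) * 10))

    @property
    def metric_pairs(self) -> list[tuple[str, str]]:
        return [(d, z) for d in self.density_stats for z in self.dose_stats]

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, tuple):
                out[key] = list(value)
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                value = data[f.name]
                if isinstance(value, list):
                    value = tuple(value)
                kwargs[f.name] = value
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
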