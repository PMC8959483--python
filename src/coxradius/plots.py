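"""Matplotlib renderings: significance heatmaps and contrast fans."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cox import InteractionMap
from .interpret import ContrastCurve

__all__ = ["plot_map", "plot_contrast_fan"]


def plot_map(imap: InteractionMap, path: str | Path, alpha: float = 0.05) -> None:
    """Heatmap of -log10(p) with significant cells circled."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    with np.errstate(divide="ignore"):
        img = -np.log10(imap.p_values)
    extent = [
        imap.dose_window_cm[0],
        imap.dose_window_cm[1],
        imap.density_window_cm[0],
        imap.density_window_cm[1],
    ]
    im = ax.imshow(
        img, origin="lower", aspect="auto", extent=extent, cmap="viridis"
    )
    sig = np.argwhere(np.isfinite(imap.p_values) & (imap.p_values < alpha))
    if sig.size:
        ax.scatter(
            imap.dose_centres_cm[sig[:, 1]],
            imap.density_centres_cm[sig[:, 0]],
            s=12,
            facecolors="none",
            edgecolors="white",
            linewidths=0.6,
        )
    ax.set_xlabel("dose distance from mask border (cm)")
    ax.set_ylabel("density distance from mask border (cm)")
    ax.set_title(f"{imap.metric_pair[0]} x {imap.metric_pair[1]}")
    fig.colorbar(im, ax=ax, label="-log10 p (LR test)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_contrast_fan(
    curves: Sequence[ContrastCurve], path: str | Path, density_label: str = "density"
) -> None:
    """ln(HR) vs density at each dose level, with CIs when available."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for curve in curves:
        (line,) = ax.plot(
            curve.density_grid,
            curve.ln_hr,
            label=f"dose {curve.dose_level} ({curve.dose_value:.2g})",
        )
        if curve.ci_lo is not None:
            ax.fill_between(
                curve.density_grid,
                curve.ci_lo,
                curve.ci_hi,
                color=line.get_color(),
                alpha=0.15,
                linewidth=0,
            )
    ax.axhline(0.0, color="k", linewidth=0.8)
    ax.set_xlabel(density_label)
    ax.set_ylabel("ln(hazard ratio) vs cohort mean")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
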