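"""Standard-format I/O: NIfTI volumes, curve/map CSVs, region JSON."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cox import InteractionMap
from .curves import SummaryCurve
from .geometry import VoxelGrid

__all__ = [
    "save_volume",
    "load_volume",
    "curves_to_frame",
    "save_map",
    "load_map",
]


def save_volume(path: str | Path, values: np.ndarray, grid: VoxelGrid) -> None:
    affine = np.diag([*grid.spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, VoxelGrid(tuple(data.shape), spacing)


def curves_to_frame(curves: dict[str, SummaryCurve]) -> pd.DataFrame:
    """Long-format table (patient_id, statistic, distance_cm, value, valid)."""
    rows = []
    for pid, c in curves.items():
        for d, v, ok in zip(c.distances_cm, c.values, c.valid):
            rows.append(
                {
                    "patient_id": pid,
                    "statistic": c.statistic,
                    "distance_cm": float(d),
                    "value": float(v) if np.isfinite(v) else np.nan,
                    "valid": bool(ok),
                }
            )
    return pd.DataFrame(rows)


def save_map(imap: InteractionMap, csv_path: str | Path) -> None:
    """CSV matrix with distance headers plus a JSON sidecar of metadata."""
    csv_path = Path(csv_path)
    frame = pd.DataFrame(
        imap.p_values,
        index=[f"{d:.2f}" for d in imap.density_centres_cm],
        columns=[f"{d:.2f}" for d in imap.dose_centres_cm],
    )
    frame.index.name = "density_cm\\dose_cm"
    frame.to_csv(csv_path)
    sidecar = {
        "metric_pair": list(imap.metric_pair),
        "density_window_cm": list(imap.density_window_cm),
        "dose_window_cm": list(imap.dose_window_cm),
        "n_used": imap.n_used.tolist(),
        "n_events_used": imap.n_events_used.tolist(),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_map(csv_path: str | Path) -> InteractionMap:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path, index_col=0)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return InteractionMap(
        p_values=frame.to_numpy(dtype=float),
        n_used=np.asarray(meta["n_used"], dtype=int),
        n_events_used=np.asarray(meta["n_events_used"], dtype=int),
        metric_pair=tuple(meta["metric_pair"]),
        density_window_cm=tuple(meta["density_window_cm"]),
        dose_window_cm=tuple(meta["dose_window_cm"]),
    )
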