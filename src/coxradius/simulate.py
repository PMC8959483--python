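"""Synthetic cohort generator with a planted density-dose interaction.

Each patient gets phased CT-like volumes, masks, a SABR-like dose field
and rigid motion; survival times carry a proportional-hazards signal in
which a density statistic at one radial location interacts with a dose
statistic at another.  The planted statistics are computed through the
*real* extraction pipeline, so parameter recovery is an end-to-end test
of the whole stack rather than of the generator alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .config import RunConfig
from .dose import DoseField, MotionModel
from .geometry import VoxelGrid

__all__ = ["CohortConfig", "PatientData", "Cohort", "generate_patient",
           "generate_outcomes", "generate_cohort"]


@dataclass
class CohortConfig:
    """Knobs for the synthetic cohort."""

    n_patients: int = 200
    seed: int = 0

    grid_dims: tuple[int, int, int] = (64, 64, 32)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    n_phases: int = 5

    tumour_radius_range_mm: tuple[float, float] = (4.0, 16.0)
    tumour_hu: float = 40.0
    heterogeneity_sd_hu: float = 60.0
    lung_hu: float = -800.0
    lung_noise_sd_hu: float = 40.0
    surface_hu_mean: float = -250.0
    surface_hu_sd: float = 150.0
    peritumour_gradient_mm: float = 5.0

    prescription_gy: float = 60.0
    n_fractions: int = 5
    alpha_beta: float = 10.0
    margin_mm: float = 5.0
    penumbra_steepness: float = 1.0  # 1/mm in the sigmoidal fall-off
    incidental_scale: float = 0.25  # incidental dose plateau, fraction of Rx
    incidental_range_mm: float = 30.0
    cold_spot_prob: float = 0.7
    cold_spot_depth: float = 0.8  # max fractional dose reduction in a sector
    cold_spot_sectors: int = 3

    motion_amplitude_mm: tuple[float, float] = (4.0, 0.5)  # lognormal (median, sigma)

    # planted outcome signal (statistics are pipeline-extracted values)
    planted_density_stat: str = "mean"
    planted_density_cm: float = 0.0
    planted_dose_stat: str = "dose_sd"
    planted_dose_cm: float = 3.0
    b1: float = 0.0  # dose main effect (per SD)
    b2: float = 0.0  # density main effect (per SD)
    b3: float = 0.0  # interaction (per SD x SD)
    clinical_coefs: dict = field(default_factory=dict)

    baseline_rate_per_month: float = 0.012
    target_event_fraction: float = 0.17


@dataclass
class PatientData:
    """One synthetic patient's imaging inputs."""

    patient_id: str
    grid: VoxelGrid
    phases: list[np.ndarray]
    gtv: np.ndarray
    lung: np.ndarray
    body: np.ndarray
    dose: DoseField
    motion: MotionModel
    covariates: dict
    sdm: object | None = None  # cached SignedDistanceMap for the GTV


@dataclass
class Cohort:
    """Curves + clinical table for a generated cohort (volumes discarded)."""

    clinical: pd.DataFrame
    density_curves: dict  # stat -> {patient_id: SummaryCurve}
    dose_curves: dict
    planted_density: np.ndarray
    planted_dose: np.ndarray
    mean_gtv_dose: np.ndarray
    manifest: dict


def _physical_coords(grid: VoxelGrid) -> list[np.ndarray]:
    """Voxel-centre coordinates (mm) centred on the grid midpoint."""
    axes = [
        (np.arange(d) - (d - 1) / 2.0) * s
        for d, s in zip(grid.dims, grid.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def generate_patient(config: CohortConfig, patient_seed: int) -> PatientData:
    """Deterministically generate one patient from ``(config.seed, patient_seed)``."""
    rng = np.random.default_rng([config.seed, patient_seed])
    grid = VoxelGrid(tuple(config.grid_dims), tuple(config.spacing_mm))
    xx, yy, zz = _physical_coords(grid)

    lo_r, hi_r = config.tumour_radius_range_mm
    r = rng.uniform(lo_r, hi_r)
    axes_scale = rng.uniform(0.8, 1.2, size=3)
    radii = r * axes_scale
    half_extent = [d * s / 2.0 for d, s in zip(grid.dims, grid.spacing)]
    if any(rr >= he - 2.0 for rr, he in zip(radii, half_extent)):
        raise ValueError("tumour exceeds the grid")
    gtv = (xx / radii[0]) ** 2 + (yy / radii[1]) ** 2 + (zz / radii[2]) ** 2 <= 1.0

    lung = (
        (xx / (half_extent[0] * 0.92)) ** 2
        + (yy / (half_extent[1] * 0.92)) ** 2
        + (zz / (half_extent[2] * 0.95)) ** 2
    ) <= 1.0
    lung |= gtv
    body = np.ones(grid.dims, dtype=bool)
    body[0, :, :] = body[-1, :, :] = False
    body[:, 0, :] = body[:, -1, :] = False
    body |= lung

    from .geometry import signed_distance_map

    sdm = signed_distance_map(gtv, grid, source_mask_id="gtv")
    d = sdm.values

    # density: tumour core with internal heterogeneity, peritumoural
    # excess density decaying away from the surface, noisy lung elsewhere
    het_sd = config.heterogeneity_sd_hu * rng.uniform(0.3, 1.7)
    surface_hu = rng.normal(config.surface_hu_mean, config.surface_hu_sd)
    peri = (surface_hu - config.lung_hu) * np.exp(
        -np.maximum(d, 0.0) / config.peritumour_gradient_mm
    )
    base = np.where(
        gtv,
        config.tumour_hu,
        config.lung_hu + peri,
    )

    amp = float(
        np.minimum(rng.lognormal(np.log(config.motion_amplitude_mm[0]),
                                 config.motion_amplitude_mm[1]), 15.0)
    )
    n_ph = config.n_phases
    ref = n_ph // 2
    direction = np.array([0.15, 0.15, 1.0])
    direction /= np.linalg.norm(direction)
    translations = np.zeros((n_ph, 3))
    for p in range(n_ph):
        translations[p] = (
            direction * amp * 0.5 * (np.cos(2 * np.pi * (p - ref) / n_ph) - 1.0)
        )

    # phases share the tumour-centred frame (masks are pre-aligned); they
    # differ by noise and a phase-dependent lung density shift
    phases = []
    for p in range(n_ph):
        lung_shift = 25.0 * (np.cos(2 * np.pi * (p - ref) / n_ph) - 1.0)
        noise_sd = np.where(gtv, het_sd, config.lung_noise_sd_hu)
        img = base + lung_shift * (~gtv) + rng.normal(0.0, 1.0, grid.dims) * noise_sd
        phases.append(img)

    # SABR-like dose: uniform core inside GTV + margin, sigmoidal
    # penumbra, slowly-decaying incidental component, angular cold spots
    rx = config.prescription_gy
    fall = rx / (1.0 + np.exp(
        config.penumbra_steepness * (d - config.margin_mm)
    ))
    # per-patient incidental dose level (scatter/leakage differs by plan)
    incidental_scale = config.incidental_scale * rng.uniform(0.6, 1.6)
    incidental = (
        rx
        * incidental_scale
        * np.exp(-np.maximum(d - config.margin_mm, 0.0) / config.incidental_range_mm)
    )
    dose_vals = np.maximum(fall, incidental)
    # Angular cold-spot sectors whose depth follows a smooth random radial
    # profile (knots every 10 mm).  Nearby annuli share modulation depth,
    # distant ones are nearly independent, so dose non-uniformity carries
    # distance-resolved patient-specific signal.
    if rng.uniform() < config.cold_spot_prob:
        depth_hi = config.cold_spot_depth
    else:
        depth_hi = 0.1
    knot_d = np.arange(-10.0, 60.1, 10.0)
    knot_depth = rng.uniform(0.0, depth_hi, size=knot_d.size)
    depth_profile = np.interp(d, knot_d, knot_depth)
    phi = np.arctan2(yy, xx)
    modulation = 1.0 - depth_profile * 0.5 * (
        1.0 + np.cos(config.cold_spot_sectors * phi + rng.uniform(0, 2 * np.pi))
    ) * (d > config.margin_mm)
    dose_vals = np.maximum(dose_vals * modulation, 0.0)

    dose = DoseField(
        dose_vals, grid, "physical", config.n_fractions, config.alpha_beta
    )
    motion = MotionModel(translations=translations, reference_phase=ref)

    volume_cc = gtv.sum() * grid.voxel_volume / 1000.0
    covariates = {
        "age": float(np.clip(rng.normal(75.0, 8.0), 45.0, 95.0)),
        "sex": int(rng.uniform() < 0.5),
        "lobe_upper": int(rng.uniform() < 0.67),
        "volume_cc": float(volume_cc),
        "motion_amplitude": amp,
    }
    return PatientData(
        patient_id=f"P{patient_seed:04d}",
        grid=grid,
        phases=phases,
        gtv=gtv,
        lung=lung,
        body=body,
        dose=dose,
        motion=motion,
        covariates=covariates,
        sdm=sdm,
    )


def generate_outcomes(
    config: CohortConfig,
    planted_density: np.ndarray,
    planted_dose: np.ndarray,
    clinical: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw survival times from a proportional-hazards model on the
    pipeline-extracted planted statistics (standardised within-cohort).

    Censoring is uniform on (0, c) with c tuned by bisection so the
    expected event fraction matches the configured target.
    """
    def z(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        sd = np.std(v, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    zd = z(planted_dose)
    zn = z(planted_density)
    lp = config.b1 * zd + config.b2 * zn + config.b3 * zd * zn
    for name, coef in config.clinical_coefs.items():
        lp = lp + coef * z(clinical[name].to_numpy())
    hazard = config.baseline_rate_per_month * np.exp(lp)
    n = len(clinical)
    event_times = rng.exponential(1.0 / hazard)
    u = rng.uniform(size=n)

    def event_fraction(c: float) -> float:
        return float(np.mean(event_times <= c * u))

    lo, hi = 1e-6, 1e7
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if event_fraction(mid) < config.target_event_fraction:
            lo = mid
        else:
            hi = mid
    c = np.sqrt(lo * hi)
    censor = c * u
    time = np.minimum(event_times, censor)
    event = (event_times <= censor).astype(int)
    time = np.maximum(time, 1e-3)

    out = clinical.copy()
    out["time"] = time
    out["event"] = event
    return out


def generate_cohort(
    config: CohortConfig,
    run_config: RunConfig | None = None,
    patient_ids: Iterable[int] | None = None,
) -> Cohort:
    """Generate patients, push each through the extraction pipeline,
    discard the volumes, and attach planted survival outcomes."""
    from .evaluate import extract_region_values
    from .pipeline import extract_patient_curves

    run_config = run_config or RunConfig()
    ids = list(patient_ids) if patient_ids is not None else list(
        range(config.n_patients)
    )

    density_curves: dict = {s: {} for s in run_config.density_stats}
    dose_curves: dict = {s: {} for s in run_config.dose_stats}
    rows = []
    planted_density = []
    planted_dose = []
    mean_gtv_dose = []
    d_cm = config.planted_density_cm
    z_cm = config.planted_dose_cm
    for pid in ids:
        patient = generate_patient(config, pid)
        extraction = extract_patient_curves(patient, run_config)
        for s in run_config.density_stats:
            density_curves[s][patient.patient_id] = extraction["density"][s]
        for s in run_config.dose_stats:
            dose_curves[s][patient.patient_id] = extraction["dose"][s]
        pd_curve = extraction["density"][config.planted_density_stat]
        pz_curve = extraction["dose"][config.planted_dose_stat]
        planted_density.append(
            extract_region_values(pd_curve, (d_cm, d_cm + 0.0999))
        )
        planted_dose.append(extract_region_values(pz_curve, (z_cm, z_cm + 0.0999)))
        mean_gtv_dose.append(extraction["mean_gtv_dose"])
        rows.append({"patient_id": patient.patient_id, **patient.covariates})

    clinical = pd.DataFrame(rows).set_index("patient_id")
    planted_density = np.asarray(planted_density, dtype=float)
    planted_dose = np.asarray(planted_dose, dtype=float)
    # planted values must exist for the hazard to be well defined
    planted_density = np.where(
        np.isfinite(planted_density), planted_density,
        np.nanmean(planted_density),
    )
    planted_dose = np.where(
        np.isfinite(planted_dose), planted_dose, np.nanmean(planted_dose)
    )
    rng = np.random.default_rng([config.seed, 987654321])
    clinical = generate_outcomes(
        config, planted_density, planted_dose, clinical, rng
    )
    manifest = {
        "seed": config.seed,
        "n_patients": len(ids),
        "planted": {
            "density_stat": config.planted_density_stat,
            "density_cm": config.planted_density_cm,
            "dose_stat": config.planted_dose_stat,
            "dose_cm": config.planted_dose_cm,
            "b1": config.b1,
            "b2": config.b2,
            "b3": config.b3,
        },
        "target_event_fraction": config.target_event_fraction,
        "event_fraction": float(clinical["event"].mean()),
    }
    return Cohort(
        clinical=clinical,
        density_curves=density_curves,
        dose_curves=dose_curves,
        planted_density=planted_density,
        planted_dose=planted_dose,
        mean_gtv_dose=np.asarray(mean_gtv_dose, dtype=float),
        manifest=manifest,
    )
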