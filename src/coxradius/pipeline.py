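"""End-to-end orchestration: per-patient curve extraction and cohort maps.

This is the single extraction path shared by the analysis workflow and
the synthetic generator (which plants outcome signal in the values this
code produces).
"""

from __future__ import annotations

import logging
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .config import RunConfig
from .cox import InteractionMap, filter_covariates, fit_cox, interaction_map
from .curves import annulus_stats, gaussian_smooth
from .dose import blur_dose_for_motion, dose_curve, to_eqd2
from .geometry import annulus_labels, signed_distance_map
from .histograms import build_radial_histogram
from .phases import select_optimal_phase

if TYPE_CHECKING:
    from .simulate import Cohort, PatientData

log = logging.getLogger(__name__)


def extract_patient_curves(patient: "PatientData", cfg: RunConfig) -> dict:
    """Density and dose summary curves for one patient.

    Density: per-phase radial histograms restricted to lung+GTV over the
    density window; the optimal phase (max summed neighbour SSIM, cyclic)
    supplies the mean/SD/p90 curves.  Dose: motion-blurred, EQD2-converted
    dose histogram restricted to the body mask over the dose window.
    All curves are Gaussian-smoothed over distance.
    """
    grid = patient.grid
    sdm = patient.sdm
    if sdm is None:
        sdm = signed_distance_map(patient.gtv, grid, source_mask_id="gtv")
    density_labels = annulus_labels(sdm, cfg.density_window_cm)
    density_restrict = patient.lung | patient.gtv
    hu_edges = cfg.density_bin_edges()

    hists = [
        build_radial_histogram(
            img, density_labels, density_restrict, hu_edges, grid,
            restrict_mask_id="lung+gtv",
        )
        for img in patient.phases
    ]
    if len(hists) >= 3:
        best = select_optimal_phase(hists)
        chosen = hists[best.phase_index]
        phase_index = best.phase_index
    else:
        phase_index = patient.motion.reference_phase if len(hists) > 1 else 0
        chosen = hists[min(phase_index, len(hists) - 1)]

    density = {}
    for stat in cfg.density_stats:
        curve = annulus_stats(chosen, stat, patient_id=patient.patient_id)
        density[stat] = gaussian_smooth(curve, cfg.smoothing_sigma_mm)

    blurred = blur_dose_for_motion(patient.dose, patient.motion)
    eqd2 = to_eqd2(blurred)
    dose_labels = annulus_labels(sdm, cfg.dose_window_cm)
    dose_hist = build_radial_histogram(
        eqd2.values, dose_labels, patient.body, cfg.dose_bin_edges(), grid,
        restrict_mask_id="body",
    )
    dose = {}
    for stat in cfg.dose_stats:
        curve = dose_curve(
            dose_hist, stat, a=cfg.gen_mean_a, threshold=cfg.dose_threshold_gy
        )
        curve = gaussian_smooth(curve, cfg.smoothing_sigma_mm)
        dose[stat] = type(curve)(
            statistic=curve.statistic,
            distances_cm=curve.distances_cm,
            values=curve.values,
            valid=curve.valid,
            patient_id=patient.patient_id,
        )

    return {
        "density": density,
        "dose": dose,
        "optimal_phase": phase_index,
        "mean_gtv_dose": float(eqd2.values[patient.gtv].mean()),
    }


def baseline_model(
    clinical: pd.DataFrame,
    covariates: list[str],
    cfg: RunConfig,
):
    """Availability/complete-case filtering plus the clinical-only fit."""
    kept, table = filter_covariates(
        clinical, covariates,
        availability_threshold=cfg.availability_threshold,
    )
    fit = fit_cox(table, kept)
    return kept, table, fit


def build_maps(cohort: "Cohort", cfg: RunConfig) -> dict[tuple[str, str], InteractionMap]:
    """One interaction map per (density statistic, dose statistic) pair."""
    kept, table, _ = baseline_model(
        cohort.clinical, list(cfg.covariates), cfg
    )
    maps = {}
    for dens_stat, dose_stat in cfg.metric_pairs:
        maps[(dens_stat, dose_stat)] = interaction_map(
            cohort.density_curves[dens_stat],
            cohort.dose_curves[dose_stat],
            table,
            kept,
            metric_pair=(dens_stat, dose_stat),
            min_events=cfg.min_events_per_cell,
        )
        log.info("map %s x %s done", dens_stat, dose_stat)
    return maps


def nzv_granularity(dose_stat_or_density: str, cfg: RunConfig) -> float:
    """Granularity for the near-zero-variance screen by value domain."""
    if dose_stat_or_density in ("mean", "sd", "p90"):
        return 1.0  # HU
    if dose_stat_or_density == "fraction_below":
        return 0.01  # one percentage point
    return 0.1  # Gy


def evaluate_maps(
    cohort: "Cohort",
    maps: dict[tuple[str, str], InteractionMap],
    cfg: RunConfig,
):
    """Post-process every map and evaluate surviving regions end-to-end."""
    from .evaluate import evaluate_region, extract_region_values
    from .regions import near_zero_variance, postprocess_map

    kept, table, base_fit = baseline_model(
        cohort.clinical, list(cfg.covariates), cfg
    )
    results = []
    for (dens_stat, dose_stat), imap in maps.items():
        regions = postprocess_map(
            imap,
            alpha=cfg.alpha,
            min_thickness=cfg.min_thickness_mm,
            min_box_mm=cfg.min_box_mm,
        )
        for region in regions:
            entry = {
                "metric_pair": (dens_stat, dose_stat),
                "region": region,
                "model": None,
            }
            if region.status != "boxed":
                results.append(entry)
                continue
            dens_vals = np.array([
                extract_region_values(c, region.box_density_cm)
                for c in cohort.density_curves[dens_stat].values()
            ])
            dose_vals = np.array([
                extract_region_values(c, region.box_dose_cm)
                for c in cohort.dose_curves[dose_stat].values()
            ])
            nzv_d = near_zero_variance(
                dens_vals, nzv_granularity(dens_stat, cfg),
                cfg.nzv_unique_cut, cfg.nzv_freq_cut,
            )
            nzv_z = near_zero_variance(
                dose_vals, nzv_granularity(dose_stat, cfg),
                cfg.nzv_unique_cut, cfg.nzv_freq_cut,
            )
            if nzv_d or nzv_z:
                entry["region"] = type(region)(
                    cells=region.cells,
                    density_window_cm=region.density_window_cm,
                    dose_window_cm=region.dose_window_cm,
                    status="rejected_nzv",
                    box_density_cm=region.box_density_cm,
                    box_dose_cm=region.box_dose_cm,
                    diagnostics=region.diagnostics,
                )
                results.append(entry)
                continue
            model = evaluate_region(
                region,
                cohort.density_curves[dens_stat],
                cohort.dose_curves[dose_stat],
                table,
                kept,
                baseline_c_index=base_fit.c_index,
                n_resamples=cfg.n_bootstrap,
                seed=cfg.seed,
                skew_bound=cfg.skew_bound,
            )
            entry["model"] = model
            results.append(entry)
    return results
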