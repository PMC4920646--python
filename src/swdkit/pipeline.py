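"""End-to-end in-silico experiments: simulate -> detect -> analyze cohorts.

One animal-session is simulated, pushed through the detection pipeline and
reduced to per-epoch metrics (and optionally interictal band powers and
ictal peak frequencies); recordings are discarded as soon as the metrics
are extracted so whole cohorts fit comfortably in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import SessionDesign
from .detect import DetectionParams, detect_swds, match_events
from .ictal import WaveletParams, animal_peak_frequency, attach_peak_frequencies
from .interictal import (
    SpectralParams,
    antialias_resample,
    epoch_band_powers,
    normalize_band_powers,
)
from .io import Event, EventList, Recording, rasterize_mask
from .presets import get_preset
from .quantify import epoch_metrics, normalize_metrics, overall_effect
from .synth import SessionConfig, assemble_session

__all__ = [
    "AnimalResult",
    "run_animal",
    "run_cohort",
    "arm_overall_effect",
    "arm_band_power_change",
]


@dataclass
class AnimalResult:
    animal: str
    metrics: pd.DataFrame
    detected: EventList
    ground_truth: EventList
    detection_report: dict
    band_powers: pd.DataFrame | None = None
    peak_freq_hz: float | None = None
    recording: Recording | None = None


def _animal_seed(seed: int, arm_id: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, arm_id, index]))


def run_animal(
    config: SessionConfig,
    rng: np.random.Generator,
    *,
    animal: str = "a0",
    detection: DetectionParams | None = None,
    compute_bands: bool = False,
    compute_peak_freq: bool = False,
    wavelet: WaveletParams | None = None,
    spectral: SpectralParams | None = None,
    keep_recording: bool = False,
) -> AnimalResult:
    """Simulate one animal and run the requested analysis stages."""
    recording, truth = assemble_session(config, rng)
    detected, report = detect_swds(
        recording,
        detection,
        ground_truth=truth,
        design=config.design,
        return_report=True,
    )
    metrics = epoch_metrics(detected, config.design)
    metrics.insert(0, "animal", animal)

    peak = None
    if compute_peak_freq:
        with_freq = attach_peak_frequencies(recording, detected, wavelet)
        peak, _ = animal_peak_frequency(with_freq)
        detected = with_freq

    bands = None
    if compute_bands:
        spectral = spectral or SpectralParams()
        rec200 = antialias_resample(recording, spectral.resample_hz)
        pad = spectral.mask_pad_s
        # exclude the union of detected and annotated seizures: annotations
        # stand in for the visual refinement pass that catches the short
        # events automatic detection misses
        swds = list(detected) + list(truth.with_label("swd"))
        padded_swds = [Event(e.start_s - pad, e.end_s + pad, "swd") for e in swds]
        mask_events = EventList(
            padded_swds + [e for e in truth if e.label in ("artifact", "sleep")],
            validate=False,
        )
        mask = rasterize_mask(mask_events, ("swd", "artifact", "sleep"), rec200)
        bands = epoch_band_powers(rec200, mask, config.design, spectral)
        bands.insert(0, "animal", animal)

    return AnimalResult(
        animal=animal,
        metrics=metrics,
        detected=detected,
        ground_truth=truth,
        detection_report=report,
        band_powers=bands,
        peak_freq_hz=peak,
        recording=recording if keep_recording else None,
    )


def run_cohort(
    preset: str,
    n_animals: int,
    seed: int,
    *,
    arm_id: int = 0,
    base_config: SessionConfig | None = None,
    detection: DetectionParams | None = None,
    compute_bands: bool = False,
    compute_peak_freq: bool = False,
) -> dict:
    """Simulate and analyze one treatment arm.

    Returns a dict with the stacked epoch-metrics table (column ``dose_arm``
    added), per-animal peak frequencies, stacked band-power table, detected
    and ground-truth event lists per animal, and detection fidelity summary.
    """
    base = base_config or SessionConfig()
    drug = get_preset(preset, base)
    config = replace(base, drug=drug)
    results = []
    for i in range(n_animals):
        rng = _animal_seed(seed, arm_id, i)
        results.append(
            run_animal(
                config,
                rng,
                animal=f"{preset}_{i}",
                detection=detection,
                compute_bands=compute_bands,
                compute_peak_freq=compute_peak_freq,
            )
        )
    metrics = pd.concat([r.metrics for r in results], ignore_index=True)
    metrics.insert(1, "dose_arm", preset)
    bands = None
    if compute_bands:
        bands = pd.concat([r.band_powers for r in results], ignore_index=True)
        bands.insert(1, "dose_arm", preset)
    fidelity = [
        match_events(r.detected, r.ground_truth, min_truth_duration_s=1.2)
        for r in results
    ]
    return {
        "preset": preset,
        "config": config,
        "metrics": metrics,
        "band_powers": bands,
        "peak_freqs": [r.peak_freq_hz for r in results],
        "detected": [r.detected for r in results],
        "ground_truth": [r.ground_truth for r in results],
        "fidelity": fidelity,
    }


def arm_overall_effect(
    drug_metrics: pd.DataFrame,
    vehicle_metrics: pd.DataFrame,
    design: SessionDesign,
    metric: str,
) -> dict:
    """Overall percent change of a drug arm vs vehicle for one seizure metric.

    ``sem_comparison`` additionally propagates the sampling error of the
    vehicle-group normalization itself (the vehicle mean every drug animal
    is divided by), which the plain across-animal SEM cannot see because it
    shifts the whole arm coherently.
    """
    drug_norm = normalize_metrics(drug_metrics, design, vehicle_table=vehicle_metrics)
    res = overall_effect(drug_norm, design, metric)
    veh_norm = normalize_metrics(vehicle_metrics, design, vehicle_table=vehicle_metrics)
    veh_res = overall_effect(veh_norm, design, metric)
    if np.isfinite(res.get("sem", np.nan)) and np.isfinite(veh_res.get("sem", np.nan)):
        rel_d = res["sem"] / abs(res["mean_pct_of_vehicle"])
        rel_v = veh_res["sem"] / abs(veh_res["mean_pct_of_vehicle"])
        res["sem_comparison"] = abs(res["mean_pct_of_vehicle"]) * float(
            np.sqrt(rel_d**2 + rel_v**2)
        )
    else:
        res["sem_comparison"] = res.get("sem", np.nan)
    return res


def arm_band_power_change(
    drug_bands: pd.DataFrame,
    vehicle_bands: pd.DataFrame,
    design: SessionDesign,
    band: str,
) -> dict:
    """Mean percent change of one band's interictal power vs vehicle.

    Per animal: mean ``pct_vehicle`` over the treatment epochs; the group
    mean and SEM are taken across animals.
    """
    drug_norm = normalize_band_powers(drug_bands, design, vehicle_table=vehicle_bands)
    sel = drug_norm[
        (drug_norm["band"] == band)
        & (drug_norm["epoch_index"].isin(design.treatment_epochs))
    ]
    per_animal = sel.groupby("animal")["pct_vehicle"].mean().dropna()
    mean = float(per_animal.mean())
    sem = float(per_animal.std(ddof=1) / np.sqrt(per_animal.size)) if per_animal.size > 1 else np.nan

    veh_norm = normalize_band_powers(vehicle_bands, design, vehicle_table=vehicle_bands)
    vsel = veh_norm[
        (veh_norm["band"] == band)
        & (veh_norm["epoch_index"].isin(design.treatment_epochs))
    ]
    veh_pa = vsel.groupby("animal")["pct_vehicle"].mean().dropna()
    if veh_pa.size > 1 and np.isfinite(sem):
        rel_v = float(veh_pa.std(ddof=1) / np.sqrt(veh_pa.size)) / abs(veh_pa.mean())
        sem_comparison = abs(mean) * float(np.sqrt((sem / abs(mean)) ** 2 + rel_v**2))
    else:
        sem_comparison = sem
    return {
        "band": band,
        "mean_pct_of_vehicle": mean,
        "sem": sem,
        "sem_comparison": sem_comparison,
        "percent_change": abs(100.0 - mean),
        "direction": "decrease" if mean < 100.0 else "increase",
        "n": int(per_animal.size),
    }
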