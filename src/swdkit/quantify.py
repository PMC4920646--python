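"""Seizure quantification in 20-min epochs, normalization and overall effects.

Three parameters are quantified per epoch: total time spent in seizures,
number of seizures and mean duration of individual seizures.  Conventions:
total time splits an edge-spanning event between epochs (time is conserved
exactly); the count and the event's full duration are attributed to the
epoch containing the event's start (counts stay integral).  Epochs with no
seizure have a *missing* mean duration, never zero.

Normalization: each treatment-epoch value is expressed as a percentage of
the per-epoch mean of the control period for the same animal, then as a
percentage of the vehicle-group mean at the matching epoch.  The overall
effect of an arm is computed on animal-level means across the treatment
epochs and reported as a group mean +/- SEM percent change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import SessionDesign
from .io import EventList

__all__ = [
    "epoch_metrics",
    "normalize_metrics",
    "overall_effect",
    "cohort_metrics",
]

METRICS = ("total_time_s", "n_seizures", "mean_duration_s")


def epoch_metrics(events: EventList, design: SessionDesign) -> pd.DataFrame:
    """Per-epoch seizure metrics for one animal.

    ``events`` should contain the accepted SWDs.  Events outside the session
    window are clipped for total time and dropped from counts when their
    start lies outside.
    """
    swds = [e for e in events if e.label == "swd"]
    rows = []
    for e_idx in design.epochs:
        lo, hi = design.epoch_bounds(e_idx)
        total = 0.0
        durations = []
        for ev in swds:
            overlap = min(ev.end_s, hi) - max(ev.start_s, lo)
            if overlap > 0:
                total += overlap
            if lo <= ev.start_s < hi:
                durations.append(ev.duration_s)
        rows.append(
            {
                "epoch_index": e_idx,
                "total_time_s": total,
                "n_seizures": len(durations),
                "mean_duration_s": float(np.mean(durations)) if durations else np.nan,
            }
        )
    return pd.DataFrame(rows)


def normalize_metrics(
    table: pd.DataFrame,
    design: SessionDesign,
    vehicle_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Control-period and vehicle-group normalization of epoch metrics.

    ``table``: long or wide frame with columns animal (optional), epoch_index
    and the three metric columns.  Adds ``<metric>_pct_control`` columns and,
    when a vehicle table is provided, ``<metric>_pct_vehicle``.  Animals with
    a zero control value for a metric are excluded (missing) for that metric.
    """
    df = table.copy()
    ctrl = design.control_epochs
    keys = [k for k in ("animal", "dose_arm") if k in df.columns]
    if not keys:
        df["_one"] = 0
        keys = ["_one"]

    for metric in METRICS:
        base = (
            df.loc[df["epoch_index"].isin(ctrl)]
            .groupby(keys)[metric]
            .mean()
            .rename("_base")
        )
        df = df.join(base, on=keys)
        ok = df["_base"] > 0
        df[f"{metric}_pct_control"] = np.where(
            ok, 100.0 * df[metric] / df["_base"], np.nan
        )
        df = df.drop(columns="_base")
    if "_one" in df.columns:
        df = df.drop(columns="_one")

    if vehicle_table is not None:
        veh = vehicle_table.copy()
        if f"{METRICS[0]}_pct_control" not in veh.columns:
            veh = normalize_metrics(veh, design)
        for metric in METRICS:
            ref = (
                veh.groupby("epoch_index")[f"{metric}_pct_control"]
                .mean()
                .rename("ref")
            )
            df = df.join(ref, on="epoch_index")
            df[f"{metric}_pct_vehicle"] = (
                100.0 * df[f"{metric}_pct_control"] / df["ref"]
            )
            df = df.drop(columns="ref")
    return df


def overall_effect(
    normalized: pd.DataFrame,
    design: SessionDesign,
    metric: str = "total_time_s",
    *,
    column: str | None = None,
) -> dict:
    """Overall percent change of an arm over the full treatment period.

    Per animal: mean of the normalized %-of-vehicle values across treatment
    epochs (missing epochs omitted).  Returns the group mean, SEM, percent
    change magnitude and direction.
    """
    col = column or f"{metric}_pct_vehicle"
    if col not in normalized.columns:
        raise KeyError(f"column {col!r} absent; run normalize_metrics with a vehicle table")
    trt = normalized[normalized["epoch_index"].isin(design.treatment_epochs)]
    if "animal" in normalized.columns:
        per_animal = trt.groupby("animal")[col].mean()
    else:
        per_animal = pd.Series([trt[col].mean()])
    per_animal = per_animal.dropna()
    if per_animal.size < 2:
        return {
            "mean_pct_of_vehicle": float(per_animal.mean()) if per_animal.size else np.nan,
            "sem": np.nan,
            "percent_change": np.nan,
            "direction": None,
            "n": int(per_animal.size),
        }
    mean = float(per_animal.mean())
    sem = float(per_animal.std(ddof=1) / np.sqrt(per_animal.size))
    return {
        "mean_pct_of_vehicle": mean,
        "sem": sem,
        "percent_change": abs(100.0 - mean),
        "direction": "decrease" if mean < 100.0 else "increase",
        "n": int(per_animal.size),
    }


def cohort_metrics(per_animal_events: dict[str, EventList], design: SessionDesign) -> pd.DataFrame:
    """Stack :func:`epoch_metrics` for a labeled set of animals."""
    frames = []
    for animal, events in per_animal_events.items():
        t = epoch_metrics(events, design)
        t.insert(0, "animal", animal)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
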