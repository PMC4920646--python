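"""Interictal spectral analysis: masked short-time Fourier band power.

The recording is resampled to 200 Hz through an anti-aliasing FIR low-pass,
samples inside detected SWDs, artifacts and sleep bouts are excluded, and a
Gaussian-window STFT (spectral SD ~ 1 Hz, 1-80 Hz at 1 Hz bins) is computed
over the unmasked runs of every 20-min epoch.  Band power is the mean power
over a band's bins: delta 1-4, theta 5-8, alpha 9-12, beta 13-30, gamma
31-80 Hz with the 48-52 Hz bins excluded to avoid mains contamination.
Per-epoch spectra are time-averaged with run-length weighting; epochs with
less than 10% usable time are reported missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .design import SessionDesign
from .io import Recording, SampleMask

__all__ = [
    "SpectralParams",
    "antialias_resample",
    "resample_mask",
    "stft_power",
    "epoch_band_powers",
    "normalize_band_powers",
]

DEFAULT_BANDS: dict[str, tuple[int, int]] = {
    "delta": (1, 4),
    "theta": (5, 8),
    "alpha": (9, 12),
    "beta": (13, 30),
    "gamma": (31, 80),
}


@dataclass(frozen=True)
class SpectralParams:
    resample_hz: float = 200.0
    freq_range_hz: tuple[float, float] = (1.0, 80.0)
    sigma_f_hz: float = 1.0  # spectral SD of the Gaussian taper
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    notch_exclusion_hz: tuple[float, float] = (48.0, 52.0)
    min_run_s: float = 2.0
    min_epoch_fraction: float = 0.10
    # guard margin around excluded seizures: detected SWD extents are a bit
    # tighter than the underlying event, and the high-amplitude onset/offset
    # would otherwise leak into the "interictal" spectra
    mask_pad_s: float = 0.5

    def __post_init__(self) -> None:
        if self.resample_hz <= 2 * self.freq_range_hz[1]:
            raise ValueError("resample rate must exceed twice the top analysis frequency")

    def band_bins(self, band: str, freqs: np.ndarray) -> np.ndarray:
        lo, hi = self.bands[band]
        sel = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        if band == "gamma":
            nlo, nhi = self.notch_exclusion_hz
            sel &= ~((freqs >= nlo - 1e-9) & (freqs <= nhi + 1e-9))
        return sel


def antialias_resample(recording: Recording, target_hz: float = 200.0) -> Recording:
    """FIR anti-aliased polyphase resampling to ``target_hz``.

    Identity passthrough when the recording is already at the target rate.
    """
    if target_hz > recording.fs:
        raise ValueError("upsampling is not supported; target must not exceed fs")
    if target_hz == recording.fs:
        return recording
    frac = Fraction(target_hz / recording.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(recording.samples, up, down, axis=1)
    return Recording(out, fs=target_hz, channel_labels=list(recording.channel_labels),
                     t0=recording.t0)


def resample_mask(mask: SampleMask, target_hz: float) -> SampleMask:
    """Nearest-interval projection of an exclusion mask onto a new rate.

    A target sample is masked when any source sample in its footprint was
    masked (conservative: exclusion is preserved).
    """
    if target_hz == mask.fs:
        return mask
    ratio = mask.fs / target_hz
    n_out = int(round(mask.n_samples / ratio))
    idx0 = np.floor(np.arange(n_out) * ratio).astype(int)
    idx1 = np.minimum(np.ceil((np.arange(n_out) + 1) * ratio).astype(int), mask.n_samples)
    cum = np.r_[0, np.cumsum(mask.mask)]
    hit = (cum[idx1] - cum[idx0]) > 0
    return SampleMask(hit, target_hz, mask.t0, mask.provenance)


def _gaussian_window(fs: float, sigma_f_hz: float) -> np.ndarray:
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f_hz)
    half = int(round(4.0 * sigma_t * fs))
    n = 2 * half + 1
    return signal.windows.gaussian(n, std=sigma_t * fs)


def stft_power(
    segment: np.ndarray,
    fs: float,
    params: SpectralParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-window spectrogram restricted to the analysis grid.

    Returns (power[t, f], freqs) with 1 Hz bins over 1-80 Hz; power is a
    one-sided density (uV^2/Hz), hop is half the window length.
    """
    params = params or SpectralParams()
    win = _gaussian_window(fs, params.sigma_f_hz)
    if segment.size < 2 * win.size:
        raise ValueError("segment shorter than two window lengths")
    nfft = int(round(fs / 0.5))  # 0.5 Hz native grid; integer-Hz bins selected below
    nfft = max(nfft, win.size)
    freqs, _, sxx = signal.spectrogram(
        np.asarray(segment, dtype=float),
        fs=fs,
        window=win,
        noverlap=win.size // 2,
        nfft=nfft,
        scaling="density",
        mode="psd",
        detrend=False,
    )
    lo, hi = params.freq_range_hz
    grid = np.arange(int(lo), int(hi) + 1, dtype=float)
    sel = np.isclose(freqs[:, None], grid[None, :], atol=1e-6).any(axis=1)
    return sxx[sel].T, freqs[sel]


def epoch_band_powers(
    recording: Recording,
    mask: SampleMask,
    design: SessionDesign,
    params: SpectralParams | None = None,
    *,
    channel: int = 0,
) -> pd.DataFrame:
    """Per-epoch band power over the unmasked runs of a (resampled) recording.

    The STFT is evaluated on each unmasked run of at least ``min_run_s``;
    run spectra are averaged weighted by run length.  Epochs with less than
    ``min_epoch_fraction`` usable time yield missing band powers.
    Returns a tidy frame with columns epoch_index, band, mean_power,
    fraction_unmasked.
    """
    params = params or SpectralParams()
    if mask.n_samples != recording.n_samples:
        raise ValueError("mask must be aligned to the recording (resample it first)")
    x = recording.channel(channel)
    fs = recording.fs
    rows = []
    for e_idx in design.epochs:
        start, end = design.epoch_bounds(e_idx)
        i0 = max(recording.index_of(start), 0)
        i1 = min(recording.index_of(end), recording.n_samples)
        if i1 <= i0:
            continue
        free = ~mask.mask[i0:i1]
        frac = float(free.mean())
        spectra, weights = [], []
        if frac >= params.min_epoch_fraction:
            edges = np.diff(free.astype(np.int8))
            starts = np.flatnonzero(edges == 1) + 1
            ends = np.flatnonzero(edges == -1) + 1
            if free.size and free[0]:
                starts = np.r_[0, starts]
            if free.size and free[-1]:
                ends = np.r_[ends, free.size]
            for s, e in zip(starts, ends):
                if (e - s) / fs < params.min_run_s:
                    continue
                seg = x[i0 + s : i0 + e]
                win = _gaussian_window(fs, params.sigma_f_hz)
                if seg.size < 2 * win.size:
                    continue
                power, freqs = stft_power(seg, fs, params)
                spectra.append(power.mean(axis=0))
                weights.append(e - s)
        if spectra:
            mean_spec = np.average(np.asarray(spectra), axis=0, weights=np.asarray(weights, dtype=float))
            for band in params.bands:
                bins = params.band_bins(band, freqs)
                rows.append(
                    {
                        "epoch_index": e_idx,
                        "band": band,
                        "mean_power": float(mean_spec[bins].mean()),
                        "fraction_unmasked": frac,
                    }
                )
        else:
            for band in params.bands:
                rows.append(
                    {
                        "epoch_index": e_idx,
                        "band": band,
                        "mean_power": np.nan,
                        "fraction_unmasked": frac,
                    }
                )
    return pd.DataFrame(rows, columns=["epoch_index", "band", "mean_power", "fraction_unmasked"])


def normalize_band_powers(
    table: pd.DataFrame,
    design: SessionDesign,
    vehicle_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Normalize band powers to the control period and to the vehicle group.

    ``table`` must carry columns animal, dose_arm, epoch_index, band,
    mean_power.  Adds ``pct_control`` (per animal and band: epoch power as a
    percentage of the mean of the control epochs) and, when a vehicle table
    (already control-normalized, or raw with control epochs present) is
    given, ``pct_vehicle`` (percentage of the vehicle-group mean at the
    matching epoch and band).  Zero or missing control power yields missing
    values.
    """
    df = table.copy()
    ctrl_epochs = design.control_epochs
    keys = [k for k in ("animal", "dose_arm") if k in df.columns] + ["band"]
    ctrl = (
        df.loc[df["epoch_index"].isin(ctrl_epochs)]
        .groupby(keys)["mean_power"]
        .mean()
        .rename("_ctrl")
    )
    df = df.join(ctrl, on=keys)
    ok = df["_ctrl"] > 0
    df["pct_control"] = np.where(ok, 100.0 * df["mean_power"] / df["_ctrl"], np.nan)
    df = df.drop(columns="_ctrl")

    if vehicle_table is not None:
        veh = vehicle_table.copy()
        if "pct_control" not in veh.columns:
            veh = normalize_band_powers(veh, design)
        ref = (
            veh.groupby(["epoch_index", "band"])["pct_control"].mean().rename("vehicle_mean")
        )
        df = df.join(ref, on=["epoch_index", "band"])
        df["pct_vehicle"] = 100.0 * df["pct_control"] / df["vehicle_mean"]
        df = df.drop(columns="vehicle_mean")
    return df
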