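"""Synthetic GAERS-like EEG sessions with ground-truth annotations.

The generator emulates the phenomenology of a freely-moving GAERS recording:
a 1/f-shaped desynchronized-wake background, scheduled non-REM bouts with
elevated delta power and 12 Hz sleep spindles, sporadic broadband movement
artifacts, and spike-and-wave discharges (SWDs) whose morphology (sharp
spike + slow wave at ~7 Hz, with harmonics) dominates the trace.  Seizure
starts follow an inhomogeneous Poisson process with a refractory dead time;
durations are gamma distributed (moment-matched to mean 16.1 s, SD 14.3 s,
truncated below 1 s by resampling).  A parametric drug-effect model scales
the seizure rate, seizure duration, SWD cycle frequency and per-band
background amplitude after the injection at t = 0.

Everything inserted into the signal is reported in a ground-truth event list
with the same schema as the detector output, so detector and quantification
stages can be validated by direct diffing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats

from .design import SessionDesign
from .io import Event, EventList, Recording

__all__ = [
    "SwdShapeParams",
    "SeizureProcessParams",
    "DrugEffectModel",
    "AnimalVariability",
    "SessionConfig",
    "generate_background",
    "sample_seizure_intervals",
    "synthesize_swd",
    "assemble_session",
    "sleep_intervals",
    "gamma_duration_dist",
    "truncated_mean_duration",
]

# printed analysis bands (inclusive integer-Hz edges, as reported)
ANALYSIS_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1, 4),
    "theta": (5, 8),
    "alpha": (9, 12),
    "beta": (13, 30),
    "gamma": (31, 80),
}

# Synthesis gain bands are flared 2 Hz beyond the printed edges so the ~1 Hz
# spectral window of the interictal analysis sees a locally flat gain and the
# measured band-power ratio equals the configured amplitude factor squared.
GAIN_FLARE_HZ = 2.0


@dataclass(frozen=True)
class SwdShapeParams:
    """Morphology of a spike-and-wave cycle.

    One cycle = a sharp positive spike occupying ``spike_fraction`` of the
    cycle riding on a slower sinusoidal wave, plus weak harmonic components.
    Amplitudes are in microvolts; with the default wake background SD of
    50 uV the spike sits at 8 background SDs (comfortably above the 5-9 SD
    detection window) and the wave at 3 SDs (below threshold, so each cycle
    yields a single threshold-crossing complex).
    """

    cycle_freq_hz: float = 6.90
    spike_fraction: float = 0.15
    spike_amp_uv: float = 400.0
    wave_amp_uv: float = 100.0
    harmonics: tuple[float, ...] = (0.25, 0.10)  # of wave_amp at 2f, 3f
    ramp_s: float = 0.2

    def __post_init__(self) -> None:
        if self.cycle_freq_hz <= 0:
            raise ValueError("cycle_freq_hz must be positive")
        if not 0 < self.spike_fraction < 1:
            raise ValueError("spike_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SeizureProcessParams:
    """Seizure initiation/duration process.

    Starts: Poisson with ``rate_per_min``, thinned by a non-paralyzable dead
    time equal to the ongoing seizure plus ``refractory_s``.  Durations:
    gamma, moment-matched to ``duration_mean_s``/``duration_sd_s`` and
    truncated below ``duration_min_s`` by resampling.
    """

    rate_per_min: float = 0.75
    duration_family: str = "gamma"
    duration_mean_s: float = 16.1
    duration_sd_s: float = 14.3
    duration_min_s: float = 1.0
    refractory_s: float = 5.0

    def __post_init__(self) -> None:
        if self.rate_per_min <= 0:
            raise ValueError("rate_per_min must be positive")
        if self.duration_family != "gamma":
            raise ValueError("only the gamma duration family is implemented")


def gamma_duration_dist(process: SeizureProcessParams):
    """Moment-matched gamma distribution of untruncated seizure durations."""
    k = (process.duration_mean_s / process.duration_sd_s) ** 2
    theta = process.duration_sd_s**2 / process.duration_mean_s
    return stats.gamma(k, scale=theta)


def truncated_mean_duration(process: SeizureProcessParams, multiplier: float = 1.0) -> float:
    """E[m*X | m*X >= duration_min] for the gamma duration distribution.

    Uses the gamma identity  E[X; X > a] = k*theta * (1 - F_{k+1}(a)).
    """
    if multiplier <= 0:
        raise ValueError("duration multiplier must be positive")
    k = (process.duration_mean_s / process.duration_sd_s) ** 2
    theta = process.duration_sd_s**2 / process.duration_mean_s
    a = process.duration_min_s / multiplier
    sf_k = stats.gamma.sf(a, k, scale=theta)
    if sf_k <= 0:
        return process.duration_min_s
    partial = k * theta * stats.gamma.sf(a, k + 1, scale=theta)
    return multiplier * partial / sf_k


def truncated_mean_sq_duration(process: SeizureProcessParams, multiplier: float = 1.0) -> float:
    """E[(m*X)^2 | m*X >= duration_min] via E[X^2; X > a] = k(k+1)theta^2 (1 - F_{k+2}(a))."""
    if multiplier <= 0:
        raise ValueError("duration multiplier must be positive")
    k = (process.duration_mean_s / process.duration_sd_s) ** 2
    theta = process.duration_sd_s**2 / process.duration_mean_s
    a = process.duration_min_s / multiplier
    sf_k = stats.gamma.sf(a, k, scale=theta)
    if sf_k <= 0:
        return process.duration_min_s**2
    partial = k * (k + 1) * theta**2 * stats.gamma.sf(a, k + 2, scale=theta)
    return multiplier**2 * partial / sf_k


def _sample_truncated_durations(
    rng: np.random.Generator,
    process: SeizureProcessParams,
    multipliers: np.ndarray,
) -> np.ndarray:
    """Sample m*X conditioned on m*X >= duration_min (inverse-CDF)."""
    dist = gamma_duration_dist(process)
    lo = dist.cdf(process.duration_min_s / np.asarray(multipliers, dtype=float))
    u = rng.uniform(lo, 1.0)
    return np.asarray(multipliers) * dist.ppf(u)


@dataclass(frozen=True)
class DrugEffectModel:
    """Injection-locked parametric drug effect.

    All effects are null before the injection (t < 0).  Rate, duration and
    band-amplitude effects develop linearly over ``onset_s`` and then hold
    (optional exponential washout after ``offset_s``).  The cycle-frequency
    shift engages as a step at the injection (``freq_onset_s = 0``): arm-level
    peak frequencies are measured on whatever treatment-period seizures
    occur, and for strongly suppressive arms those are concentrated right
    after injection, so a step is the parametrization under which the
    expected measured arm frequency equals the configured one.
    """

    rate_multiplier: float = 1.0
    duration_multiplier: float = 1.0
    cycle_freq_shift_hz: float = 0.0
    band_amp_multipliers: dict[str, float] = field(default_factory=dict)
    onset_s: float = 300.0
    freq_onset_s: float = 0.0
    offset_s: float | None = None
    washout_tau_s: float | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.rate_multiplier < 0 or self.duration_multiplier < 0:
            raise ValueError("multipliers must be non-negative")
        if any(m < 0 for m in self.band_amp_multipliers.values()):
            raise ValueError("band amplitude multipliers must be non-negative")
        unknown = set(self.band_amp_multipliers) - set(ANALYSIS_BANDS)
        if unknown:
            raise ValueError(f"unknown bands {sorted(unknown)}")

    def level(self, t: np.ndarray | float, onset_s: float | None = None) -> np.ndarray:
        """Effect engagement in [0, 1] as a function of session time."""
        onset = self.onset_s if onset_s is None else onset_s
        t = np.asarray(t, dtype=float)
        lev = np.clip(t / onset, 0.0, 1.0) if onset > 0 else (t >= 0).astype(float)
        lev = np.where(t < 0, 0.0, lev)
        if self.offset_s is not None and self.washout_tau_s:
            decay = np.exp(-np.maximum(t - self.offset_s, 0.0) / self.washout_tau_s)
            lev = lev * np.where(t > self.offset_s, decay, 1.0)
        return lev

    def rate_mult(self, t) -> np.ndarray:
        return 1.0 + (self.rate_multiplier - 1.0) * self.level(t)

    def duration_mult(self, t) -> np.ndarray:
        return 1.0 + (self.duration_multiplier - 1.0) * self.level(t)

    def freq_shift(self, t) -> np.ndarray:
        return self.cycle_freq_shift_hz * self.level(t, onset_s=self.freq_onset_s)

    def band_amp_mult(self, band: str, t) -> np.ndarray:
        m = self.band_amp_multipliers.get(band, 1.0)
        return 1.0 + (m - 1.0) * self.level(t)

    def with_response_jitter(self, eps: float, sd: float) -> "DrugEffectModel":
        """Per-animal drug-response heterogeneity, mean-preserving.

        Each multiplier m is replaced by a lognormal draw with log-SD
        proportional to |log m| (no spread when the effect is null) and with
        E[m_animal] = m, so cohort means stay anchored on the configured
        effect.  ``eps`` is a standard-normal draw shared by all effect
        dimensions of one animal (a common "potency" factor); the frequency
        shift scales linearly.
        """

        def jit(m: float) -> float:
            if m <= 0:
                return m
            lm = math.log(m)
            return math.exp(lm + sd * lm * eps - 0.5 * (sd * lm) ** 2)

        return replace(
            self,
            rate_multiplier=jit(self.rate_multiplier),
            duration_multiplier=jit(self.duration_multiplier),
            cycle_freq_shift_hz=self.cycle_freq_shift_hz * (1.0 + sd * eps),
            band_amp_multipliers={b: jit(m) for b, m in self.band_amp_multipliers.items()},
        )


VEHICLE = DrugEffectModel(name="vehicle")


@dataclass(frozen=True)
class AnimalVariability:
    """Between-animal heterogeneity of baseline physiology and drug response."""

    rate_sd_log: float = 0.2
    duration_factor_sd_log: float = 0.15
    base_freq_sd_hz: float = 0.10
    exposure_sd_log: float = 0.10
    event_freq_sd_hz: float = 0.25


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to synthesize one animal-session."""

    design: SessionDesign = field(default_factory=SessionDesign)
    fs: float = 256.0
    shape: SwdShapeParams = field(default_factory=SwdShapeParams)
    process: SeizureProcessParams = field(default_factory=SeizureProcessParams)
    drug: DrugEffectModel = VEHICLE
    background_sd_uv: float = 50.0
    artifact_rate_per_min: float = 0.2
    artifact_duration_s: float = 0.4
    artifact_amp_factor: float = 10.0
    sleep: bool = True
    sleep_bout_offset_s: float = 840.0
    sleep_bout_len_s: float = 180.0
    spindle_period_s: float = 8.0
    spindle_duration_s: float = 0.8
    spindle_freq_hz: float = 12.0
    spindle_amp_factor: float = 3.0
    nonrem_delta_factor: float = 1.5  # extra delta amplitude added in non-REM
    variability: AnimalVariability = field(default_factory=AnimalVariability)


def sleep_intervals(config: SessionConfig) -> list[tuple[float, float]]:
    """Deterministic non-REM schedule: one bout per 20-min epoch.

    The same within-epoch phase in every epoch keeps the wake fraction
    identical across control and treatment, so state scheduling cancels out
    of all control-normalized seizure metrics.
    """
    if not config.sleep or config.sleep_bout_len_s <= 0:
        return []
    design = config.design
    out = []
    for idx in design.epochs:
        start, end = design.epoch_bounds(idx)
        s = start + config.sleep_bout_offset_s
        e = min(s + config.sleep_bout_len_s, end, design.treatment_end_s)
        if e > s and s < end:
            out.append((s, e))
    return out


def _in_intervals(t: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    hit = np.zeros(np.shape(t), dtype=bool)
    for s, e in intervals:
        hit |= (t >= s) & (t < e)
    return hit


# ---------------------------------------------------------------------------
# background


def _one_over_f_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise with power ~ 1/f above 1 Hz (flat below)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))
    spec *= shaping
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _band_component(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """FFT band-pass with 1 Hz raised-cosine edges."""
    n = x.size
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    w = np.zeros_like(f)
    w[(f >= lo) & (f <= hi)] = 1.0
    rise = (f > lo - 1.0) & (f < lo)
    w[rise] = 0.5 * (1 + np.cos(np.pi * (lo - f[rise])))
    fall = (f > hi) & (f < hi + 1.0)
    w[fall] = 0.5 * (1 + np.cos(np.pi * (f[fall] - hi)))
    return np.fft.irfft(spec * w, n=n)


def generate_background(
    duration_s: float,
    fs: float,
    seed: int | np.random.Generator,
    *,
    config: SessionConfig | None = None,
    t0: float = 0.0,
) -> tuple[Recording, EventList]:
    """Generate state-dependent background noise plus spindle annotations.

    Returns the background recording and an event list holding the sleep
    bouts and spindle bursts that were inserted.  Drug band-amplitude
    multipliers from ``config.drug`` are applied multiplicatively to the
    corresponding band-limited components, ramped with the drug kinetics.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    config = config or SessionConfig(fs=fs)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration_s * fs))
    x = _one_over_f_noise(n, fs, rng) * config.background_sd_uv
    t = t0 + np.arange(n) / fs

    # drug-scaled band components (flared so analysis bins see flat gain)
    for band, mult in config.drug.band_amp_multipliers.items():
        if mult == 1.0:
            continue
        lo, hi = ANALYSIS_BANDS[band]
        comp = _band_component(x, fs, max(lo - GAIN_FLARE_HZ, 0.0), hi + GAIN_FLARE_HZ)
        x += (config.drug.band_amp_mult(band, t) - 1.0) * comp

    events: list[Event] = []
    bouts = [
        (s, e)
        for s, e in sleep_intervals(config)
        if e > t0 and s < t0 + duration_s
    ]
    if bouts:
        sleeping = _in_intervals(t, bouts)
        extra_delta = _band_component(
            _one_over_f_noise(n, fs, rng) * config.background_sd_uv, fs, 0.5, 4.5
        )
        x += config.nonrem_delta_factor * extra_delta * sleeping
        for s, e in bouts:
            events.append(Event(round(max(s, t0), 3), round(min(e, t0 + duration_s), 3), "sleep"))
            # spindle bursts on a regular grid within the bout
            ts = np.arange(s + config.spindle_period_s / 2, e - config.spindle_duration_s,
                           config.spindle_period_s)
            for ss in ts:
                i0 = int(round((ss - t0) * fs))
                m = int(round(config.spindle_duration_s * fs))
                if i0 < 0 or i0 + m > n:
                    continue
                tt = np.arange(m) / fs
                env = np.sin(np.pi * tt / config.spindle_duration_s) ** 2
                burst = (
                    config.spindle_amp_factor
                    * config.background_sd_uv
                    * env
                    * np.sin(2 * np.pi * config.spindle_freq_hz * tt + rng.uniform(0, 2 * np.pi))
                )
                x[i0 : i0 + m] += burst
                events.append(Event(round(ss, 3), round(ss + config.spindle_duration_s, 3), "spindle"))

    rec = Recording(x[np.newaxis, :], fs=fs, channel_labels=["EEG1"], t0=t0)
    return rec, EventList(events)


# ---------------------------------------------------------------------------
# seizure point process


def sample_seizure_intervals(
    process: SeizureProcessParams,
    drug: DrugEffectModel,
    design: SessionDesign,
    seed: int | np.random.Generator,
    *,
    sleep: list[tuple[float, float]] | None = None,
) -> list[tuple[float, float]]:
    """Sample (start_s, duration_s) pairs over the session.

    Starts: inhomogeneous Poisson (rate ``rate_per_min * rate_mult(t)``,
    zero during sleep bouts) realized by thinning, with a non-paralyzable
    dead time covering each accepted seizure plus the refractory period.
    Durations: truncated gamma scaled by ``duration_mult`` at the start
    time.  No event crosses the session end (the last one is clipped).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sleep = sleep or []
    lam0 = process.rate_per_min / 60.0
    lam_max = lam0 * max(1.0, drug.rate_multiplier)
    t_start, t_end = design.control_start_s, design.treatment_end_s
    n_cand = rng.poisson(lam_max * (t_end - t_start))
    cand = np.sort(rng.uniform(t_start, t_end, size=n_cand))
    keep = rng.uniform(size=n_cand) < lam0 * np.asarray(drug.rate_mult(cand)) / lam_max
    cand = cand[keep]
    if sleep:
        cand = cand[~_in_intervals(cand, sleep)]

    if cand.size == 0:
        return []
    mults = np.maximum(np.asarray(drug.duration_mult(cand), dtype=float), 1e-9)
    durs = _sample_truncated_durations(rng, process, mults)
    out: list[tuple[float, float]] = []
    busy_until = -np.inf
    for t, d in zip(cand, durs):
        if t < busy_until:
            continue
        d = min(float(d), t_end - t)
        if d < process.duration_min_s:
            continue
        out.append((float(t), d))
        busy_until = t + d + process.refractory_s
    return out


# ---------------------------------------------------------------------------
# SWD waveform


def synthesize_swd(
    duration_s: float,
    shape: SwdShapeParams,
    fs: float,
    *,
    cycle_freq_hz: float | None = None,
) -> np.ndarray:
    """Concatenated spike-and-wave cycles with onset/offset amplitude ramps.

    The spike is a periodic von-Mises-shaped pulse (FWHM = ``spike_fraction``
    of a cycle) at the top of a sinusoidal wave; harmonic components are
    added at 2f and 3f.  Waveform length is ``round(duration_s * fs)``.
    """
    if duration_s < shape.ramp_s * 2 and duration_s < 1.0:
        raise ValueError("SWD duration must be at least 1 s")
    f = shape.cycle_freq_hz if cycle_freq_hz is None else cycle_freq_hz
    if f <= 0:
        raise ValueError("cycle frequency must be positive")
    n = int(round(duration_s * fs))
    phi = 2 * np.pi * f * np.arange(n) / fs

    kappa = (2.355 / (2 * np.pi * shape.spike_fraction)) ** 2
    pulse = np.exp(kappa * (np.cos(phi) - 1.0))
    # zero-mean, unit-peak periodic pulse; cycle mean is exp(-kappa) * I0(kappa)
    mean_pulse = float(special.i0e(kappa))
    pulse = (pulse - mean_pulse) / (1.0 - mean_pulse)

    x = shape.spike_amp_uv * pulse + shape.wave_amp_uv * np.cos(phi)
    for k, ratio in enumerate(shape.harmonics, start=2):
        x += ratio * shape.wave_amp_uv * np.cos(k * phi)

    if shape.ramp_s > 0:
        m = min(int(round(shape.ramp_s * fs)), n // 2)
        if m > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
            x[:m] *= ramp
            x[-m:] *= ramp[::-1]
    return x


# ---------------------------------------------------------------------------
# session assembly


def assemble_session(
    config: SessionConfig,
    seed: int | np.random.Generator,
) -> tuple[Recording, EventList]:
    """Synthesize a full animal-session: background + SWDs + artifacts.

    Returns the recording (t0 = control start) and the ground-truth event
    list.  For ground-truth ``swd`` events the ``mean_wavelet_freq_hz``
    column carries the true cycle frequency of the inserted waveform.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    design = config.design
    var = config.variability

    # per-animal physiology and drug exposure
    rate_factor = float(np.exp(rng.normal(0.0, var.rate_sd_log)))
    duration_factor = float(np.exp(rng.normal(0.0, var.duration_factor_sd_log)))
    base_freq = float(rng.normal(config.shape.cycle_freq_hz, var.base_freq_sd_hz))
    exposure_eps = float(rng.standard_normal())

    process = replace(
        config.process,
        rate_per_min=config.process.rate_per_min * rate_factor,
        duration_mean_s=config.process.duration_mean_s * duration_factor,
        duration_sd_s=config.process.duration_sd_s * duration_factor,
    )
    drug = config.drug.with_response_jitter(exposure_eps, var.exposure_sd_log)

    bouts = sleep_intervals(config)
    cfg = replace(config, drug=drug)
    recording, events = generate_background(
        design.duration_s, config.fs, rng, config=cfg, t0=design.control_start_s
    )
    x = recording.samples[0]
    n = x.size
    fs = config.fs

    gt: list[Event] = list(events)

    seizures = sample_seizure_intervals(process, drug, design, rng, sleep=bouts)
    for start, dur in seizures:
        f_ev = base_freq + float(drug.freq_shift(start)) + rng.normal(0.0, var.event_freq_sd_hz)
        f_ev = float(np.clip(f_ev, 5.2, 11.5))
        wave = synthesize_swd(dur, config.shape, fs, cycle_freq_hz=f_ev)
        i0 = int(round((start - design.control_start_s) * fs))
        i1 = min(i0 + wave.size, n)
        x[i0:i1] += wave[: i1 - i0]
        gt.append(
            Event(
                round(start, 3),
                round(start + dur, 3),
                "swd",
                mean_wavelet_freq_hz=round(f_ev, 4),
            )
        )

    # movement artifacts: broadband transients in wake, clear of seizures
    if config.artifact_rate_per_min > 0:
        lam = config.artifact_rate_per_min / 60.0
        n_art = rng.poisson(lam * design.duration_s)
        t_art = np.sort(rng.uniform(design.control_start_s, design.treatment_end_s - 1.0, n_art))
        t_art = t_art[~_in_intervals(t_art, bouts)]
        forbidden = [(s - 1.0, s + d + 1.0) for s, d in seizures]
        t_art = t_art[~_in_intervals(t_art, forbidden)]
        m = int(round(config.artifact_duration_s * fs))
        last_end = -np.inf
        for ta in t_art:
            if ta < last_end:
                continue
            last_end = ta + config.artifact_duration_s
            i0 = int(round((ta - design.control_start_s) * fs))
            if i0 < 0 or i0 + m > n:
                continue
            env = np.sin(np.pi * np.arange(m) / m) ** 2
            x[i0 : i0 + m] += (
                config.artifact_amp_factor
                * config.background_sd_uv
                * env
                * rng.standard_normal(m)
            )
            gt.append(Event(round(ta, 3), round(ta + config.artifact_duration_s, 3), "artifact"))

    return recording, EventList(gt)
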