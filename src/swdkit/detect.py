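"""Semi-automatic spike-and-wave-discharge detection.

Pipeline (order is load-bearing and regression-tested):

1. high-pass filter the trace (DC remove, 0.1 s time constant);
2. mean/SD over a baseline segment of awake, artifact-free control EEG
   (chosen automatically here; can be supplied explicitly);
3. threshold crossings at mean +/- k*SD (k in 5..9, default 6), one event
   per contiguous supra-threshold excursion of either polarity, collapsed
   over a 75 ms window so one spike-wave complex (spike plus wave trough)
   yields one peak while spikes of SWDs up to 12 Hz stay distinct;
4. grouping into putative SWDs: a group opens when two consecutive peaks
   are < 0.2 s apart and extends while gaps stay < 0.4 s;
5. amalgamation of putative SWDs < 0.5 s apart (iterated to fixed point);
6. discarding putative SWDs shorter than 1 s;
7. frequency criterion: instantaneous frequencies are reciprocals of
   consecutive peak intervals; an event is accepted iff >= 75% of them lie
   in 5-12 Hz (this is what rejects sleep spindles and residual artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .design import SessionDesign
from .io import Event, EventList, Recording, SampleMask, rasterize_mask

__all__ = [
    "DetectionParams",
    "BaselineStats",
    "PutativeSwd",
    "highpass_dc_remove",
    "baseline_stats",
    "auto_baseline",
    "detect_crossings",
    "group_crossings",
    "amalgamate",
    "duration_filter",
    "frequency_criterion",
    "detect_swds",
    "match_events",
]


@dataclass(frozen=True)
class DetectionParams:
    hp_time_constant_s: float = 0.1
    threshold_sd: float = 6.0
    max_onset_interval_s: float = 0.2
    max_continuation_interval_s: float = 0.4
    amalgamation_gap_s: float = 0.5
    min_duration_s: float = 1.0
    freq_band_hz: tuple[float, float] = (5.0, 12.0)
    min_fraction_in_band: float = 0.75
    peak_collapse_window_s: float = 0.075

    def __post_init__(self) -> None:
        if not 5.0 <= self.threshold_sd <= 9.0:
            raise ValueError("threshold_sd must lie in [5, 9]")
        if not 0.0 < self.min_fraction_in_band <= 1.0:
            raise ValueError("min_fraction_in_band must lie in (0, 1]")
        if self.max_onset_interval_s > self.max_continuation_interval_s:
            raise ValueError("max onset interval cannot exceed max continuation interval")


@dataclass(frozen=True)
class BaselineStats:
    start_s: float
    end_s: float
    mean_uv: float
    sd_uv: float

    def __post_init__(self) -> None:
        if self.sd_uv <= 0:
            raise ValueError("degenerate baseline: SD must be positive")


@dataclass
class PutativeSwd:
    start_s: float
    end_s: float
    peak_times_s: np.ndarray
    instantaneous_freqs_hz: np.ndarray = field(default_factory=lambda: np.empty(0))
    frac_in_band: float = np.nan
    accepted: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times_s)


def highpass_dc_remove(x: np.ndarray, fs: float, tau_s: float = 0.1) -> np.ndarray:
    """First-order DC-remove: subtract an exponential running mean.

    Equivalent to an RC high-pass with cutoff 1/(2*pi*tau) ~ 1.6 Hz at the
    default 0.1 s time constant.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    a = 1.0 - np.exp(-1.0 / (fs * tau_s))
    running_mean = signal.lfilter([a], [1.0, a - 1.0], np.asarray(x, dtype=float))
    return x - running_mean


def baseline_stats(
    x: np.ndarray,
    fs: float,
    interval: tuple[float, float],
    *,
    t0: float = 0.0,
    min_duration_s: float = 10.0,
) -> BaselineStats:
    """Mean and SD of the (already filtered) signal over a time interval."""
    start, end = interval
    if end - start < min_duration_s:
        raise ValueError(f"baseline interval must span at least {min_duration_s} s")
    i0 = int(np.floor((start - t0) * fs + 1e-9))
    i1 = int(np.floor((end - t0) * fs + 1e-9))
    if i0 < 0 or i1 > x.size:
        raise ValueError("baseline interval outside recording")
    seg = x[i0:i1]
    sd = float(seg.std())
    return BaselineStats(start, end, float(seg.mean()), sd)


def auto_baseline(
    recording: Recording,
    events: EventList,
    design: SessionDesign,
    *,
    min_s: float = 60.0,
    cap_s: float = 120.0,
    exclude_labels: tuple[str, ...] = ("swd", "artifact", "sleep", "spindle"),
) -> tuple[float, float]:
    """Deterministic stand-in for the manual baseline selection.

    Returns the longest unmasked wake interval within the control period
    (ties broken toward the earliest), truncated to ``cap_s``.  Raises when
    no eligible interval of at least ``min_s`` exists, in which case a
    baseline must be supplied explicitly.
    """
    mask = rasterize_mask(events, exclude_labels, recording)
    t_lo = max(design.control_start_s, recording.t0)
    t_hi = min(design.injection_s, recording.t0 + recording.duration_s)
    i0 = recording.index_of(t_lo)
    i1 = recording.index_of(t_hi)
    free = ~mask.mask[i0:i1]
    if free.size == 0 or not free.any():
        raise ValueError("no eligible baseline interval in control period; pass one explicitly")
    edges = np.diff(free.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if free[0]:
        starts = np.r_[0, starts]
    if free[-1]:
        ends = np.r_[ends, free.size]
    lengths = ends - starts
    best = int(np.argmax(lengths))
    if lengths[best] / recording.fs < min_s:
        raise ValueError("no artifact/seizure-free control segment of sufficient length; pass one explicitly")
    start_t = t_lo + starts[best] / recording.fs
    end_t = min(start_t + cap_s, t_lo + ends[best] / recording.fs)
    return (start_t, end_t)


def detect_crossings(
    x: np.ndarray,
    fs: float,
    baseline: BaselineStats,
    k: float,
    *,
    t0: float = 0.0,
    collapse_window_s: float = 0.075,
) -> np.ndarray:
    """Onset times of supra-threshold excursions, collapsed per complex.

    An excursion is a contiguous run of samples above mean + k*SD or below
    mean - k*SD; each contributes one event at its onset.  Events of either
    polarity within ``collapse_window_s`` of the previously kept event are
    collapsed into it.
    """
    hi = baseline.mean_uv + k * baseline.sd_uv
    lo = baseline.mean_uv - k * baseline.sd_uv
    onsets = []
    for cond in (x > hi, x < lo):
        c = np.asarray(cond)
        idx = np.flatnonzero(c & ~np.r_[False, c[:-1]])
        onsets.append(idx)
    merged = np.sort(np.concatenate(onsets)) / fs + t0
    if merged.size == 0 or collapse_window_s <= 0:
        return merged
    kept = [merged[0]]
    for tm in merged[1:]:
        if tm - kept[-1] >= collapse_window_s:
            kept.append(tm)
    return np.asarray(kept)


def group_crossings(
    peak_times: np.ndarray,
    max_onset_s: float = 0.2,
    max_continuation_s: float = 0.4,
    *,
    collapse_window_s: float = 0.075,
) -> list[PutativeSwd]:
    """Group collapsed peaks into putative SWDs.

    A putative SWD opens when two consecutive peaks are < ``max_onset_s``
    apart; further peaks join while each gap is < ``max_continuation_s``.
    Event extent spans first to last joined peak, extended by half the
    collapse window on each side.
    """
    peaks = np.sort(np.asarray(peak_times, dtype=float))
    half = collapse_window_s / 2.0
    out: list[PutativeSwd] = []
    i = 0
    n = peaks.size
    while i < n - 1:
        if peaks[i + 1] - peaks[i] < max_onset_s:
            j = i + 1
            while j + 1 < n and peaks[j + 1] - peaks[j] < max_continuation_s:
                j += 1
            out.append(
                PutativeSwd(
                    start_s=peaks[i] - half,
                    end_s=peaks[j] + half,
                    peak_times_s=peaks[i : j + 1].copy(),
                )
            )
            i = j + 1
        else:
            i += 1
    return out


def amalgamate(putatives: list[PutativeSwd], gap_s: float = 0.5) -> list[PutativeSwd]:
    """Merge putative SWDs separated by less than ``gap_s``; iterated to a fixed point."""
    current = sorted(putatives, key=lambda p: p.start_s)
    while True:
        merged: list[PutativeSwd] = []
        changed = False
        for p in current:
            if merged and p.start_s - merged[-1].end_s < gap_s:
                prev = merged[-1]
                merged[-1] = PutativeSwd(
                    start_s=prev.start_s,
                    end_s=max(prev.end_s, p.end_s),
                    peak_times_s=np.concatenate([prev.peak_times_s, p.peak_times_s]),
                )
                changed = True
            else:
                merged.append(p)
        current = merged
        if not changed:
            return current


def duration_filter(putatives: list[PutativeSwd], min_s: float = 1.0) -> list[PutativeSwd]:
    """Keep putative SWDs whose duration is at least ``min_s`` (boundary inclusive)."""
    return [p for p in putatives if p.duration_s >= min_s]


def frequency_criterion(
    putative: PutativeSwd,
    band: tuple[float, float] = (5.0, 12.0),
    min_frac: float = 0.75,
) -> PutativeSwd:
    """Apply the instantaneous-frequency acceptance criterion in place.

    Instantaneous frequencies are 1 / (interval between consecutive peaks);
    the event is accepted iff the fraction inside ``band`` (inclusive) is at
    least ``min_frac``.  Events with < 2 peaks are rejected with fraction
    recorded as 0.
    """
    peaks = np.asarray(putative.peak_times_s)
    if peaks.size < 2:
        putative.instantaneous_freqs_hz = np.empty(0)
        putative.frac_in_band = 0.0
        putative.accepted = False
        return putative
    freqs = 1.0 / np.diff(np.sort(peaks))
    frac = float(np.mean((freqs >= band[0]) & (freqs <= band[1])))
    putative.instantaneous_freqs_hz = freqs
    putative.frac_in_band = frac
    putative.accepted = frac >= min_frac
    return putative


def detect_swds(
    recording: Recording,
    params: DetectionParams | None = None,
    baseline: BaselineStats | tuple[float, float] | None = None,
    *,
    channel: int = 0,
    ground_truth: EventList | None = None,
    design: SessionDesign | None = None,
    return_report: bool = False,
):
    """Run the full detection pipeline on one channel.

    ``baseline`` may be precomputed stats, a (start_s, end_s) interval, or
    None, in which case the baseline segment is chosen automatically from
    ``ground_truth`` annotations over the control period of ``design``.
    Returns an :class:`EventList` of accepted SWDs (and a stage-count report
    when ``return_report`` is set).
    """
    params = params or DetectionParams()
    x = highpass_dc_remove(recording.channel(channel), recording.fs, params.hp_time_constant_s)
    if baseline is None:
        if ground_truth is None or design is None:
            raise ValueError("either a baseline or (ground_truth, design) must be given")
        baseline = auto_baseline(recording, ground_truth, design)
    if not isinstance(baseline, BaselineStats):
        baseline = baseline_stats(x, recording.fs, tuple(baseline), t0=recording.t0)

    peaks = detect_crossings(
        x,
        recording.fs,
        baseline,
        params.threshold_sd,
        t0=recording.t0,
        collapse_window_s=params.peak_collapse_window_s,
    )
    grouped = group_crossings(
        peaks,
        params.max_onset_interval_s,
        params.max_continuation_interval_s,
        collapse_window_s=params.peak_collapse_window_s,
    )
    merged = amalgamate(grouped, params.amalgamation_gap_s)
    long_enough = duration_filter(merged, params.min_duration_s)
    judged = [
        frequency_criterion(p, params.freq_band_hz, params.min_fraction_in_band)
        for p in long_enough
    ]
    events = EventList(
        [
            Event(
                start_s=round(p.start_s, 3),
                end_s=round(p.end_s, 3),
                label="swd",
                n_peaks=p.n_peaks,
                frac_in_band=round(p.frac_in_band, 4),
                accepted=True,
            )
            for p in judged
            if p.accepted
        ]
    )
    if not return_report:
        return events
    report = {
        "baseline": {
            "start_s": baseline.start_s,
            "end_s": baseline.end_s,
            "mean_uv": baseline.mean_uv,
            "sd_uv": baseline.sd_uv,
        },
        "threshold_sd": params.threshold_sd,
        "n_crossing_peaks": int(len(peaks)),
        "n_putative": len(grouped),
        "n_amalgamated": len(merged),
        "n_min_duration": len(long_enough),
        "n_accepted": len(events),
    }
    return events, report


def match_events(
    detected: EventList,
    truth: EventList,
    *,
    iou_threshold: float = 0.5,
    min_truth_duration_s: float = 0.0,
) -> dict:
    """Greedy IoU matching of detected vs ground-truth SWDs.

    Returns precision/recall plus per-match onset/offset errors.  Each truth
    event can absorb at most one detection and vice versa; candidate pairs
    are taken in decreasing IoU order.  ``min_truth_duration_s`` excludes
    ground-truth events too short for the detector's own duration filter
    from the recall denominator (they still absorb matching detections).
    """
    det = [e for e in detected if e.label == "swd"]
    tru = [e for e in truth if e.label == "swd"]
    pairs = []
    for i, d in enumerate(det):
        for j, g in enumerate(tru):
            inter = min(d.end_s, g.end_s) - max(d.start_s, g.start_s)
            if inter <= 0:
                continue
            union = max(d.end_s, g.end_s) - min(d.start_s, g.start_s)
            iou = inter / union
            if iou >= iou_threshold:
                pairs.append((iou, i, j))
    pairs.sort(reverse=True)
    used_d, used_t, matches = set(), set(), []
    for iou, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matches.append((i, j, iou))
    n_match = len(matches)
    eligible = [
        j for j, g in enumerate(tru) if g.duration_s >= min_truth_duration_s
    ]
    n_matched_eligible = len(used_t.intersection(eligible))
    precision = n_match / len(det) if det else float("nan")
    recall = n_matched_eligible / len(eligible) if eligible else float("nan")
    onset_err = [abs(det[i].start_s - tru[j].start_s) for i, j, _ in matches]
    offset_err = [abs(det[i].end_s - tru[j].end_s) for i, j, _ in matches]
    return {
        "n_detected": len(det),
        "n_truth": len(tru),
        "n_matched": n_match,
        "precision": precision,
        "recall": recall,
        "median_onset_error_s": float(np.median(onset_err)) if onset_err else float("nan"),
        "median_offset_error_s": float(np.median(offset_err)) if offset_err else float("nan"),
        "matches": matches,
    }
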