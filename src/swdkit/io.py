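"""Readers and writers for recordings, event lists, masks and configs.

Signal format
-------------
The native on-disk format is a float32 little-endian binary (``.dat``,
channel-major) with a JSON sidecar (same stem, ``.json``) carrying ``fs``,
``channel_labels``, ``t0`` and the array shape.  EDF files can be read when
:mod:`mne` is installed (``pip install swdkit[edf]``); EDF writing is not
supported.

Event format
------------
Events (seizures, spindles, artifacts, sleep bouts) travel as CSV with the
header ``start_s,end_s,label,n_peaks,frac_in_band,mean_wavelet_freq_hz,
accepted``.  Times are stored at 1 ms resolution.  Intervals are half-open
``[start_s, end_s)`` in session time, a convention shared by every module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import SessionDesign

__all__ = [
    "Recording",
    "Event",
    "EventList",
    "SampleMask",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "rasterize_mask",
    "load_config",
    "save_config",
]

EVENT_COLUMNS = [
    "start_s",
    "end_s",
    "label",
    "n_peaks",
    "frac_in_band",
    "mean_wavelet_freq_hz",
    "accepted",
]

VALID_LABELS = frozenset({"swd", "spindle", "artifact", "sleep"})


@dataclass
class Recording:
    """Continuous EEG: microvolt samples, sampling rate and session timeline.

    ``t0`` is the session time of the first sample; with the standard
    protocol it equals -2400 s (start of the 40-min control period).
    """

    samples: np.ndarray  # (n_channels, n_samples) float64, microvolts
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite (no NaN/Inf)")
        if not self.channel_labels:
            self.channel_labels = [f"EEG{i + 1}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, index: int = 0) -> np.ndarray:
        return self.samples[index]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def index_of(self, t: float) -> int:
        """Sample index holding session time ``t`` (floor convention)."""
        return int(np.floor((t - self.t0) * self.fs + 1e-9))


@dataclass(frozen=True)
class Event:
    start_s: float
    end_s: float
    label: str = "swd"
    n_peaks: int | None = None
    frac_in_band: float | None = None
    mean_wavelet_freq_hz: float | None = None
    accepted: bool | None = None

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"event must have start_s < end_s, got {self.start_s}, {self.end_s}")
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


class EventList:
    """Ordered list of labeled half-open intervals.

    After finalization events are sorted by start time and events sharing a
    label never overlap.
    """

    def __init__(self, events: Iterable[Event] = (), validate: bool = True):
        self.events: list[Event] = sorted(events, key=lambda e: (e.start_s, e.end_s))
        if validate:
            self._validate()

    def _validate(self) -> None:
        last_end: dict[str, float] = {}
        for ev in self.events:
            if ev.label in last_end and ev.start_s < last_end[ev.label] - 1e-9:
                raise ValueError(
                    f"overlapping {ev.label!r} events at t={ev.start_s:.3f}"
                )
            last_end[ev.label] = max(last_end.get(ev.label, -np.inf), ev.end_s)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def with_label(self, *labels: str) -> "EventList":
        return EventList([e for e in self.events if e.label in labels], validate=False)

    def accepted(self) -> "EventList":
        return EventList([e for e in self.events if e.accepted], validate=False)

    def durations(self) -> np.ndarray:
        return np.array([e.duration_s for e in self.events])

    def starts(self) -> np.ndarray:
        return np.array([e.start_s for e in self.events])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "start_s": round(e.start_s, 3),
                "end_s": round(e.end_s, 3),
                "label": e.label,
                "n_peaks": e.n_peaks,
                "frac_in_band": e.frac_in_band,
                "mean_wavelet_freq_hz": e.mean_wavelet_freq_hz,
                "accepted": e.accepted,
            }
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)


@dataclass
class SampleMask:
    """Boolean exclusion mask aligned to a recording timeline.

    ``mask[i]`` is True when sample ``i`` is excluded.  ``provenance`` lists
    the event labels that were rasterized into the mask.
    """

    mask: np.ndarray
    fs: float
    t0: float
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.mask.size

    def fraction_masked(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    def __or__(self, other: "SampleMask") -> "SampleMask":
        if self.mask.size != other.mask.size:
            raise ValueError("mask lengths differ")
        return SampleMask(
            self.mask | other.mask,
            self.fs,
            self.t0,
            tuple(dict.fromkeys(self.provenance + other.provenance)),
        )


# ---------------------------------------------------------------------------
# recordings


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a recording as float32 binary plus JSON sidecar; returns .dat path."""
    path = Path(path)
    if path.suffix == ".edf":
        raise ValueError("EDF writing is not supported; use the .dat native format")
    dat = path.with_suffix(".dat")
    recording.samples.astype("<f4").tofile(dat)
    header = {
        "fs": recording.fs,
        "channel_labels": recording.channel_labels,
        "t0": recording.t0,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "dtype": "<f4",
    }
    dat.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return dat


def read_recording(path: str | Path) -> Recording:
    """Read an EDF (via mne, if installed) or native .dat/.json recording."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    header_path = path.with_suffix(".json")
    if not header_path.exists():
        raise ValueError(f"missing sidecar header {header_path}")
    try:
        header = json.loads(header_path.read_text())
        fs = float(header["fs"])
        n_channels = int(header["n_channels"])
        n_samples = int(header["n_samples"])
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"unreadable sidecar header {header_path}: {exc}") from exc
    raw = np.fromfile(path, dtype=header.get("dtype", "<f4"))
    if raw.size != n_channels * n_samples:
        raise ValueError(
            f"{path}: expected {n_channels}x{n_samples} samples, found {raw.size}"
            " (mismatched channel lengths or truncated file)"
        )
    samples = raw.reshape(n_channels, n_samples).astype(float)
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"{path}: non-finite samples")
    return Recording(
        samples,
        fs=fs,
        channel_labels=list(header.get("channel_labels", [])),
        t0=float(header.get("t0", 0.0)),
    )


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF requires mne; install swdkit[edf] or use the native format"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(samples, fs=float(raw.info["sfreq"]), channel_labels=list(raw.ch_names))


# ---------------------------------------------------------------------------
# events


def write_events(events: EventList, path: str | Path) -> Path:
    path = Path(path)
    events._validate()
    events.to_frame().to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> EventList:
    """Read an event CSV; rows are sorted by start time on the way in."""
    df = pd.read_csv(Path(path))
    missing = {"start_s", "end_s", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"event file {path} lacks columns {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            Event(
                start_s=round(float(row.start_s), 3),
                end_s=round(float(row.end_s), 3),
                label=str(row.label),
                n_peaks=None if _isna(getattr(row, "n_peaks", None)) else int(row.n_peaks),
                frac_in_band=None
                if _isna(getattr(row, "frac_in_band", None))
                else float(row.frac_in_band),
                mean_wavelet_freq_hz=None
                if _isna(getattr(row, "mean_wavelet_freq_hz", None))
                else float(row.mean_wavelet_freq_hz),
                accepted=None
                if _isna(getattr(row, "accepted", None))
                else bool(row.accepted),
            )
        )
    return EventList(events)


def _isna(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


# ---------------------------------------------------------------------------
# masks


def rasterize_mask(
    events: EventList | Sequence[Event],
    labels: Sequence[str],
    recording: Recording,
) -> SampleMask:
    """Mask every sample whose time falls in ``[start_s, end_s)`` of a labeled event.

    Events extending beyond the recording span are clipped.
    """
    labels = tuple(labels)
    mask = np.zeros(recording.n_samples, dtype=bool)
    t_end = recording.t0 + recording.n_samples / recording.fs
    for ev in events:
        if ev.label not in labels:
            continue
        if ev.end_s <= recording.t0 or ev.start_s >= t_end:
            continue
        i0 = max(recording.index_of(max(ev.start_s, recording.t0)), 0)
        i1 = min(recording.index_of(min(ev.end_s, t_end)), recording.n_samples)
        mask[i0:i1] = True
    return SampleMask(mask, recording.fs, recording.t0, provenance=labels)


# ---------------------------------------------------------------------------
# configs


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text) or {}
    if path.suffix == ".json":
        return json.loads(text)
    raise ValueError(f"unsupported config format {path.suffix!r}")


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(config, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(config, indent=1))
    else:
        raise ValueError(f"unsupported config format {path.suffix!r}")
    return path


def design_from_config(config: dict) -> SessionDesign:
    """Build a :class:`SessionDesign` from a (possibly partial) config dict."""
    kwargs = {
        k: config[k]
        for k in (
            "control_start_s",
            "injection_s",
            "antagonist_injection_s",
            "treatment_end_s",
            "epoch_length_s",
        )
        if k in config
    }
    return SessionDesign(**kwargs)


# convenience re-export for modules that mutate events
def replace_event(event: Event, **changes) -> Event:
    return replace(event, **changes)
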