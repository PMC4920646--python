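"""Session timeline bookkeeping.

Session time is measured in seconds with the injection of the agonist (or
vehicle) at t = 0.  The standard protocol is a 40-min control period
(two 20-min epochs, t in [-2400, 0)) followed by a 2-h treatment period
(six 20-min epochs, t in [0, 7200)).  An optional antagonist injection
occurs 10 min before the end of the control period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SessionDesign"]


@dataclass(frozen=True)
class SessionDesign:
    """Timing of the control/treatment protocol and the 20-min epoch grid.

    Epochs are indexed -2, -1 (control) and 0..5 (treatment); epoch ``i``
    spans ``[i * epoch_length_s, (i + 1) * epoch_length_s)`` in session time.
    """

    control_start_s: float = -2400.0
    injection_s: float = 0.0
    antagonist_injection_s: float | None = -600.0
    treatment_end_s: float = 7200.0
    epoch_length_s: float = 1200.0

    def __post_init__(self) -> None:
        n_ctrl = (self.injection_s - self.control_start_s) / self.epoch_length_s
        n_trt = (self.treatment_end_s - self.injection_s) / self.epoch_length_s
        if abs(n_ctrl - round(n_ctrl)) > 1e-9 or abs(n_trt - round(n_trt)) > 1e-9:
            raise ValueError("epoch boundaries must align with the epoch length")
        if n_ctrl <= 0 or n_trt <= 0:
            raise ValueError("control and treatment windows must be non-empty")

    @property
    def n_control_epochs(self) -> int:
        return int(round((self.injection_s - self.control_start_s) / self.epoch_length_s))

    @property
    def n_treatment_epochs(self) -> int:
        return int(round((self.treatment_end_s - self.injection_s) / self.epoch_length_s))

    @property
    def duration_s(self) -> float:
        return self.treatment_end_s - self.control_start_s

    @property
    def control_epochs(self) -> list[int]:
        return list(range(-self.n_control_epochs, 0))

    @property
    def treatment_epochs(self) -> list[int]:
        return list(range(self.n_treatment_epochs))

    @property
    def epochs(self) -> list[int]:
        return self.control_epochs + self.treatment_epochs

    def epoch_bounds(self, index: int) -> tuple[float, float]:
        """Half-open ``[start, end)`` session-time bounds of epoch ``index``."""
        if index not in self.epochs:
            raise ValueError(f"epoch index {index} outside session window")
        start = self.injection_s + index * self.epoch_length_s
        return start, start + self.epoch_length_s

    def epoch_of(self, t: float | np.ndarray) -> np.ndarray:
        """Epoch index for session time(s) ``t``.

        Times outside the session window map to the sentinel
        ``numpy.iinfo(int).min`` so every in-window time maps to exactly one
        epoch and out-of-window times to none.
        """
        t = np.asarray(t, dtype=float)
        idx = np.floor((t - self.injection_s) / self.epoch_length_s).astype(int)
        out = (t < self.control_start_s) | (t >= self.treatment_end_s)
        idx = np.where(out, np.iinfo(int).min, idx)
        return idx
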