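"""Uniformly sampled physiological traces shared by the cardiac and pupil pipelines."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SignalQualityError(ValueError):
    """Raised when a recording is unusable (flat signal, too few beats, ...)."""


@dataclass
class PhysioTrace:
    """A uniformly sampled 1-D physiological signal.

    ``channel`` is ``"ppg"`` (pulse-oximetry waveform) or ``"pupil"``
    (pupil diameter).  ``valid`` marks samples usable for analysis; tracker
    dropouts and blink-padding are flagged invalid rather than removed so the
    time base stays uniform.  ``start_time_s`` is the time of the first sample
    on the shared experiment clock (seconds from scan start).
    """

    samples: np.ndarray
    fs_hz: float
    channel: str = "ppg"
    valid: np.ndarray | None = None
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.channel not in ("ppg", "pupil"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.valid is None:
            self.valid = np.ones(self.samples.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.samples.shape:
                raise ValueError("valid mask must align with samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + (self.n_samples - 1) / self.fs_hz

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.fs_hz

    def window_indices(self, t0: float, t1: float, *, closed: str = "left") -> np.ndarray:
        """Indices of samples with time in the requested window.

        ``closed="left"`` selects [t0, t1); ``closed="right"`` selects (t0, t1].
        A half-sample tolerance absorbs floating-point onset rounding.
        """
        t = self.times()
        eps = 0.5 / self.fs_hz * 1e-6
        if closed == "left":
            m = (t >= t0 - eps) & (t < t1 - eps)
        elif closed == "right":
            m = (t > t0 + eps) & (t <= t1 + eps)
        else:
            raise ValueError("closed must be 'left' or 'right'")
        return np.nonzero(m)[0]
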