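"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["PupilTrace", "EpochSet", "ContSignal", "PLRMetrics"]


@dataclass
class PupilTrace:
    """Timestamped monocular pupil samples with a missing-data mask.

    ``pupil`` is finite wherever ``missing`` is False; missing samples may
    be NaN.  ``time`` is strictly increasing.
    """

    time: np.ndarray
    pupil: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (self.time.shape == self.pupil.shape == self.missing.shape):
            raise ValueError("time, pupil and missing must have equal shape")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(~np.isfinite(self.pupil[~self.missing])):
            raise ValueError("pupil must be finite where not missing")

    @property
    def rate(self) -> float:
        """Nominal sampling rate (Hz) from the median sample interval."""
        if self.time.size < 2:
            raise ValueError("rate undefined for <2 samples")
        return 1.0 / float(np.median(np.diff(self.time)))

    def copy(self) -> "PupilTrace":
        return PupilTrace(self.time.copy(), self.pupil.copy(), self.missing.copy())


@dataclass
class EpochSet:
    """Per-trial windows sharing a single time axis.

    ``data`` is (n_trials, n_times) for pupil epochs or
    (n_channels, n_trials, n_times) for multichannel signals.  ``labels``
    carries one row per trial (condition factors, subject id).  ``rejected``
    flags trials excluded from analysis; ``reasons`` explains why.
    """

    data: np.ndarray
    times: np.ndarray
    labels: pd.DataFrame
    missing: Optional[np.ndarray] = None
    rejected: Optional[np.ndarray] = None
    reasons: Optional[list] = None
    baselines: Optional[np.ndarray] = None
    channels: Optional[list] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        n = self.n_trials
        if len(self.labels) != n:
            raise ValueError("labels must have one row per trial")
        if self.rejected is None:
            self.rejected = np.zeros(n, dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.reasons is None:
            self.reasons = [""] * n

    @property
    def n_trials(self) -> int:
        return self.data.shape[-2]

    @property
    def n_times(self) -> int:
        return self.data.shape[-1]

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    def retained(self) -> np.ndarray:
        return ~self.rejected


@dataclass
class ContSignal:
    """Uniformly sampled multichannel recording with pulse markers."""

    time: np.ndarray
    channels: pd.DataFrame          # one column per channel
    rate: float
    markers: np.ndarray = field(default_factory=lambda: np.empty(0))
    missing: Optional[np.ndarray] = None   # (n_samples,) mask shared by channels

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.markers = np.asarray(self.markers, dtype=float)
        if len(self.channels) != self.time.size:
            raise ValueError("channel length must match time axis")
        if self.markers.size and (
            self.markers.min() < self.time[0] or self.markers.max() > self.time[-1]
        ):
            raise ValueError("markers must lie within the recording")
        if self.missing is None:
            self.missing = np.zeros(self.time.size, dtype=bool)

    @property
    def channel_names(self) -> list:
        return list(self.channels.columns)

    def values(self) -> np.ndarray:
        """(n_channels, n_samples) array view of the channel data."""
        return self.channels.to_numpy().T


@dataclass(frozen=True)
class PLRMetrics:
    """Kinematic parameters of one averaged pupillary light reflex."""

    onset_latency_ms: float
    peak_constriction_amplitude: float      # z-units, negative
    t_peak_constriction_ms: float
    peak_constriction_velocity: float       # z/s, negative
    avg_constriction_velocity: float        # z/s, negative
    peak_dilation_velocity: float           # z/s, positive
    avg_dilation_velocity: float            # z/s

    def __post_init__(self) -> None:
        if not self.onset_latency_ms < self.t_peak_constriction_ms:
            raise ValueError("onset must precede peak constriction")

    def as_dict(self) -> dict:
        return {
            "onset_latency_ms": self.onset_latency_ms,
            "peak_constriction_amplitude": self.peak_constriction_amplitude,
            "t_peak_constriction_ms": self.t_peak_constriction_ms,
            "peak_constriction_velocity": self.peak_constriction_velocity,
            "avg_constriction_velocity": self.avg_constriction_velocity,
            "peak_dilation_velocity": self.peak_dilation_velocity,
            "avg_dilation_velocity": self.avg_dilation_velocity,
        }
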