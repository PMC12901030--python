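"""Shared in-memory containers for epoched sensor data and gaze records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EpochSet:
    """Epoched multichannel recordings.

    Attributes
    ----------
    data : array, shape (trials, sensors, time)
    fs : sampling rate, Hz
    t0 : time of the first sample relative to the alignment event, seconds
    meta : per-trial metadata (one row per trial)
    """

    data: np.ndarray
    fs: float
    t0: float
    meta: pd.DataFrame
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, sensors, time)")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError(
                f"meta has {len(self.meta)} rows for {self.data.shape[0]} trials"
            )
        if self.channel_names is None:
            self.channel_names = [f"S{i:03d}" for i in range(self.data.shape[1])]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def time_mask(self, t_start: float, t_stop: float) -> np.ndarray:
        """Boolean sample mask for ``t_start <= t < t_stop``."""
        t = self.times
        return (t >= t_start) & (t < t_stop)


@dataclass
class GazeRecord:
    """Gaze position (degrees visual angle) and pupil traces per trial.

    ``planted_saccade_times`` holds the generator's ground truth: one
    array of onset times (seconds, relative to ``t0``) per trial.
    """

    x: np.ndarray            # (trials, time), degrees
    y: np.ndarray            # (trials, time), degrees
    pupil: np.ndarray        # (trials, time), arbitrary units
    fs: float
    t0: float = 0.0
    planted_saccade_times: list[np.ndarray] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.x.shape[0]

    @property
    def n_samples(self) -> int:
        return self.x.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs
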