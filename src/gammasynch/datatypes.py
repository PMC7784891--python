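"""Core in-memory containers shared across the analysis modules.

Conventions
-----------
* Times are seconds, LFP samples are microvolts (or z units after
  normalization), currents are picoamperes with inhibitory events stored
  as positive deflections.
* Trial-structured LFP is aligned so that t = 0 is click-train onset and
  the stimulus occupies the half-open interval [0, stim_duration).
* The tidy metric table used for aggregation and reporting has the fixed
  columns ``condition, subject, channel, metric, value``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

METRIC_COLUMNS = ("condition", "subject", "channel", "metric", "value")


@dataclass
class LFPTrialSet:
    """Trial-aligned LFP segments plus the stimulus-free reference epochs.

    Attributes
    ----------
    sample_rate : float
        Sampling rate in Hz, shared by every stored segment.
    trials : ndarray, shape (n_trials, n_samples)
        LFP covering ``trial_window`` around each click-train onset.
    mid_isi : ndarray, shape (n_trials, n_mid_samples)
        200-ms spontaneous segment taken at the mid-point of the
        inter-stimulus interval preceding each trial.
    prestim : ndarray, 1-D
        Continuous LFP record preceding the first click train (>= 10 s
        for baseline-power analysis; also the z-scoring reference).
    stim_onsets : ndarray
        Onset times of each click train in session time (s).
    trial_window : tuple(float, float)
        Time span of each trial row relative to onset, default (-0.5, 1.0).
    stim_duration : float
        Click-train duration in seconds (0.5 s).
    zscored : bool
        Whether the set has been normalized by the pre-stimulus record.
    """

    sample_rate: float
    trials: np.ndarray
    mid_isi: np.ndarray
    prestim: np.ndarray
    stim_onsets: np.ndarray
    trial_window: tuple[float, float] = (-0.5, 1.0)
    stim_duration: float = 0.5
    subject_id: str = "sim"
    channel_id: str = "ch0"
    zscored: bool = False

    def __post_init__(self) -> None:
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        self.mid_isi = np.atleast_2d(np.asarray(self.mid_isi, dtype=float))
        self.prestim = np.asarray(self.prestim, dtype=float).ravel()
        self.stim_onsets = np.asarray(self.stim_onsets, dtype=float).ravel()
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.trial_window[1] <= self.trial_window[0]:
            raise ValueError("trial_window must be increasing")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Per-sample times of a trial row, relative to stimulus onset."""
        n = self.trials.shape[1]
        return self.trial_window[0] + np.arange(n) / self.sample_rate


@dataclass
class SpikeTrainPair:
    """Two sorted spike-time sequences recorded on the same tetrode."""

    times_a: np.ndarray
    times_b: np.ndarray
    duration: float
    unit_ids: tuple[str, str] = ("unit_a", "unit_b")

    def __post_init__(self) -> None:
        self.times_a = np.asarray(self.times_a, dtype=float).ravel()
        self.times_b = np.asarray(self.times_b, dtype=float).ravel()
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name, t in (("times_a", self.times_a), ("times_b", self.times_b)):
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ValueError(f"{name} outside [0, duration]")
            if np.any(np.diff(t) < 0):
                raise ValueError(f"{name} must be sorted")


@dataclass
class IPSCEventTrains:
    """Per-cell sIPSC event times (s) and amplitudes (pA) for one pair."""

    times_a: np.ndarray
    times_b: np.ndarray
    amps_a: np.ndarray
    amps_b: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times_a = np.asarray(self.times_a, dtype=float).ravel()
        self.times_b = np.asarray(self.times_b, dtype=float).ravel()
        self.amps_a = np.asarray(self.amps_a, dtype=float).ravel()
        self.amps_b = np.asarray(self.amps_b, dtype=float).ravel()
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.times_a.size != self.amps_a.size or self.times_b.size != self.amps_b.size:
            raise ValueError("each event needs exactly one amplitude")
        for name, t in (("times_a", self.times_a), ("times_b", self.times_b)):
            if np.any(np.diff(t) < 0):
                raise ValueError(f"{name} must be sorted")
        if (self.amps_a.size and self.amps_a.min() <= 0) or (
            self.amps_b.size and self.amps_b.min() <= 0
        ):
            raise ValueError("amplitudes must be positive")


@dataclass
class PairedTraces:
    """Simultaneous voltage-clamp current traces from two cells (pA)."""

    sample_rate: float
    current_a: np.ndarray
    current_b: np.ndarray

    def __post_init__(self) -> None:
        self.current_a = np.asarray(self.current_a, dtype=float).ravel()
        self.current_b = np.asarray(self.current_b, dtype=float).ravel()
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.current_a.size != self.current_b.size:
            raise ValueError("paired traces must have equal length")

    @property
    def duration(self) -> float:
        return self.current_a.size / self.sample_rate


@dataclass
class YMazeSession:
    """Sequence of arm entries; consecutive entries always differ."""

    entries: Sequence[str]

    def __post_init__(self) -> None:
        entries = list(self.entries)
        for prev, cur in zip(entries, entries[1:]):
            if prev == cur:
                raise ValueError("consecutive arm entries must differ")
        self.entries = entries


@dataclass
class StartleSession:
    """Startle amplitudes per trial type (pulse-alone and prepulse+pulse)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"trial_type", "amplitude"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"startle table needs columns {sorted(required)}")
        if (self.table["amplitude"] < 0).any():
            raise ValueError("startle amplitudes must be >= 0")


@dataclass(frozen=True)
class CellFluorescence:
    """ROI measurement of one cell from an immunofluorescence image."""

    integrated_density: float
    area: float
    background_mean: float
    group: str = "non-PV"
    genotype: str = "control"

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.background_mean < 0:
            raise ValueError("background_mean must be >= 0")


def metric_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Build the tidy long-format metric table from row dicts."""
    df = pd.DataFrame(list(rows), columns=list(METRIC_COLUMNS))
    return df
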