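"""Synchronous sIPSC quantification from paired voltage-clamp recordings.

Events are spontaneous inhibitory postsynaptic currents (> 5 pA, stored
as positive deflections).  Two simultaneously recorded pyramidal cells
share presynaptic interneurons, so a fraction of their sIPSCs coincide;
an event is *synchronous* if the other cell has at least one event
within a +/-10 ms window (closed interval).  The reported percentage
pools the events of both cells, which makes it symmetric in the pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .datatypes import IPSCEventTrains

DEFAULT_WINDOW_HALFWIDTH = 0.010
DEFAULT_THRESHOLD = 5.0  # pA, strict


class IEISummary(NamedTuple):
    mean: float  # s
    sd: float
    n: int


def inter_event_intervals(times: np.ndarray) -> IEISummary:
    """Successive-difference intervals of one event train."""
    times = np.asarray(times, dtype=float).ravel()
    if times.size < 2:
        raise ValueError("need >= 2 events for inter-event intervals")
    iei = np.diff(times)
    return IEISummary(mean=float(iei.mean()), sd=float(iei.std(ddof=1)),
                      n=int(iei.size))


@dataclass
class SynchronyResult:
    """Per-pair synchronous-event summary."""

    pct_synchronous: float   # pooled over both cells
    window_halfwidth: float
    n_events_a: int
    n_events_b: int
    mean_iei_a: float        # s, NaN if < 2 events
    mean_iei_b: float
    pct_a: float             # per-cell variants
    pct_b: float


def _n_synchronous(times: np.ndarray, other: np.ndarray, w: float) -> int:
    """Events of ``times`` with >= 1 partner in ``other`` within +/-w (closed)."""
    if times.size == 0 or other.size == 0:
        return 0
    lo = np.searchsorted(other, times - w, side="left")
    hi = np.searchsorted(other, times + w, side="right")
    return int(np.count_nonzero(hi > lo))


def synchronous_fraction(
    trains: IPSCEventTrains,
    window_halfwidth: float = DEFAULT_WINDOW_HALFWIDTH,
) -> SynchronyResult:
    """Percentage of events with a partner in the other cell within the window.

    Coincidence is per-event with a closed +/-``window_halfwidth``
    interval; one event may partner many.  The pooled percentage is
    ``100 * (sync_a + sync_b) / (n_a + n_b)``, symmetric under swapping
    the cells and monotone non-decreasing in the window.
    """
    if window_halfwidth <= 0:
        raise ValueError("window_halfwidth must be positive")
    a, b = trains.times_a, trains.times_b
    if a.size == 0 or b.size == 0:
        warnings.warn("empty event train; synchronous percentage set to 0")
        pct = pct_a = pct_b = 0.0
        sync_a = sync_b = 0
    else:
        sync_a = _n_synchronous(a, b, window_halfwidth)
        sync_b = _n_synchronous(b, a, window_halfwidth)
        pct = 100.0 * (sync_a + sync_b) / (a.size + b.size)
        pct_a = 100.0 * sync_a / a.size
        pct_b = 100.0 * sync_b / b.size

    def _mean_iei(t: np.ndarray) -> float:
        return float(np.diff(t).mean()) if t.size >= 2 else float("nan")

    return SynchronyResult(
        pct_synchronous=float(pct), window_halfwidth=window_halfwidth,
        n_events_a=int(a.size), n_events_b=int(b.size),
        mean_iei_a=_mean_iei(a), mean_iei_b=_mean_iei(b),
        pct_a=float(pct_a), pct_b=float(pct_b),
    )


def expected_synchronous_fraction(
    total_rate: float,
    shared_rate: float,
    window_halfwidth: float = DEFAULT_WINDOW_HALFWIDTH,
) -> float:
    """Closed-form expected synchronous fraction for a Poisson mixture.

    For two cells each firing at total rate r with a shared Poisson
    component of rate s, an event is synchronous with probability
    ``[s + (r - s) * (1 - exp(-2 w r))] / r``: shared events always
    coincide, and an independent event sees the other cell's Poisson
    process inside its 2w window.  Returned as a fraction (0-1).
    """
    r, s, w = total_rate, shared_rate, window_halfwidth
    if r <= 0:
        raise ValueError("total_rate must be positive")
    if not 0 <= s <= r:
        raise ValueError("need 0 <= shared_rate <= total_rate")
    return (s + (r - s) * (1.0 - math.exp(-2.0 * w * r))) / r


# ------------------------------------------------------- event detection

def _block_median_baseline(x: np.ndarray, block: int) -> np.ndarray:
    """Piecewise-linear baseline from medians of non-overlapping blocks."""
    n = x.size
    n_blocks = max(1, n // block)
    trimmed = x[: n_blocks * block].reshape(n_blocks, block)
    medians = np.median(trimmed, axis=1)
    centers = (np.arange(n_blocks) + 0.5) * block
    return np.interp(np.arange(n), centers, medians)


def detect_ipsc_events(
    trace: np.ndarray,
    sample_rate: float,
    threshold: float = DEFAULT_THRESHOLD,
    min_separation: float = 0.002,
    baseline_block: float = 0.1,
    smooth_sigma: float = 0.0003,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect sIPSC events (> ``threshold`` pA, strict) in a current trace.

    The trace (inward currents rectified to positive deflections) is
    baseline-subtracted with a sliding block-median, lightly smoothed,
    and local maxima separated by >= ``min_separation`` are kept if
    their unsmoothed amplitude above baseline strictly exceeds the
    threshold.  Returns ``(peak_times_s, amplitudes_pA)``; an all-flat
    trace yields empty arrays.
    """
    if sample_rate < 2000:
        raise ValueError("sample_rate must be >= 2 kHz for sIPSC detection")
    x = np.asarray(trace, dtype=float).ravel()
    if x.size == 0 or np.ptp(x) == 0:
        return np.array([]), np.array([])
    baseline = _block_median_baseline(x, max(1, int(round(baseline_block * sample_rate))))
    d = x - baseline
    smoothed = gaussian_filter1d(d, smooth_sigma * sample_rate) if smooth_sigma > 0 else d
    distance = max(1, int(round(min_separation * sample_rate)))
    # prominence (not height) rejects noise bumps riding the decay tail
    # of a preceding large event
    peaks, _ = find_peaks(smoothed, prominence=0.5 * threshold, distance=distance)
    if peaks.size == 0:
        return np.array([]), np.array([])
    # refine amplitude/time on the unsmoothed baseline-subtracted trace
    half = max(1, int(round(0.001 * sample_rate)))
    times, amps = [], []
    last_j = -distance - 1
    for p in peaks:
        lo, hi = max(0, p - half), min(d.size, p + half + 1)
        j = lo + int(np.argmax(d[lo:hi]))
        if j - last_j <= distance and times:
            continue  # refined onto the same peak
        amp = d[j]
        if amp > threshold:  # strict: exactly-threshold events are excluded
            times.append(j / sample_rate)
            amps.append(amp)
            last_j = j
    return np.asarray(times), np.asarray(amps)


def detect_pair(
    traces,
    threshold: float = DEFAULT_THRESHOLD,
    min_separation: float = 0.002,
) -> IPSCEventTrains:
    """Run event detection on both traces of a pair."""
    ta, aa = detect_ipsc_events(traces.current_a, traces.sample_rate,
                                threshold, min_separation)
    tb, ab = detect_ipsc_events(traces.current_b, traces.sample_rate,
                                threshold, min_separation)
    return IPSCEventTrains(times_a=ta, times_b=tb, amps_a=aa, amps_b=ab,
                           duration=traces.duration)
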