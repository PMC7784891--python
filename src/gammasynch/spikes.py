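"""In vivo spike-pair synchrony: binned cross-correlation with a shuffle null.

Synchrony of two simultaneously recorded pyramidal cells is quantified
as the zero-lag Pearson correlation of spike counts in 5-ms bins, with a
correlogram over +/-100 ms of lag and an inter-spike-interval (ISI)
shuffle null that preserves each train's spike count and ISI multiset
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import SpikeTrainPair

DEFAULT_BIN_WIDTH = 0.005


def bin_spike_trains(
    pair: SpikeTrainPair, bin_width: float = DEFAULT_BIN_WIDTH
) -> tuple[np.ndarray, np.ndarray]:
    """Count spikes of both trains in half-open bins over [0, duration).

    Spikes exactly at t = duration fall outside the last half-open bin
    and are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if pair.duration < bin_width:
        raise ValueError("duration must cover at least one bin")
    n_bins = int(np.floor(pair.duration / bin_width + 1e-9))
    counts = []
    for t in (pair.times_a, pair.times_b):
        if np.any(np.diff(t) < 0):
            raise ValueError("spike times must be sorted")
        idx = np.floor(t / bin_width).astype(int)
        idx = idx[idx < n_bins]
        counts.append(np.bincount(idx, minlength=n_bins))
    return counts[0], counts[1]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN (not 0) when either vector has zero variance."""
    xs = x.std()
    ys = y.std()
    if xs == 0 or ys == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (xs * ys))


@dataclass
class CrossCorrResult:
    """Zero-lag coefficient and lag correlogram of binned counts."""

    coefficient: float
    lags: np.ndarray         # s, negative = train b leads
    correlogram: np.ndarray  # Pearson r at each lag
    bin_width: float
    n_bins: int
    null_mean: float | None = None
    null_sd: float | None = None

    @property
    def valid(self) -> bool:
        return not np.isnan(self.coefficient)


def cross_correlation(
    pair: SpikeTrainPair,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_lag: float = 0.1,
) -> CrossCorrResult:
    """Pearson correlation of binned counts at zero lag and over +/-max_lag.

    A train with zero count variance yields a NaN coefficient (flagged
    via ``result.valid``), never a silent 0.
    """
    if pair.times_a.size == 0 or pair.times_b.size == 0:
        raise ValueError("both trains must be non-empty")
    a, b = bin_spike_trains(pair, bin_width)
    k_max = int(round(max_lag / bin_width))
    lags = np.arange(-k_max, k_max + 1) * bin_width
    cgram = np.empty(lags.size)
    for j, k in enumerate(range(-k_max, k_max + 1)):
        if k >= 0:
            cgram[j] = _pearson(a[: a.size - k] if k else a, b[k:])
        else:
            cgram[j] = _pearson(a[-k:], b[: b.size + k])
    return CrossCorrResult(
        coefficient=_pearson(a, b), lags=lags, correlogram=cgram,
        bin_width=bin_width, n_bins=a.size,
    )


def peak_correlation(result: CrossCorrResult, within: float = 0.010) -> float:
    """Largest correlogram value within +/-``within`` s of zero lag."""
    mask = np.abs(result.lags) <= within + 1e-12
    return float(np.nanmax(result.correlogram[mask]))


@dataclass
class ShuffleNullResult:
    """ISI-shuffle null distribution of the zero-lag coefficient."""

    observed: float
    null_mean: float
    null_sd: float
    quantile: float       # fraction of shuffles <= observed
    null: np.ndarray
    n_shuffles: int


def _isi_shuffle(times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute inter-spike intervals; preserves count and ISI multiset."""
    isi = np.diff(times)
    return times[0] + np.concatenate(([0.0], np.cumsum(rng.permutation(isi))))


def shuffle_null(
    pair: SpikeTrainPair,
    n_shuffles: int = 100,
    seed: int | np.random.SeedSequence | None = 0,
    bin_width: float = DEFAULT_BIN_WIDTH,
    shuffle_train: str = "b",
) -> ShuffleNullResult:
    """Null distribution of the coefficient under ISI shuffling of one train.

    Shuffling inter-spike intervals (rather than spike times) preserves
    the shuffled train's rate and ISI statistics while destroying its
    temporal alignment with the partner train.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be >= 20")
    if pair.times_a.size < 3 or pair.times_b.size < 3:
        raise ValueError("each train needs >= 3 spikes for ISI shuffling")
    if shuffle_train not in ("a", "b"):
        raise ValueError("shuffle_train must be 'a' or 'b'")
    rng = np.random.default_rng(seed)
    a, b = bin_spike_trains(pair, bin_width)
    observed = _pearson(a, b)
    n_bins = a.size
    fixed = a if shuffle_train == "b" else b
    times = pair.times_b if shuffle_train == "b" else pair.times_a
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        t = _isi_shuffle(times, rng)
        idx = np.floor(t / bin_width).astype(int)
        counts = np.bincount(idx[idx < n_bins], minlength=n_bins)
        null[i] = _pearson(fixed, counts)
    return ShuffleNullResult(
        observed=float(observed),
        null_mean=float(np.nanmean(null)),
        null_sd=float(np.nanstd(null)),
        quantile=float(np.mean(null <= observed)),
        null=null,
        n_shuffles=n_shuffles,
    )
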