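"""Auditory steady-state response (ASSR) analysis of trial-structured LFP.

Implements the analysis chain applied to 40-Hz click-train recordings:

* z-scoring of every segment against the pre-stimulus record;
* time-frequency decomposition (complex Morlet, 7 cycles, 1-Hz steps for
  power; Hann STFT with 60 % overlap, zero-padded to a 1-Hz grid, for
  intertrial coherence);
* evoked power (decompose the trial-averaged trace) and total power
  (decompose each trial, then average), both with the mean mid-ISI
  spontaneous band power subtracted in the z-scored power domain;
* baseline band power over the last 10 s before the first train, split
  into 50 contiguous 200-ms segments;
* intertrial coherence (resultant length of per-trial STFT phases);
* N1 amplitude (first prominent negative peak of the averaged trace);
* per-animal / per-channel aggregation of the tidy metric table.

Power convention: Morlet power is the squared amplitude envelope, i.e. a
sinusoid of amplitude A has band power A^2 at its frequency.  Band power
of a finite segment (analysis window or 200-ms spontaneous segment) is
estimated on the excised segment after symmetric padding, so stimulus
windows and mid-ISI reference segments share one estimator.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.signal import ShortTimeFFT, get_window
from scipy.fft import next_fast_len

from .datatypes import LFPTrialSet, METRIC_COLUMNS

DEFAULT_BAND = (35.0, 44.0)
DEFAULT_WINDOW = (0.3, 0.5)  # last 200 ms of the 500-ms click train


# ---------------------------------------------------------------- z-score

def zscore_lfp(trials: LFPTrialSet) -> LFPTrialSet:
    """Normalize every segment by the pre-stimulus record's mean and SD.

    The pre-stimulus record is the only epoch guaranteed free of
    stimulus-driven activity, so it serves as the z-scoring reference
    for the whole channel.  Idempotent up to floating tolerance.
    """
    if trials.prestim.size / trials.sample_rate < 10.0:
        raise ValueError("pre-stimulus record must be >= 10 s for z-scoring")
    mu = trials.prestim.mean()
    sd = trials.prestim.std()
    if sd == 0:
        raise ValueError("pre-stimulus record is constant; cannot z-score")
    out = copy.copy(trials)
    out.trials = (trials.trials - mu) / sd
    out.mid_isi = (trials.mid_isi - mu) / sd
    out.prestim = (trials.prestim - mu) / sd
    out.zscored = True
    return out


# ------------------------------------------------- Morlet decomposition

def _morlet_kernel(freq: float, sample_rate: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet kernel scaled so a sinusoid of amplitude A
    produces |W| = A (power A^2)."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    g = np.exp(-0.5 * (t / sigma_t) ** 2)
    return (2.0 / g.sum()) * g * np.exp(2j * np.pi * freq * t)


def morlet_tfr(
    x: np.ndarray,
    sample_rate: float,
    freqs: np.ndarray,
    n_cycles: float = 7.0,
) -> np.ndarray:
    """Complex Morlet transform of ``x`` (last axis = time).

    Returns an array of shape ``x.shape[:-1] + (n_freqs, n_times)``.
    """
    x = np.asarray(x, dtype=float)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    if np.any(freqs > sample_rate / 2):
        raise ValueError("requested frequency above Nyquist")
    n = x.shape[-1]
    kernels = [_morlet_kernel(f, sample_rate, n_cycles) for f in freqs]
    nfft = next_fast_len(n + max(k.size for k in kernels) - 1)
    X = np.fft.fft(x, nfft)
    out = np.empty(x.shape[:-1] + (freqs.size, n), dtype=complex)
    for i, k in enumerate(kernels):
        K = np.fft.fft(k, nfft)
        y = np.fft.ifft(X * K)
        start = (k.size - 1) // 2
        out[..., i, :] = y[..., start:start + n]
    return out


def _segment_band_power(
    segments: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = DEFAULT_BAND,
    n_cycles: float = 7.0,
) -> np.ndarray:
    """Mean Morlet band power of each row of ``segments``.

    Each segment is symmetrically padded by up to its own length before
    decomposition so wavelet edge effects do not bias short (200-ms)
    segments, then power is averaged over the unpadded span and the
    1-Hz band grid.
    """
    segs = np.atleast_2d(np.asarray(segments, dtype=float))
    m = segs.shape[-1]
    freqs = np.arange(band[0], band[1] + 0.5)
    pad = int(min(m, np.ceil(sample_rate * 5.0 * n_cycles / (2 * np.pi * band[0]))))
    padded = np.pad(segs, ((0, 0), (pad, pad)), mode="symmetric")
    w = morlet_tfr(padded, sample_rate, freqs, n_cycles)
    power = np.abs(w[..., pad:pad + m]) ** 2
    return power.mean(axis=(-2, -1))


# ---------------------------------------------------------- spectrogram

@dataclass
class Spectrogram:
    """Time-frequency decomposition of a single trace."""

    freqs: np.ndarray
    times: np.ndarray
    values: np.ndarray  # complex, (n_freqs, n_times)
    method: str
    sample_rate: float

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.values) ** 2


def _stft(x: np.ndarray, sample_rate: float, win_duration: float = 0.2,
          overlap: float = 0.6, f_max: float = 100.0):
    """Hann STFT zero-padded to an (approximately) 1-Hz frequency grid.

    Returns ``(freqs, window_center_times, complex_stft)`` with the STFT
    shaped ``x.shape[:-1] + (n_freqs, n_times)``.
    """
    nper = int(round(win_duration * sample_rate))
    hop = max(1, int(round(nper * (1.0 - overlap))))
    mfft = max(nper, int(round(sample_rate)))  # ~1-Hz bins
    win = get_window("hann", nper)
    sft = ShortTimeFFT(win, hop=hop, fs=sample_rate, mfft=mfft,
                       fft_mode="onesided")
    S = sft.stft(np.asarray(x, dtype=float))
    sel = sft.f <= f_max
    return sft.f[sel], sft.t(np.shape(x)[-1]), S[..., sel, :]


def tf_decompose(
    trace: np.ndarray,
    sample_rate: float,
    freqs: np.ndarray | None = None,
    method: str = "morlet",
    n_cycles: float = 7.0,
) -> Spectrogram:
    """Decompose a single trace into a :class:`Spectrogram`.

    ``morlet`` is the power path (7 cycles, 1-Hz steps); ``stft`` is the
    phase-locking path (200-ms Hann windows, 60 % overlap, zero-padded
    to a 1-Hz grid).
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if method == "morlet":
        if freqs is None:
            freqs = np.arange(1.0, 101.0)
        freqs = np.asarray(freqs, dtype=float)
        if trace.size / sample_rate < 2.0 / freqs.min():
            raise ValueError("trace shorter than 2 cycles of the lowest frequency")
        values = morlet_tfr(trace, sample_rate, freqs, n_cycles)
        times = np.arange(trace.size) / sample_rate
        return Spectrogram(freqs=freqs, times=times, values=values,
                           method="morlet", sample_rate=sample_rate)
    if method == "stft":
        f, t, S = _stft(trace, sample_rate)
        if freqs is not None:
            freqs = np.asarray(freqs, dtype=float)
            if freqs.max() > sample_rate / 2:
                raise ValueError("requested frequency above Nyquist")
            sel = (f >= freqs.min()) & (f <= freqs.max())
            f, S = f[sel], S[sel, :]
        # approximate amplitude envelope: double the one-sided magnitude
        S = S * 2.0 / np.sum(get_window("hann", int(round(0.2 * sample_rate))))
        return Spectrogram(freqs=f, times=t, values=S, method="stft",
                           sample_rate=sample_rate)
    raise ValueError("method must be 'morlet' or 'stft'")


# ------------------------------------------------------------- summaries

@dataclass
class PowerSummary:
    """Band/window power summary for one channel."""

    metric: str  # evoked | total | baseline
    band: tuple[float, float]
    window: tuple[float, float] | None
    value: float
    subject_id: str
    channel_id: str


def _window_slice(trials: LFPTrialSet, window: tuple[float, float]) -> slice:
    t0, t1 = trials.trial_window
    if window[0] < t0 or window[1] > t1 or window[1] <= window[0]:
        raise ValueError(f"analysis window {window} outside trial span ({t0}, {t1})")
    i0 = int(round((window[0] - t0) * trials.sample_rate))
    i1 = int(round((window[1] - t0) * trials.sample_rate))
    return slice(i0, i1)


def assr_power(
    trials: LFPTrialSet,
    mode: str = "evoked",
    band: tuple[float, float] = DEFAULT_BAND,
    window: tuple[float, float] = DEFAULT_WINDOW,
    spontaneous: str = "power",
    check_normalized: bool = True,
) -> PowerSummary:
    """Evoked or total ASSR band power with spontaneous subtraction.

    ``evoked`` decomposes the trial-averaged trace; ``total`` decomposes
    each trial and averages the power.  In the default ``spontaneous
    ='power'`` variant the mean band power of the decomposed mid-ISI
    segments is subtracted in the z-scored power domain; with
    ``spontaneous='trace'`` the mid-ISI segment (same length as the
    analysis window) is subtracted trial-wise in the time domain before
    decomposition.  Because power of an average never exceeds average
    power and the subtrahend is identical, evoked <= total always.
    """
    if mode not in ("evoked", "total"):
        raise ValueError("mode must be 'evoked' or 'total'")
    if check_normalized and not trials.zscored:
        raise ValueError("trials must be z-scored first (see zscore_lfp)")
    if trials.mid_isi.size == 0:
        raise ValueError("mid-ISI spontaneous segments are required")
    sl = _window_slice(trials, window)
    fs = trials.sample_rate
    windows = trials.trials[:, sl]

    if spontaneous == "power":
        ref = _segment_band_power(trials.mid_isi, fs, band)
        if mode == "evoked":
            value = float(
                _segment_band_power(windows.mean(axis=0), fs, band)[0] - ref.mean()
            )
        else:
            value = float((_segment_band_power(windows, fs, band) - ref).mean())
    elif spontaneous == "trace":
        if trials.mid_isi.shape[1] != windows.shape[1]:
            raise ValueError(
                "trace-domain subtraction needs mid-ISI segments matching the "
                "analysis-window length"
            )
        diffs = windows - trials.mid_isi
        if mode == "evoked":
            value = float(_segment_band_power(diffs.mean(axis=0), fs, band)[0])
        else:
            value = float(_segment_band_power(diffs, fs, band).mean())
    else:
        raise ValueError("spontaneous must be 'power' or 'trace'")
    return PowerSummary(metric=mode, band=band, window=window, value=value,
                        subject_id=trials.subject_id, channel_id=trials.channel_id)


def baseline_power(
    trials: LFPTrialSet,
    band: tuple[float, float] = DEFAULT_BAND,
    n_segments: int = 50,
    segment_duration: float = 0.2,
) -> PowerSummary:
    """Pre-stimulus band power: last 10 s split into 50 x 200-ms segments."""
    fs = trials.sample_rate
    seg_len = int(round(segment_duration * fs))
    needed = n_segments * seg_len
    if trials.prestim.size < needed:
        raise ValueError(
            f"pre-stimulus record must be >= {n_segments * segment_duration:.0f} s "
            f"({needed} samples at {fs:g} Hz); got {trials.prestim.size} samples"
        )
    segs = trials.prestim[-needed:].reshape(n_segments, seg_len)
    value = float(_segment_band_power(segs, fs, band).mean())
    return PowerSummary(metric="baseline", band=band, window=None, value=value,
                        subject_id=trials.subject_id, channel_id=trials.channel_id)


# ------------------------------------------------- intertrial coherence

@dataclass
class ITCResult:
    """Intertrial phase coherence over the 0-100 Hz STFT grid."""

    freqs: np.ndarray
    times: np.ndarray
    values: np.ndarray  # (n_freqs, n_times), NaN where phase undefined
    n_trials: int
    band_value: float
    n_excluded_bins: int


def intertrial_coherence(
    trials: LFPTrialSet,
    band: tuple[float, float] = DEFAULT_BAND,
    window: tuple[float, float] = DEFAULT_WINDOW,
    win_duration: float = 0.2,
    overlap: float = 0.6,
) -> ITCResult:
    """Resultant length of per-trial STFT phases, 0-100 Hz.

    Zero-power bins have undefined phase; they are excluded from the
    per-bin average and counted in ``n_excluded_bins``.  The band metric
    is the mean ITC in ``band`` over window centers inside ``window``.
    """
    if trials.n_trials < 1:
        raise ValueError("need at least one trial")
    f, t, S = _stft(trials.trials, trials.sample_rate,
                    win_duration=win_duration, overlap=overlap)
    t = t + trials.trial_window[0]
    mag = np.abs(S)
    zero = mag == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(zero, np.nan + 0j, S / np.where(zero, 1.0, mag))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        itc = np.abs(np.nanmean(unit, axis=0))
    fmask = (f >= band[0]) & (f <= band[1])
    tmask = (t >= window[0]) & (t < window[1])
    if not fmask.any() or not tmask.any():
        raise ValueError("no STFT bins inside the requested band/window")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        band_value = float(np.nanmean(itc[np.ix_(fmask, tmask)]))
    return ITCResult(freqs=f, times=t, values=itc, n_trials=trials.n_trials,
                     band_value=band_value, n_excluded_bins=int(zero.sum()))


# ----------------------------------------------------------------- N1

class N1Result(NamedTuple):
    amplitude: float  # positive magnitude
    latency: float    # s post-onset
    is_local_min: bool


def n1_amplitude(
    trials: LFPTrialSet,
    window: tuple[float, float] = (0.010, 0.100),
) -> N1Result:
    """Magnitude of the first prominent negative peak of the averaged trace.

    Searches ``window`` (s post-onset) for the minimum of the
    trial-averaged trace.  If the minimum is not a strict interior local
    minimum the magnitude at the window minimum is still returned, with
    ``is_local_min=False``.
    """
    avg = trials.trials.mean(axis=0)
    t = trials.times
    mask = (t >= window[0]) & (t <= window[1])
    if not mask.any():
        raise ValueError("N1 search window outside trial span")
    seg = avg[mask]
    i = int(np.argmin(seg))
    local = 0 < i < seg.size - 1 and seg[i] < seg[i - 1] and seg[i] < seg[i + 1]
    return N1Result(amplitude=float(abs(seg[i])), latency=float(t[mask][i]),
                    is_local_min=bool(local))


# ------------------------------------------------------------ aggregate

def aggregate(metrics: pd.DataFrame, design: str = "per_animal") -> pd.DataFrame:
    """Aggregate a tidy metric table under the per-animal or per-channel design.

    ``per_animal`` averages across channels within each
    (condition, subject, metric) group; ``per_channel`` is an identity
    pass-through.  Both designs yield the same sign of condition
    contrasts on preset-generated data.
    """
    missing = set(METRIC_COLUMNS) - set(metrics.columns)
    if missing:
        raise ValueError(f"metric table missing columns {sorted(missing)}")
    if len(metrics) == 0:
        raise ValueError("empty metric table")
    if design == "per_channel":
        return metrics.copy()
    if design == "per_animal":
        out = (
            metrics.groupby(["condition", "subject", "metric"], as_index=False,
                            sort=False, observed=True)["value"].mean()
        )
        out["channel"] = "all"
        return out[list(METRIC_COLUMNS)]
    raise ValueError("design must be 'per_animal' or 'per_channel'")
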