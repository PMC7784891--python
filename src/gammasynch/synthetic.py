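"""Synthetic-data generators with the statistical structure the analyses assume.

The generators emulate the study conditions: 50 click-train trials per
recording channel with 20-s inter-stimulus intervals, a >= 10-s
pre-stimulus record and a 200-ms mid-ISI spontaneous segment per trial;
correlated pyramidal spike-train pairs; paired sIPSC event trains with a
controllable shared-event rate; Y-maze sessions; and startle tables.
Everything is deterministic given a seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datatypes import (
    IPSCEventTrains,
    LFPTrialSet,
    PairedTraces,
    SpikeTrainPair,
    StartleSession,
    YMazeSession,
)
from .presets import GenotypePreset

ARMS = ("A", "B", "C")


def _pink_noise(rng: np.random.Generator, n: int, sd: float,
                sample_rate: float) -> np.ndarray:
    """1/f noise by spectral shaping of white Gaussian noise.

    The power spectral density is ``c / max(f, 1 Hz)`` (flattened below
    1 Hz, zero at DC) with ``c`` chosen so a full-bandwidth record has
    expected standard deviation ``sd``.  The PSD is anchored to absolute
    frequency, so segments of different lengths carry identical
    gamma-band power density.
    """
    if sd == 0 or n == 0:
        return np.zeros(n)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    c = sd**2 / (1.0 + math.log(sample_rate / 2.0))
    psd = c / np.maximum(f, 1.0)
    df = sample_rate / n
    amp = np.sqrt(psd * df * n / 2.0)
    amp[0] = 0.0
    if n % 2 == 0:
        amp[-1] *= math.sqrt(2.0)  # Nyquist bin counted once
    spec = np.fft.rfft(rng.standard_normal(n))
    return np.fft.irfft(spec * amp, n)


def _narrowband(rng: np.random.Generator, t: np.ndarray, amp: float,
                band: tuple[float, float] = (35.0, 44.0)) -> np.ndarray:
    """One realization of the ongoing gamma process: a random-frequency,
    random-phase sinusoid within the band."""
    if amp == 0:
        return np.zeros_like(t)
    f = rng.uniform(*band)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return amp * np.cos(2.0 * np.pi * f * t + phi)


def _evoked_phases(rng: np.random.Generator, kappa: float, n: int) -> np.ndarray:
    if np.isinf(kappa):
        return np.zeros(n)
    if kappa == 0:
        return rng.uniform(-np.pi, np.pi, n)
    return rng.vonmises(0.0, kappa, n)


def generate_assr_trials(
    preset: GenotypePreset,
    n_trials: int = 50,
    seed: int | np.random.SeedSequence | None = 0,
    sample_rate: float = 1000.0,
    trial_window: tuple[float, float] = (-0.5, 1.0),
    stim_duration: float = 0.5,
    stim_freq: float = 40.0,
    prestim_duration: float = 12.0,
    mid_isi_duration: float = 0.2,
    n1_center: float = 0.040,
    n1_fwhm: float = 0.025,
    subject_id: str = "sim",
    channel_id: str = "ch0",
) -> LFPTrialSet:
    """Simulate one channel's click-train session as an :class:`LFPTrialSet`.

    Each trial is the sum of 1/f background noise, the ongoing
    narrow-band 35–44 Hz process (present in every segment, including
    the pre-stimulus record and mid-ISI segments), a 40-Hz sinusoid of
    amplitude ``preset.evoked_amp`` during the stimulus whose per-trial
    phase is von Mises(0, ``preset.phase_kappa``), and a negative
    Gaussian-shaped onset potential of depth ``preset.n1_amp`` centered
    ``n1_center`` seconds after onset.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if sample_rate < 500:
        raise ValueError("sample_rate must be >= 500 Hz")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)

    t = trial_window[0] + np.arange(
        int(round((trial_window[1] - trial_window[0]) * sample_rate))
    ) / sample_rate
    n_samples = t.size
    n_mid = int(round(mid_isi_duration * sample_rate))
    n_pre = int(round(prestim_duration * sample_rate))

    phases = _evoked_phases(rng, preset.phase_kappa, n_trials)
    stim_mask = (t >= 0.0) & (t < stim_duration)
    sigma = n1_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    n1 = -preset.n1_amp * np.exp(-0.5 * ((t - n1_center) / sigma) ** 2)

    trials = np.empty((n_trials, n_samples))
    mid_isi = np.empty((n_trials, n_mid))
    t_mid = np.arange(n_mid) / sample_rate
    for i in range(n_trials):
        x = _pink_noise(rng, n_samples, preset.pink_noise_sd, sample_rate)
        x += _narrowband(rng, t, preset.baseline_gamma_amp)
        x[stim_mask] += preset.evoked_amp * np.cos(
            2.0 * np.pi * stim_freq * t[stim_mask] + phases[i]
        )
        x += n1
        trials[i] = x
        mid_isi[i] = _pink_noise(rng, n_mid, preset.pink_noise_sd, sample_rate) + _narrowband(
            rng, t_mid, preset.baseline_gamma_amp
        )

    t_pre = np.arange(n_pre) / sample_rate
    prestim = _pink_noise(rng, n_pre, preset.pink_noise_sd, sample_rate) + _narrowband(
        rng, t_pre, preset.baseline_gamma_amp
    )
    stim_onsets = prestim_duration + 20.0 * np.arange(n_trials)
    return LFPTrialSet(
        sample_rate=sample_rate,
        trials=trials,
        mid_isi=mid_isi,
        prestim=prestim,
        stim_onsets=stim_onsets,
        trial_window=trial_window,
        stim_duration=stim_duration,
        subject_id=subject_id,
        channel_id=channel_id,
        zscored=False,
    )


def _poisson_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def _ipsc_amplitudes(rng: np.random.Generator, n: int, median: float = 20.0,
                     sigma: float = 0.5, floor: float = 5.0) -> np.ndarray:
    """Log-normal amplitudes (pA), truncated to be strictly above ``floor``."""
    amps = rng.lognormal(math.log(median), sigma, n)
    while np.any(amps <= floor):
        bad = amps <= floor
        amps[bad] = rng.lognormal(math.log(median), sigma, int(bad.sum()))
    return amps


def generate_event_train_pair(
    indep_rate: float,
    shared_rate: float,
    duration: float,
    jitter_halfwidth: float = 0.003,
    seed: int | np.random.SeedSequence | None = 0,
    amp_median: float = 20.0,
    amp_sigma: float = 0.5,
) -> IPSCEventTrains:
    """Paired Poisson sIPSC event trains with a common shared component.

    Each cell receives an independent homogeneous Poisson process at
    ``indep_rate`` plus a copy of a shared Poisson process at
    ``shared_rate``; each copy is jittered independently by
    Uniform(+/- ``jitter_halfwidth``), so the relative offset of a shared
    pair never exceeds twice the half-width (within the +/-10 ms
    coincidence window at the 3-ms default).
    """
    if indep_rate < 0 or shared_rate < 0:
        raise ValueError("rates must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if jitter_halfwidth < 0:
        raise ValueError("jitter_halfwidth must be >= 0")
    rng = np.random.default_rng(seed)
    shared = _poisson_times(rng, shared_rate, duration)

    cells = []
    for _ in range(2):
        own = _poisson_times(rng, indep_rate, duration)
        if jitter_halfwidth > 0 and shared.size:
            jit = shared + rng.uniform(-jitter_halfwidth, jitter_halfwidth, shared.size)
            jit = np.clip(jit, 0.0, duration)
        else:
            jit = shared
        times = np.sort(np.concatenate([own, jit]))
        amps = _ipsc_amplitudes(rng, times.size, amp_median, amp_sigma)
        cells.append((times, amps))
    return IPSCEventTrains(
        times_a=cells[0][0], times_b=cells[1][0],
        amps_a=cells[0][1], amps_b=cells[1][1],
        duration=duration,
    )


def ipsc_kernel_peak_delay(rise: float = 0.001, decay: float = 0.010) -> float:
    """Delay from event time to peak of the difference-of-exponentials kernel."""
    return math.log(decay / rise) * decay * rise / (decay - rise)


def render_ipsc_traces(
    trains: IPSCEventTrains,
    sample_rate: float = 10000.0,
    rise: float = 0.001,
    decay: float = 0.010,
    noise_sd: float = 1.0,
    seed: int | np.random.SeedSequence | None = 0,
) -> PairedTraces:
    """Render event trains into paired current traces (pA, events positive).

    Each event is a difference-of-exponentials kernel
    ``exp(-t/decay) - exp(-t/rise)`` normalized to unit peak and scaled
    to the event amplitude, so a noise-free 20-pA event peaks at exactly
    20 pA one kernel-peak delay after the event time.
    """
    if not (decay > rise > 0):
        raise ValueError("need decay > rise > 0")
    if sample_rate * rise < 4:
        raise ValueError(
            f"sample_rate {sample_rate} Hz cannot resolve a {rise * 1e3:.2f}-ms "
            "rise time (need >= 4 samples per rise)"
        )
    rng = np.random.default_rng(seed)
    n = int(round(trains.duration * sample_rate))
    tk = np.arange(0.0, 8.0 * decay, 1.0 / sample_rate)
    kernel = np.exp(-tk / decay) - np.exp(-tk / rise)
    kernel /= kernel.max()

    traces = []
    for times, amps in ((trains.times_a, trains.amps_a),
                        (trains.times_b, trains.amps_b)):
        x = np.zeros(n + kernel.size)
        for t0, a in zip(times, amps):
            i = int(round(t0 * sample_rate))
            if 0 <= i < n:
                x[i:i + kernel.size] += a * kernel
        x = x[:n]
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, n)
        traces.append(x)
    return PairedTraces(sample_rate=sample_rate, current_a=traces[0],
                        current_b=traces[1])


def generate_spike_pair(
    rate: float,
    shared_frac: float,
    duration: float,
    seed: int | np.random.SeedSequence | None = 0,
    unit_ids: tuple[str, str] = ("unit_a", "unit_b"),
) -> SpikeTrainPair:
    """Correlated Poisson spike-train pair with marginal rate ``rate``.

    Each train is the union of a shared Poisson process at
    ``shared_frac * rate`` (identical spike times in both trains) and an
    own independent process at ``(1 - shared_frac) * rate``, so the
    marginal rate of each train is ``rate`` and the expected zero-lag
    Pearson correlation of binned counts equals ``shared_frac`` for any
    bin width (counts share exactly the common component's variance).
    """
    if not 0.0 <= shared_frac <= 1.0:
        raise ValueError("shared_frac must be in [0, 1]")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    shared = _poisson_times(rng, shared_frac * rate, duration)
    own_a = _poisson_times(rng, (1.0 - shared_frac) * rate, duration)
    own_b = _poisson_times(rng, (1.0 - shared_frac) * rate, duration)
    return SpikeTrainPair(
        times_a=np.sort(np.concatenate([shared, own_a])),
        times_b=np.sort(np.concatenate([shared, own_b])),
        duration=duration,
        unit_ids=unit_ids,
    )


def generate_ymaze_session(
    policy: str = "alternating",
    n_entries: int = 15,
    lapse: float = 0.0,
    seed: int | np.random.SeedSequence | None = 0,
) -> YMazeSession:
    """Simulate a Y-maze arm-entry sequence.

    Policies: ``random`` chooses uniformly between the two non-current
    arms; ``alternating`` always enters the least recently visited arm;
    ``lapse`` alternates with probability ``1 - lapse`` and otherwise
    chooses randomly.
    """
    if n_entries < 3:
        raise ValueError("n_entries must be >= 3")
    if policy not in ("random", "alternating", "lapse"):
        raise ValueError("policy must be 'random', 'alternating' or 'lapse'")
    if not 0.0 <= lapse <= 1.0:
        raise ValueError("lapse must be in [0, 1]")
    rng = np.random.default_rng(seed)
    first = ARMS[rng.integers(3)]
    others = [a for a in ARMS if a != first]
    second = others[rng.integers(2)]
    entries = [first, second]
    while len(entries) < n_entries:
        cur, prev = entries[-1], entries[-2]
        candidates = [a for a in ARMS if a != cur]
        least_recent = next(a for a in candidates if a != prev)
        if policy == "alternating" or (policy == "lapse" and rng.random() >= lapse):
            entries.append(least_recent)
        else:
            entries.append(candidates[rng.integers(2)])
    return YMazeSession(entries=entries)


def generate_ppi_session(
    preset: GenotypePreset,
    baseline_startle: float = 100.0,
    n_trials_per_type: int = 10,
    noise_sigma: float = 0.2,
    seed: int | np.random.SeedSequence | None = 0,
) -> StartleSession:
    """Simulate a startle/prepulse session as a trial table.

    Pulse-alone amplitudes are log-normal around ``baseline_startle``
    (identical across presets: the startle reflex itself is unaffected
    by genotype or treatment); prepulse+pulse amplitudes are attenuated
    by the preset's per-intensity fraction.
    """
    if baseline_startle <= 0:
        raise ValueError("baseline_startle must be positive")
    rng = np.random.default_rng(seed)

    def draw(mean: float, n: int) -> np.ndarray:
        if noise_sigma == 0:
            return np.full(n, mean)
        return mean * np.exp(
            rng.normal(0.0, noise_sigma, n) - 0.5 * noise_sigma**2
        )

    rows = [("pulse_alone", a) for a in draw(baseline_startle, n_trials_per_type)]
    for db, atten in preset.ppi_attenuation.items():
        mean = baseline_startle * (1.0 - atten)
        rows += [(f"pp{db}", a) for a in draw(mean, n_trials_per_type)]
    table = pd.DataFrame(rows, columns=["trial_type", "amplitude"])
    return StartleSession(table=table)
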