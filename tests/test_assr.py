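import numpy as np
import pytest
from scipy.stats import spearmanr

import gammasynch as gs
from gammasynch.assr import zscore_lfp
from gammasynch.datatypes import LFPTrialSet, metric_table
from gammasynch.presets import make_preset


def _trialset(trials, fs=1000.0, prestim=None, mid_isi=None, **kw):
    trials = np.atleast_2d(trials)
    n = trials.shape[0]
    if prestim is None:
        prestim = np.random.default_rng(0).normal(0, 1, int(12 * fs))
    if mid_isi is None:
        mid_isi = np.zeros((n, int(0.2 * fs)))
    return LFPTrialSet(sample_rate=fs, trials=trials, mid_isi=mid_isi,
                       prestim=prestim, stim_onsets=np.arange(n), **kw)


class TestZScore:
    def test_known_mean_and_sd(self):
        rng = np.random.default_rng(1)
        pre = rng.normal(size=12000)
        pre = (pre - pre.mean()) / pre.std() * 2.0 + 5.0  # exact mean 5, sd 2
        ts = _trialset(np.full((2, 1500), 9.0), prestim=pre)
        z = zscore_lfp(ts)
        assert np.allclose(z.trials, 2.0)
        assert z.zscored

    def test_idempotent(self):
        ts = gs.generate_assr_trials(make_preset("control"), 5, seed=0)
        z1 = zscore_lfp(ts)
        z2 = zscore_lfp(z1)
        assert np.allclose(z1.trials, z2.trials, atol=1e-9)

    def test_flat_record_rejected(self):
        ts = _trialset(np.zeros((2, 1500)), prestim=np.full(12000, 3.0))
        with pytest.raises(ValueError, match="constant"):
            zscore_lfp(ts)


class TestTFDecompose:
    def test_sinusoid_power_scales_quadratically(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        spec1 = gs.tf_decompose(np.cos(2 * np.pi * 40 * t), fs,
                                freqs=np.arange(30.0, 51.0))
        spec2 = gs.tf_decompose(2 * np.cos(2 * np.pi * 40 * t), fs,
                                freqs=np.arange(30.0, 51.0))
        i40 = np.argmin(np.abs(spec1.freqs - 40))
        mid = slice(500, 1500)
        p1 = spec1.power[i40, mid].mean()
        p2 = spec2.power[i40, mid].mean()
        assert p2 / p1 == pytest.approx(4.0, rel=1e-6)
        # peak frequency is the stimulus frequency
        assert spec1.freqs[np.argmax(spec1.power[:, mid].mean(axis=1))] == 40

    def test_dc_input_has_no_gamma_power(self):
        fs = 1000.0
        spec = gs.tf_decompose(np.full(2000, 7.0), fs, freqs=np.arange(35.0, 45.0))
        # interior only: the convolution boundary sees the implicit edge step
        assert spec.power[:, 500:1500].max() < 1e-6

    def test_white_noise_stft_power_flat_across_gamma(self):
        """Flat-PSD input gives flat STFT band power (periodogram oracle)."""
        from scipy.signal import welch

        rng = np.random.default_rng(5)
        fs = 1000.0
        x = rng.standard_normal(int(120 * fs))
        spec = gs.tf_decompose(x, fs, method="stft")
        sel_lo = (spec.freqs >= 30) & (spec.freqs < 40)
        sel_hi = (spec.freqs >= 40) & (spec.freqs <= 50)
        p = spec.power
        lo = p[sel_lo].mean(axis=0).mean()
        hi = p[sel_hi].mean(axis=0).mean()
        n_win = p.shape[1]
        se = p[sel_lo | sel_hi].mean(axis=0).std() / np.sqrt(n_win) * np.sqrt(2)
        assert abs(lo - hi) < 3 * se
        # periodogram oracle agrees that the PSD itself is flat
        f, pxx = welch(x, fs, nperseg=2048)
        oracle_lo = pxx[(f >= 30) & (f < 40)].mean()
        oracle_hi = pxx[(f >= 40) & (f <= 50)].mean()
        assert abs(oracle_lo / oracle_hi - 1) < 0.1

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            gs.tf_decompose(np.zeros(2000), 500.0, freqs=np.array([300.0]))


class TestAssrPower:
    def test_identical_trials_evoked_equals_total(self, preset_factory):
        p = preset_factory(evoked_amp=5.0, phase_kappa=float("inf"))
        ts = gs.generate_assr_trials(p, 10, seed=0)
        ev = gs.assr_power(ts, "evoked", check_normalized=False).value
        to = gs.assr_power(ts, "total", check_normalized=False).value
        assert ev == pytest.approx(to, rel=1e-9)

    def test_evoked_never_exceeds_total(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            trials = rng.normal(size=(6, 1500))
            mid = rng.normal(size=(6, 200))
            ts = _trialset(trials, mid_isi=mid)
            ts.zscored = True
            for variant in ("power", "trace"):
                ev = gs.assr_power(ts, "evoked", spontaneous=variant).value
                to = gs.assr_power(ts, "total", spontaneous=variant).value
                assert ev <= to + 1e-9

    def test_requires_zscored_trials(self, preset_factory):
        ts = gs.generate_assr_trials(preset_factory(pink_noise_sd=5.0), 5, seed=0)
        with pytest.raises(ValueError, match="z-score"):
            gs.assr_power(ts, "evoked")

    def test_window_outside_trial_span_rejected(self, condition_sets):
        with pytest.raises(ValueError, match="window"):
            gs.assr_power(condition_sets["control"], "evoked", window=(0.8, 1.2))

    def test_missing_mid_isi_rejected(self):
        ts = _trialset(np.random.default_rng(0).normal(size=(3, 1500)),
                       mid_isi=np.empty((3, 0)))
        ts.zscored = True
        with pytest.raises(ValueError, match="mid-ISI"):
            gs.assr_power(ts, "evoked")

    def test_trial_reordering_invariance(self, condition_sets):
        import copy

        z = condition_sets["control"]
        perm = np.random.default_rng(3).permutation(z.n_trials)
        z2 = copy.copy(z)
        z2.trials = z.trials[perm]
        z2.mid_isi = z.mid_isi[perm]
        for mode in ("evoked", "total"):
            assert gs.assr_power(z, mode).value == pytest.approx(
                gs.assr_power(z2, mode).value, rel=1e-9)
        assert gs.intertrial_coherence(z).band_value == pytest.approx(
            gs.intertrial_coherence(z2).band_value, rel=1e-9)

    def test_condition_contrast_and_rescue(self, condition_sets):
        ev = {lab: gs.assr_power(z, "evoked").value
              for lab, z in condition_sets.items()}
        assert ev["control"] > ev["mutant"]
        deficit = ev["control"] - ev["mutant"]
        assert abs(ev["mutant_gsk3b_inhibited"] - ev["control"]) < 0.3 * deficit

    def test_evoked_amp_rank_recovery(self, preset_factory):
        """Measured evoked power recovers the preset amplitude ordering."""
        amps, values = [], []
        for seed in range(10):
            for amp in (1.0, 2.0, 3.0, 4.0, 6.0, 8.0):
                p = preset_factory(evoked_amp=amp, phase_kappa=8.0,
                                   baseline_gamma_amp=2.0, pink_noise_sd=10.0)
                ts = zscore_lfp(gs.generate_assr_trials(p, 50, seed=seed))
                amps.append(amp)
                values.append(gs.assr_power(ts, "evoked").value)
        rho = spearmanr(amps, values).statistic
        assert rho >= 0.9


class TestBaselinePower:
    def test_uses_50_segments_of_200ms(self, preset_factory):
        ts = gs.generate_assr_trials(preset_factory(pink_noise_sd=5.0), 3,
                                     seed=0, prestim_duration=10.0)
        assert ts.prestim.size == 10000  # exactly 50 x 200 ms at 1 kHz
        gs.baseline_power(ts)  # accepted
        short = _trialset(np.zeros((2, 1500)), prestim=np.zeros(9000))
        with pytest.raises(ValueError, match="10"):
            gs.baseline_power(short)

    def test_amplitude_scaling_law(self):
        fs = 1000.0
        t = np.arange(int(12 * fs)) / fs
        base = np.cos(2 * np.pi * 40 * t)
        p1 = gs.baseline_power(_trialset(np.zeros((2, 1500)), prestim=base)).value
        p2 = gs.baseline_power(_trialset(np.zeros((2, 1500)), prestim=2 * base)).value
        assert p2 / p1 == pytest.approx(4.0, rel=1e-9)

    def test_mutant_baseline_elevated_and_rescued(self, condition_sets):
        bp = {lab: gs.baseline_power(z).value for lab, z in condition_sets.items()}
        assert bp["mutant"] > bp["control"]
        excess = bp["mutant"] - bp["control"]
        assert abs(bp["mutant_gsk3b_inhibited"] - bp["control"]) < 0.3 * excess

    def test_monotone_in_gamma_amplitude(self, preset_factory):
        means = []
        for amp in (1.0, 2.0, 4.0):
            vals = []
            for seed in range(10):
                p = preset_factory(baseline_gamma_amp=amp, pink_noise_sd=10.0)
                ts = zscore_lfp(gs.generate_assr_trials(p, 2, seed=seed))
                vals.append(gs.baseline_power(ts).value)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestITC:
    def test_bounds_and_amplitude_invariance(self, condition_sets):
        import copy

        z = condition_sets["control"]
        itc = gs.intertrial_coherence(z)
        finite = itc.values[np.isfinite(itc.values)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0 + 1e-12
        z2 = copy.copy(z)
        z2.trials = z.trials * 3.7
        itc2 = gs.intertrial_coherence(z2)
        assert np.allclose(itc.values, itc2.values, equal_nan=True)

    def test_single_trial_is_one(self, preset_factory):
        p = preset_factory(evoked_amp=5.0, pink_noise_sd=1.0)
        ts = gs.generate_assr_trials(p, 1, seed=0)
        assert gs.intertrial_coherence(ts).band_value == pytest.approx(1.0)

    def test_monotone_in_phase_concentration(self, preset_factory):
        means = []
        for kappa in (0.5, 2.0, 8.0):
            vals = []
            for seed in range(10):
                p = preset_factory(evoked_amp=3.0, phase_kappa=kappa,
                                   pink_noise_sd=10.0)
                ts = gs.generate_assr_trials(p, 50, seed=seed)
                vals.append(gs.intertrial_coherence(ts).band_value)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_mutant_phase_locking_reduced(self, condition_sets):
        itc = {lab: gs.intertrial_coherence(z).band_value
               for lab, z in condition_sets.items()}
        assert itc["mutant"] < itc["control"]
        assert itc["mutant_gsk3b_inhibited"] > itc["mutant"]


class TestN1:
    def test_constructed_dip_recovered(self):
        fs = 1000.0
        t = -0.5 + np.arange(1500) / fs
        trace = -50.0 * np.exp(-0.5 * ((t - 0.040) / 0.0106) ** 2)
        ts = _trialset(np.tile(trace, (3, 1)))
        res = gs.n1_amplitude(ts)
        assert res.amplitude == pytest.approx(50.0, rel=1e-6)
        assert res.latency == pytest.approx(0.040, abs=1e-3)
        assert res.is_local_min

    def test_flat_trace_returns_zero_with_flag(self):
        ts = _trialset(np.zeros((2, 1500)))
        res = gs.n1_amplitude(ts)
        assert res.amplitude == 0.0
        assert not res.is_local_min

    def test_mutant_n1_reduced_and_not_rescued(self, condition_sets):
        n1 = {lab: gs.n1_amplitude(z).amplitude
              for lab, z in condition_sets.items()}
        assert n1["mutant"] < n1["control"]
        # the GSK3β-manipulated preset keeps the mutant-level N1
        assert abs(n1["mutant_gsk3b_inhibited"] - n1["mutant"]) < \
            abs(n1["mutant_gsk3b_inhibited"] - n1["control"])


class TestAggregate:
    def test_per_animal_means_channels(self):
        df = metric_table([
            dict(condition="c", subject="m0", channel=f"ch{i}", metric="x",
                 value=v) for i, v in enumerate([1.0, 2.0, 3.0])
        ])
        out = gs.aggregate(df, "per_animal")
        assert len(out) == 1
        assert out["value"].iloc[0] == pytest.approx(2.0)
        assert out["channel"].iloc[0] == "all"

    def test_per_channel_identity(self):
        df = metric_table([
            dict(condition="c", subject="m0", channel=f"ch{i}", metric="x",
                 value=float(i)) for i in range(3)
        ])
        out = gs.aggregate(df, "per_channel")
        assert out.equals(df)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gs.aggregate(metric_table([]), "per_animal")
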