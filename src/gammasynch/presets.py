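"""Condition presets parameterizing the synthetic experiment.

Each preset bundles every generator parameter for one experimental group
of the NMDAR-hypofunction study design: floxed control, *Grin1* mutant,
and mutant groups in which GSK3β activity has been reduced
pharmacologically (selective inhibitor) or genetically (GABAergic-neuron
knockdown).  A GSK3α-manipulated mutant group is also registered; that
manipulation leaves every deficit in place.

The numeric values form the single calibration table below.  The sIPSC
rates are chosen so that Poisson event trains reproduce the published
mean inter-event intervals and synchronous-event percentages (e.g. a
total per-cell rate of 3.493 Hz gives a mean inter-event interval of
286 ms and, with 0.645 Hz of shared events, ~24 % of events coincide
within +/-10 ms).  LFP amplitudes are stated only qualitatively in the
source figures (z-scored group data), so those values are calibrated to
reproduce the direction and rough magnitude of every group contrast
after the full analysis round trip, not any printed number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from types import MappingProxyType
from typing import Mapping


@dataclass(frozen=True)
class GenotypePreset:
    """Frozen generator parameter bundle for one condition.

    Parameters
    ----------
    evoked_amp : float
        Amplitude (µV) of the stimulus-entrained 40-Hz LFP component.
    phase_kappa : float
        von Mises concentration of the per-trial phase of the entrained
        component; controls intertrial coherence (0 = uniform phase).
    baseline_gamma_amp : float
        Amplitude (µV) of the ongoing 35–44 Hz narrow-band activity,
        present throughout (pre-stimulus, trials, mid-ISI).
    n1_amp : float
        Depth (µV) of the negative onset event-related potential.
    pink_noise_sd : float
        Standard deviation (µV) of the 1/f broadband background.
    ipsc_indep_rate, ipsc_shared_rate : float
        Poisson rates (Hz) of per-cell independent and pair-shared
        sIPSC events.
    spike_rate : float
        Marginal firing rate (Hz) of each unit of a tetrode pair.
    spike_shared_frac : float
        Probability that an emitted spike is injected into both trains;
        equals the expected zero-lag count correlation.
    alternation_lapse : float
        Probability that a Y-maze arm choice is random instead of the
        least-recently-visited arm (1.0 = chance-level performance).
    ppi_attenuation : mapping int -> float
        Fractional startle reduction per prepulse intensity
        (dB above background).
    """

    label: str
    evoked_amp: float
    phase_kappa: float
    baseline_gamma_amp: float
    n1_amp: float
    pink_noise_sd: float
    ipsc_indep_rate: float
    ipsc_shared_rate: float
    spike_rate: float
    spike_shared_frac: float
    alternation_lapse: float
    ppi_attenuation: Mapping[int, float]

    def __post_init__(self) -> None:
        for name in ("evoked_amp", "phase_kappa", "baseline_gamma_amp", "n1_amp",
                     "pink_noise_sd", "ipsc_indep_rate", "ipsc_shared_rate",
                     "spike_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("spike_shared_frac", "alternation_lapse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        object.__setattr__(self, "ppi_attenuation",
                           MappingProxyType(dict(self.ppi_attenuation)))


# --- calibration table (all preset numbers live here) -------------------

_CONTROL = dict(
    evoked_amp=6.0,
    phase_kappa=8.0,
    baseline_gamma_amp=2.0,
    n1_amp=30.0,
    pink_noise_sd=10.0,
    ipsc_indep_rate=2.848,   # + shared 0.645 -> total 3.493 Hz, IEI ~286 ms
    ipsc_shared_rate=0.645,
    spike_rate=5.0,
    spike_shared_frac=0.30,
    alternation_lapse=0.60,  # -> expected alternation index ~70 %
    ppi_attenuation={4: 0.35, 8: 0.50, 12: 0.60, 16: 0.70},
)

_MUTANT = dict(
    evoked_amp=2.0,
    phase_kappa=1.5,
    baseline_gamma_amp=4.0,
    n1_amp=15.0,
    pink_noise_sd=10.0,
    ipsc_indep_rate=2.151,   # + shared 0.180 -> total 2.331 Hz, IEI ~429 ms
    ipsc_shared_rate=0.180,
    spike_rate=5.0,
    spike_shared_frac=0.08,
    alternation_lapse=1.00,  # chance-level spatial working memory
    ppi_attenuation={4: 0.08, 8: 0.18, 12: 0.28, 16: 0.38},
)

# GSK3β manipulations restore every readout to control level except the
# N1 onset potential, which stays at the mutant level (the inhibitor did
# not affect N1).  GSK3α manipulation restores nothing.
_PRESET_TABLE: dict[str, dict] = {
    "control": _CONTROL,
    "mutant": _MUTANT,
    "mutant_gsk3b_inhibited": {**_CONTROL, "n1_amp": _MUTANT["n1_amp"]},
    "mutant_gsk3b_knockdown": {**_CONTROL, "n1_amp": _MUTANT["n1_amp"]},
    "mutant_gsk3a_inhibited": dict(_MUTANT),
}


def registered_labels() -> tuple[str, ...]:
    """Condition labels known to :func:`make_preset`."""
    return tuple(_PRESET_TABLE)


def make_preset(label: str) -> GenotypePreset:
    """Return the frozen parameter bundle registered under ``label``.

    Raises
    ------
    KeyError
        If ``label`` is unknown; the message lists the registered labels.
    """
    try:
        params = _PRESET_TABLE[label]
    except KeyError:
        raise KeyError(
            f"unknown condition label {label!r}; registered labels: "
            f"{', '.join(registered_labels())}"
        ) from None
    return GenotypePreset(label=label, **params)
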