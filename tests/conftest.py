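import numpy as np
import pytest

from gammasynch.assr import zscore_lfp
from gammasynch.presets import GenotypePreset, make_preset
from gammasynch.synthetic import generate_assr_trials


def custom_preset(**overrides) -> GenotypePreset:
    """A minimal preset (all signal components off) with overrides."""
    base = dict(
        label="custom", evoked_amp=0.0, phase_kappa=0.0,
        baseline_gamma_amp=0.0, n1_amp=0.0, pink_noise_sd=0.0,
        ipsc_indep_rate=0.0, ipsc_shared_rate=0.0, spike_rate=1.0,
        spike_shared_frac=0.0, alternation_lapse=0.0,
        ppi_attenuation={4: 0.3, 8: 0.5, 12: 0.6, 16: 0.7},
    )
    base.update(overrides)
    return GenotypePreset(**base)


@pytest.fixture
def preset_factory():
    return custom_preset


@pytest.fixture(scope="session")
def condition_sets():
    """One z-scored trial set per condition, shared across ASSR tests."""
    return {
        label: zscore_lfp(generate_assr_trials(make_preset(label), 50, seed=11))
        for label in ("control", "mutant", "mutant_gsk3b_inhibited")
    }
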