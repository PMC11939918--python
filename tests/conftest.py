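import dataclasses

import pytest

from qcmdslb import (
    baseline_correct,
    scenario_presets,
    simulate_with_truth,
)

PRESETS = ("dopc_fig2", "slb", "partial", "slv")


@pytest.fixture(scope="session")
def simulated():
    """Baseline-corrected preset traces plus generator truth, simulated once."""
    out = {}
    for name in PRESETS:
        trace, truth = simulate_with_truth(scenario_presets(name))
        out[name] = (baseline_correct(trace), truth)
    return out


@pytest.fixture(scope="session")
def simulated_noise_free():
    """Same presets with the noise switched off."""
    out = {}
    for name in PRESETS:
        cfg = dataclasses.replace(
            scenario_presets(name), noise_sd_f=0.0, noise_sd_d=0.0
        )
        trace, truth = simulate_with_truth(cfg)
        out[name] = (baseline_correct(trace), truth)
    return out
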