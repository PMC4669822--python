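import hypothesis
import numpy as np
import pytest

import chloridephys as cp

hypothesis.settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def gaba_protocol():
    """Six-sweep voltage-clamp protocol with one brief GABA application
    fully covering the ramp of sweep 3."""
    return cp.ProtocolSpec(n_sweeps=6, application_windows=[("GABA", 16.0, 17.5)])


@pytest.fixture(scope="session")
def noiseless_control_recording(gaba_protocol):
    return cp.simulate_voltage_clamp(cp.control_cell(), gaba_protocol,
                                     noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_185l_recording(gaba_protocol):
    return cp.simulate_voltage_clamp(cp.glyr185l_cell(), gaba_protocol,
                                     noise_sd=0.0, seed=0)


def equilibrated_cl(holding: float, cl_out: float = 151.0,
                    temperature: float = 295.0) -> float:
    """[Cl-]_i whose Nernst potential equals the holding potential."""
    from chloridephys.constants import rt_over_f
    return cl_out * float(np.exp(holding / rt_over_f(temperature)))
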