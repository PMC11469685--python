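import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from slacksim import channels as ch
from slacksim import neurons as nr
from slacksim import simulate as sim

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def passive_cell():
    """Single passive compartment: 20×20 µm soma, 1e-4 S/cm² leak."""
    comp = nr.Compartment(id="soma", region="soma", length_um=20.0,
                          diameter_um=20.0, channels={ch.LEAK: 1e-4})
    return nr.NeuronModel(
        subtype="PC", compartments={"soma": comp},
        channel_library={ch.LEAK: ch.leak_spec(1e-4, -70.0)},
        na_pool=ch.NaPoolParams(clamp_to_mM=10.0))


@pytest.fixture(scope="session")
def passive_analytic(passive_cell):
    """Analytic R (Ω) and τ (ms) of the passive fixture."""
    comp = passive_cell.compartments["soma"]
    r_ohm = 1.0 / (1e-4 * comp.area_cm2)
    tau_ms = 1e-6 * comp.area_cm2 * r_ohm * 1e3
    return r_ohm, tau_ms


@pytest.fixture(scope="session")
def sst_wt():
    return nr.build_preset_neuron("SST", 0)


@pytest.fixture(scope="session")
def sst_steps(sst_wt):
    proto = sim.make_current_step_protocol("culture", max_pA=300)
    return sim.run_protocol(sst_wt, proto)
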