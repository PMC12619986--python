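import numpy as np
import pytest

from mitofiber import (
    FiberPopulationSpec,
    TraceSpec,
    fit_control_model,
    generate_fiber_population,
)

SUIT_FLUXES = {"GM": 5.0, "ADP": 15.0, "SUCC": 25.0, "OLI": 6.0, "AA": 2.0}
SUIT_H2O2 = {"GM": 10.0, "ADP": 7.0, "SUCC": 18.0, "OLI": 30.0, "AA": 5.0}
STATE_TIMES = {"GM": 0.0, "ADP": 300.0, "SUCC": 600.0, "OLI": 900.0, "AA": 1200.0}


def suit_trace_spec(noise_sd=0.0, fluor_noise_sd=0.0, seed=0, **kwargs):
    protocol = [
        (s, STATE_TIMES[s], SUIT_FLUXES[s], SUIT_H2O2[s]) for s in STATE_TIMES
    ]
    return TraceSpec(
        protocol=protocol, noise_sd=noise_sd, fluor_noise_sd=fluor_noise_sd,
        seed=seed, **kwargs,
    )


@pytest.fixture(scope="session")
def control_population():
    """Large pooled unaffected fiber population."""
    return generate_fiber_population(
        FiberPopulationSpec(n_fibers=5000, seed=11),
        section_id="CTRL", participant="U_pool", timepoint="unaffected",
    )


@pytest.fixture(scope="session")
def control_model(control_population):
    return fit_control_model(control_population, channel="ndufb8")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
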