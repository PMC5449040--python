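import numpy as np
import pytest

from coilpress import (
    EnsembleModel,
    SimulationConfig,
    ThermoState,
    load_reference,
)


@pytest.fixture(scope="session")
def library():
    return load_reference()


@pytest.fixture
def noiseless_config():
    return SimulationConfig(noise_sd_H1=0.0, noise_sd_N15=0.0)


@pytest.fixture
def two_state_model():
    """Reference two-state model: dG0=2 kJ/mol, dV0=-50 mL/mol, ddelta=2 ppm."""
    return EnsembleModel(
        (
            ThermoState("A", shift=8.0),
            ThermoState("B", shift=10.0, G0=2000.0, V0=-50.0),
        )
    )


def random_ensemble(rng: np.random.Generator, n_states: int) -> EnsembleModel:
    """Seeded random ensemble with bounded, well-scaled parameters."""
    states = tuple(
        ThermoState(
            label=f"s{i}",
            shift=float(rng.uniform(6.0, 10.0)),
            G0=float(rng.uniform(-4000.0, 4000.0)),
            V0=float(rng.uniform(-80.0, 80.0)),
            beta0=float(rng.uniform(-0.5, 0.5)),
        )
        for i in range(n_states)
    )
    return EnsembleModel(states)


def mild_ensemble(rng: np.random.Generator, n_states: int) -> EnsembleModel:
    """Gentler parameter bounds, for local-expansion accuracy checks.

    Keeps the third-order term of the shift-vs-pressure curve below
    1e-4 ppm over a 10 MPa window.
    """
    states = tuple(
        ThermoState(
            label=f"s{i}",
            shift=float(rng.uniform(7.25, 8.75)),
            G0=float(rng.uniform(-2000.0, 2000.0)),
            V0=float(rng.uniform(-30.0, 30.0)),
            beta0=float(rng.uniform(-0.05, 0.05)),
        )
        for i in range(n_states)
    )
    return EnsembleModel(states)
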