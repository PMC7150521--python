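import numpy as np
import pytest

from fluxscape.reference import build_reference_model, reference_sim_config
from fluxscape.simulate import as_dynamics, find_attractors


@pytest.fixture(scope="session")
def reference_model():
    return build_reference_model()


@pytest.fixture(scope="session")
def oscillatory_model():
    return build_reference_model(variant="oscillatory")


@pytest.fixture(scope="session")
def reference_attractors(reference_model):
    """Baseline attractor set, shared across the suite (expensive)."""
    cfg = reference_sim_config(seed=1, step=0.04, horizon=300.0, n_starts=80)
    return find_attractors(reference_model, cfg, projection=("LDH", "PDH"))


@pytest.fixture(scope="session")
def reference_landscape_samples(reference_model):
    """Post-transient Langevin sample pool for the baseline landscape."""
    from fluxscape.simulate import langevin_ensemble

    cfg = reference_sim_config(seed=3, horizon=250.0)
    return langevin_ensemble(reference_model, cfg, n_walkers=500)


@pytest.fixture(scope="session")
def reference_names(reference_model):
    return list(as_dynamics(reference_model).names)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
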