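import pytest
from hypothesis import settings

from siefel import GateModelParams, make_toy_complex, simulate_gate_trajectory

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy():
    """A parameterised toy receptor-ligand complex (18 pocket contacts)."""
    return make_toy_complex(n_residues=60, seed=7)


@pytest.fixture(scope="session")
def gate_traj(toy):
    """A short two-state gate trajectory over the toy complex."""
    return simulate_gate_trajectory(
        toy, GateModelParams(n_frames=400, seed=11))
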