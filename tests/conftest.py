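import numpy as np
import pytest

from nomefoot.reference import ReferenceSequence, index_sites
from nomefoot.simulate import Epistate, SimulationConfig, make_reference


@pytest.fixture(scope="session")
def sim_reference():
    """A 1.5 kb random reference with plenty of CpG/GpC sites."""
    return make_reference(1500, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def sim_index(sim_reference):
    return index_sites(sim_reference)


@pytest.fixture
def perfect_config():
    """Deterministic chemistry: labeling and conversion are error-free."""
    def _make(**overrides):
        kwargs = dict(
            epistates=[Epistate("occluded", 1.0, [(400, 550)])],
            n_molecules=10,
            labeling_efficiency=1.0,
            protected_leak=0.0,
            conversion_rate=1.0,
            conversion_failure=0.0,
            seq_error=0.0,
            cpg_meth_prob=0.3,
            seed=42,
        )
        kwargs.update(overrides)
        return SimulationConfig(**kwargs)
    return _make


def random_reference(rng: np.random.Generator, length: int) -> ReferenceSequence:
    bases = "".join(rng.choice(list("ACGT"), size=length))
    return ReferenceSequence("rand", bases)
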