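import numpy as np
import pytest

from dcnatools.synthetic_ensembles import PlantedSpec, generate_state


@pytest.fixture(scope="session")
def planted_two_state():
    """Small two-community system with one planted interface, both layers."""
    spec = PlantedSpec(
        n_communities=2,
        nodes_per_community=6,
        frames=200,
        seed=42,
        inter_contact_p={(0, 1): 0.8},
    )
    ens, labels = generate_state(spec, "apo")
    return spec, ens, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
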