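import pytest

from fluxmark import augment, expression, network, synthetic


@pytest.fixture(scope="session")
def toy_net():
    """Augmented toy network (fixed constant)."""
    return synthetic.make_toy_network()


@pytest.fixture(scope="session")
def toy_base():
    """Toy network before histone augmentation."""
    return synthetic.make_toy_network(augmented=False)


@pytest.fixture(scope="session")
def octanoate_state():
    """Planted octanoate expression state from the seeded DE generator."""
    de, _ = synthetic.simulate_de_table(synthetic.SyntheticConfig(seed=1))
    return expression.categorize_genes(de)


def _condition_setup(net, media, state):
    bounded = augment.apply_media_config(net, media)
    split = network.split_reversible(bounded)
    cats = expression.map_genes_to_reactions(bounded, state)
    return split, cats


@pytest.fixture(scope="session")
def octanoate_setup(toy_net, octanoate_state):
    """(split network, categories) for the octanoate-treated condition."""
    return _condition_setup(toy_net, augment.octanoate_media(), octanoate_state)


@pytest.fixture(scope="session")
def control_setup(toy_net, octanoate_state):
    """(split network, categories) for the control condition (mirrored state)."""
    return _condition_setup(toy_net, augment.control_media(), octanoate_state.mirrored())
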