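import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_tree_set_noiseless():
    """Five identical trees generated under the demo clock with no noise."""
    from tdrpclock.simulate import demo_sim_spec, simulate_posterior_trees

    spec = demo_sim_spec(sigma=0.0, n_trees=5)
    return simulate_posterior_trees(spec, seed=1)


@pytest.fixture(scope="session")
def demo_tree_set_noisy():
    """500 trees with lognormal height noise sigma=0.1 under the demo clock."""
    from tdrpclock.simulate import demo_sim_spec, simulate_posterior_trees

    spec = demo_sim_spec(sigma=0.1, n_trees=500)
    return simulate_posterior_trees(spec, seed=7)
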