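import numpy as np
import pytest

import earlyburst as eb


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cherry3():
    return eb.TimeTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4():
    return eb.TimeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def yule30():
    """A conditioned 30-tip pure-birth tree, fixed across the session."""
    spec = eb.ConditioningSpec(crown_age=15.0, n_extant=30, rate_sampler=(0.1, 0.4))
    return eb.simulate_conditioned_tree(spec, seed=7)


@pytest.fixture(scope="session")
def fixture_bundle():
    """Default synthetic study bundle (tree, traits, richness)."""
    return eb.make_fixture(eb.FixtureSpec(), seed=1)
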