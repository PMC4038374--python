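import pytest

import allomorph as am


@pytest.fixture(scope="session")
def neognath():
    return am.load_neognath()


@pytest.fixture(scope="session")
def land_birds(neognath):
    return am.subset_clade(neognath, "Land birds")


@pytest.fixture()
def hand_tree():
    # 3 tips, all depths 2: hand-checkable covariance structure
    return am.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule38():
    return am.simulate_yule_tree(38, seed=101, depth=110.0)
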