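import pytest

from icerank.datasets import SyntheticConfig, generate_portfolio, load_paper_dataset


@pytest.fixture(scope="session")
def paper_arms():
    return load_paper_dataset()


@pytest.fixture(scope="session")
def arms_by_id(paper_arms):
    return {arm.arm_id: arm for arm in paper_arms}


@pytest.fixture(scope="session")
def eligible_arms(paper_arms):
    return [a for a in paper_arms if a.league_eligible]


@pytest.fixture()
def synthetic_portfolio():
    return generate_portfolio(SyntheticConfig(n_arms=8, seed=123))
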