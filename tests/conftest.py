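import pytest

import ecdtrial as et


@pytest.fixture(scope="session")
def default_trial() -> et.TrialDataset:
    """One default-configuration synthetic trial (31 clusters, n=620)."""
    return et.simulate_trial(seed=1234)


@pytest.fixture(scope="session")
def scored_trial(default_trial):
    """The default trial with every instrument scored."""
    return et.score_dataset(default_trial.df)


@pytest.fixture(scope="session")
def small_trial() -> et.TrialDataset:
    """A small, fast trial: 12 clusters x 10 participants, no attrition."""
    return et.simulate_trial(
        n_clusters_per_arm_per_stratum={"A": {"group": 2, "combined": 2, "control": 2},
                                        "B": {"group": 2, "combined": 2, "control": 2}},
        participants_per_cluster=10, attrition_rate=0.0, seed=7)
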