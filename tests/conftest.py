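import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def zero_noise_experiment():
    """One noiseless default-truth experiment, shared across tests."""
    from cryotrace import default_truth, simulate

    truth = default_truth().zero_noise()
    return simulate(truth, seed=7)


@pytest.fixture(scope="session")
def zero_noise_results(zero_noise_experiment):
    """Pipeline results for the shared noiseless experiment."""
    from cryotrace import CoolingExperiment

    return CoolingExperiment.from_tables(zero_noise_experiment.tables).fit()
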