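import pytest
from hypothesis import HealthCheck, settings

from mixtraits import experiment_model as em
from mixtraits import synthetic_data as sd

settings.register_profile(
    "package", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def experiment():
    """A default synthetic experiment (moderate noise, seed fixed)."""
    return sd.generate_experiment(sd.GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def samples(experiment):
    return em.pool_to_genotype_pot(experiment.plants, experiment.nitrogen, experiment.design)


@pytest.fixture(scope="session")
def pooled_samples(samples):
    return em.pool_irrigation_replicates(samples)


@pytest.fixture(scope="session")
def noise_free_experiment():
    cfg = sd.GeneratorConfig(sigma_plant=0.0, sigma_organ=0.0, pot_sd=0.0, conc_sd=0.0, cutting_sd=0.0)
    return sd.generate_experiment(cfg, seed=2)


@pytest.fixture(scope="session")
def noise_free_samples(noise_free_experiment):
    e = noise_free_experiment
    return em.pool_to_genotype_pot(e.plants, e.nitrogen, e.design)
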