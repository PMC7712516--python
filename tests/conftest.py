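import warnings

import pytest
from hypothesis import settings

from sf6dbeta.models import ModelData, ModelSpec
from sf6dbeta.preprocessing import build_dataset, filter_constant_respondents
from sf6dbeta.sampler import ChainConfig, run_mcmc
from sf6dbeta.synthetic import GeneratorConfig, generate_study

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_study():
    """One default-size synthetic study (126 respondents, no constants)."""
    return generate_study(GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def retained(default_study):
    adjusted = build_dataset(default_study.valuations, default_study.respondents)
    kept, _ = filter_constant_respondents(adjusted)
    return kept


@pytest.fixture(scope="session")
def brre_draws(retained):
    """A short BR+RE fit on the default study, shared across tests."""
    spec = ModelSpec.from_name("BR+RE")
    data = ModelData.from_dataframe(retained, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = run_mcmc(spec, data, ChainConfig(burn_in=400, n_samples=800, seed=11))
    return spec, data, draws


@pytest.fixture(scope="session")
def lrre_draws(retained):
    """A short LR+RE fit on the default study, shared across tests."""
    spec = ModelSpec.from_name("LR+RE")
    data = ModelData.from_dataframe(retained, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = run_mcmc(spec, data, ChainConfig(burn_in=400, n_samples=800, seed=12))
    return spec, data, draws


@pytest.fixture(scope="session")
def tiny_study():
    """A small study (14 respondents, 112 records) for fast refit loops."""
    return generate_study(GeneratorConfig(n_respondents=14, seed=55))


@pytest.fixture(scope="session")
def tiny_retained(tiny_study):
    adjusted = build_dataset(tiny_study.valuations, tiny_study.respondents)
    kept, _ = filter_constant_respondents(adjusted)
    return kept
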