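"""Shared fixtures: synthetic bundles and pipeline runs reused across tests."""

import pytest

from sretools import synth
from sretools.io import PipelineConfig
from sretools.pipeline import run_pipeline


def noiseless_spec(**overrides) -> synth.ScenarioSpec:
    kwargs = dict(seed=1, gas_noise_sd=0.0, metabolite_noise_sd=0.0,
                  biomass_noise_sd=0.0, flow_noise_sd=0.0,
                  glucose_noise_sd=0.0, ammonia_noise_sd=0.0)
    kwargs.update(overrides)
    return synth.ScenarioSpec(**kwargs)


@pytest.fixture(scope="session")
def noiseless_dataset():
    return synth.generate_sre_dataset(noiseless_spec())


@pytest.fixture(scope="session")
def noiseless_bundle(tmp_path_factory, noiseless_dataset):
    d = tmp_path_factory.mktemp("bundle_noiseless")
    noiseless_dataset.write(d)
    return d


@pytest.fixture(scope="session")
def noiseless_result(noiseless_bundle):
    return run_pipeline(PipelineConfig(), noiseless_bundle)


@pytest.fixture(scope="session")
def noisy_dataset():
    return synth.generate_sre_dataset(synth.ScenarioSpec(seed=1))


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory, noisy_dataset):
    d = tmp_path_factory.mktemp("bundle_noisy")
    noisy_dataset.write(d)
    return d


@pytest.fixture(scope="session")
def noisy_result(noisy_bundle):
    return run_pipeline(PipelineConfig(), noisy_bundle)
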