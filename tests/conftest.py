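import pytest
from hypothesis import HealthCheck, settings

from transportome import (
    RunConfig,
    bundled_registry,
    paper_like_specs,
    run_pipeline,
    simulate_dataset,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return bundled_registry()


@pytest.fixture(scope="session")
def clean_small():
    """Six species per group, no artifact injection."""
    specs = paper_like_specs(n_species=6, artifact_scale=0.0)
    return simulate_dataset(specs, seed=11)


@pytest.fixture(scope="session")
def noisy_small():
    """Six species per group with all four artifact types injected."""
    specs = paper_like_specs(n_species=6)
    return simulate_dataset(specs, seed=12)


def _run(dataset, tmp_dir, **config_kwargs):
    config = RunConfig(annotations="", metadata="", out_dir=tmp_dir, **config_kwargs)
    return run_pipeline(
        config, annotations=dataset.annotations, metadata=dataset.metadata
    )


@pytest.fixture(scope="session")
def noisy_result(noisy_small, tmp_path_factory):
    return _run(noisy_small, tmp_path_factory.mktemp("noisy_run"))


@pytest.fixture(scope="session")
def study_scale():
    """The six-group recovery scenario: 30 species per group, artifacts on."""
    specs = paper_like_specs(n_species=30)
    return simulate_dataset(specs, seed=1)


@pytest.fixture(scope="session")
def study_result(study_scale, tmp_path_factory):
    return _run(study_scale, tmp_path_factory.mktemp("study_run"))
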