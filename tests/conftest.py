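import pytest

from memomir.pipeline import PipelineConfig, run_pipeline
from memomir.simulate import (
    ScenarioConfig,
    build_ground_truth,
    expected_count_matrix,
    make_reference,
)


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    return ScenarioConfig()


@pytest.fixture(scope="session")
def small_reference(small_config):
    return make_reference(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_reference):
    return build_ground_truth(small_config, small_reference)


@pytest.fixture(scope="session")
def small_layout(small_config):
    return expected_count_matrix(small_config)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("small_run")
    report = run_pipeline(PipelineConfig(scenario=small_config, outdir=out))
    return report, out


@pytest.fixture(scope="session")
def preset_run(tmp_path_factory):
    """One full pipeline execution of the cs-memory-v1 preset, shared by the
    acceptance-style tests."""
    out = tmp_path_factory.mktemp("preset_run")
    config = PipelineConfig.from_preset("cs-memory-v1", out)
    report = run_pipeline(config)
    return report, out, config
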