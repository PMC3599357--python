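import pytest

from integranet.pipeline import load_config, run_pipeline
from integranet.synthetic_data import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory):
    """Default synthetic scenario (low noise) with planted ground truth."""
    base = tmp_path_factory.mktemp("scenario_default")
    truth = generate_scenario(ScenarioConfig(seed=0), base)
    return base, truth


@pytest.fixture(scope="session")
def pipeline_result(default_scenario):
    """Full pipeline run on the default scenario."""
    base, truth = default_scenario
    config = load_config(base / "scenario_config.toml")
    result = run_pipeline(config, base / "out")
    return truth, result


@pytest.fixture(scope="session")
def noisefree_scenario(tmp_path_factory):
    """Noise-free scenario: zero expression noise, no peak errors."""
    base = tmp_path_factory.mktemp("scenario_clean")
    truth = generate_scenario(
        ScenarioConfig(seed=3, noise_sigma=0.0, peak_fp_rate=0.0,
                       peak_fn_rate=0.0), base)
    return base, truth
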