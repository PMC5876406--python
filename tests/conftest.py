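import pytest

from knucklecrack import RunConfig, simulate


@pytest.fixture(scope="session")
def baseline_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def baseline_result(baseline_config):
    """One baseline pipeline run shared by the whole session."""
    result = simulate(baseline_config)
    assert result.converged, result.reason
    return result
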