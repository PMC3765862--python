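import pytest
from hypothesis import HealthCheck, settings

import physupply as pp

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fx() -> pp.JapanFixture:
    return pp.japan_fixture()


@pytest.fixture(scope="session")
def calibration() -> pp.CalibrationResult:
    """Retirement hazard refit to the 1998-2008 historic series."""
    return pp.calibrate_fixture()


@pytest.fixture(scope="session")
def calibrated_params(calibration) -> pp.ParameterSet:
    return pp.fixture_parameter_set(
        retirement_all=calibration.fitted["retirement_rate"]
    )


@pytest.fixture(scope="session")
def sensitivity_results(calibrated_params):
    """The fixture scenario grid run on the calibrated parameters."""
    return pp.run_sensitivity(
        calibrated_params,
        pp.fixture_scenarios(),
        pp.fixture_clock(),
        pp.fixture_criteria(),
    )
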