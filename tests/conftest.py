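import pytest

from ccsscreen import (
    CalibrantPoint,
    CalibrationModel,
    Mode,
    ccs_to_dt,
    fit_calibration,
    reference_library,
)


@pytest.fixture(scope="session")
def power_law_model() -> CalibrationModel:
    """A TWIMS calibration with known generating parameters."""
    return CalibrationModel(400.0, 0.55, edc_coefficient=1.4)


@pytest.fixture(scope="session")
def fitted_model(power_law_model) -> CalibrationModel:
    """Calibration refitted from noise-free synthetic calibrants."""
    points = [
        CalibrantPoint(mz, 1, ccs_to_dt(ccs, mz, 1, power_law_model), ccs)
        for mz, ccs in [(120.0, 110.0), (250.0, 150.0), (420.0, 185.0),
                        (600.0, 225.0), (780.0, 260.0)]
    ]
    return fit_calibration(points, edc_coefficient=1.4)


@pytest.fixture(scope="session")
def ref_library():
    return reference_library()


@pytest.fixture(scope="session")
def wet_library(ref_library):
    return [e for e in ref_library if e.mode is Mode.WET]


@pytest.fixture(scope="session")
def dry_library(ref_library):
    return [e for e in ref_library if e.mode is Mode.DRY]
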