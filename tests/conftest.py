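import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from pawcal.calibration import CalibrationParams
from pawcal.synthetic import (
    AequorinPool,
    CaKinetics,
    PlateRunConfig,
    make_ca_trajectory,
    make_luminescence,
)


@pytest.fixture
def plate_config() -> PlateRunConfig:
    return PlateRunConfig()


@pytest.fixture
def default_params() -> CalibrationParams:
    return CalibrationParams()


@pytest.fixture
def simulate_well(plate_config):
    """Factory: kinetics -> (truth trajectory, luminescence trace)."""

    def _simulate(kinetics: CaKinetics | None = None, seed: int = 42,
                  pool_counts: float = 1e7):
        kinetics = kinetics or CaKinetics()
        truth = make_ca_trajectory(kinetics, plate_config.time_grid())
        lum = make_luminescence(
            truth, AequorinPool(pool_counts), plate_config, seed=seed
        )
        return truth, lum

    return _simulate
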