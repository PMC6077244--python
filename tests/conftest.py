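import numpy as np
import pytest

from tmad import (
    AnatomicalConstants,
    BreathManeuver,
    ExchangeParams,
    GenerationTable,
    build_grid,
    estimate_exchange_params,
)


@pytest.fixture(scope="session")
def constants():
    return AnatomicalConstants()


@pytest.fixture(scope="session")
def generation_table():
    return GenerationTable.default()


@pytest.fixture(scope="session")
def grid(constants, generation_table):
    return build_grid(constants, generation_table, dz=0.1)


@pytest.fixture(scope="session")
def healthy_params():
    """Healthy-population morphometric/Haldane estimate."""
    return estimate_exchange_params()


@pytest.fixture(scope="session")
def row_b_params():
    """Fitted subject parameters for the reference 121 ml/s maneuver."""
    return ExchangeParams(J_aw=220.0, D_aw=1.6, J_A=1.76e7, D_A=7400.0)


@pytest.fixture(scope="session")
def row_b_maneuver():
    return BreathManeuver(
        IFR=121.0, EFR=121.0, V_in=726.0, V_ex=726.0, C_ambient=130.0
    )


@pytest.fixture(scope="session")
def sweep_params():
    """Subject-averaged parameters used for flow-rate sweeps."""
    return ExchangeParams(J_aw=220.0, D_aw=1.6, J_A=1.82e7, D_A=7767.0)


def end_tidal_mean(expirogram, frac=0.05):
    mask = expirogram.volume_ml >= (1 - frac) * expirogram.volume_ml[-1]
    return float(np.mean(expirogram.co_ppb[mask]))
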