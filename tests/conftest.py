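import numpy as np
import pytest

from gdsim import (
    DriveParams,
    LifecycleParams,
    calibrate_equilibrium,
    estimate_cut_params,
    pooled_counts_from_table,
)
from gdsim.datasets import CARB109_DEPOSITION_RATE, load_ox1_pool_counts


@pytest.fixture(scope="session")
def pool_table():
    return load_ox1_pool_counts()


def _line_params(table, line, xi):
    ests = {s: estimate_cut_params(pooled_counts_from_table(table, line, s)) for s in "FM"}
    return DriveParams(
        cF=ests["F"].c, chF=ests["F"].ch, crF=ests["F"].cr,
        cM=ests["M"].c, chM=ests["M"].ch, crM=ests["M"].cr,
        dF=CARB109_DEPOSITION_RATE[line], dhF=0.0, drF=1.0,
        fertility_mult=0.9, xiF=xi, xiM=xi,
    )


@pytest.fixture(scope="session")
def nos_params(pool_table):
    """Nos-promoter drive line: strong drive, resistance formation, fitness cost."""
    return _line_params(pool_table, "AeaNosC109", xi=0.90)


@pytest.fixture(scope="session")
def zpg_params(pool_table):
    """Zpg-promoter drive line: weaker drive, little resistance, no viability cost."""
    return _line_params(pool_table, "AeaZpgC109", xi=1.0)


@pytest.fixture(scope="session")
def lifecycle():
    return LifecycleParams()


@pytest.fixture(scope="session")
def calibration(lifecycle):
    return calibrate_equilibrium(lifecycle)
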