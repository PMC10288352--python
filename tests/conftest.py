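import numpy as np
import pytest

from inhibkit.params import KineticParams, NoiseModel, QuenchParams, TitrationScheme

# Reference constants used throughout the suite: the values the published
# characterization reports for this inhibitor-enzyme pair.
KI_REF = 10.6  # μmol/L
KIS_REF = 57.24  # μmol/L
IC50_REF = 22.97  # μmol/L
KSV_REF = {298.0: 1.881e5, 304.0: 1.661e5, 310.0: 1.455e5}  # L/mol
KA_REF = {298.0: 1.67e4, 304.0: 1.21e4, 310.0: 1.17e4}  # L/mol
N_REF = {298.0: 1.183, 304.0: 1.236, 310.0: 1.308}
DH_REF = -23.07  # kJ/mol
DS_REF = 3.36  # J/(mol*K)
SUBSTRATE_GRID = (6.25, 12.5, 25.0, 50.0)
INHIBITOR_GRID = (0.0, 5.21, 10.42, 20.83, 41.67)
TEMPERATURES = (298.0, 304.0, 310.0)


@pytest.fixture
def kin_params():
    return KineticParams(vmax=1.0, km=10.0, ki=KI_REF, kis=KIS_REF)


@pytest.fixture
def scheme():
    return TitrationScheme(v0=2.0, va=0.1, c_stock=100.0, n_additions=8)


@pytest.fixture
def quench_params_298():
    return QuenchParams(
        f0=1000.0,
        ksv=KSV_REF[298.0],
        ka=KA_REF[298.0],
        n=N_REF[298.0],
        eps_ex=0.012,
        eps_em=0.004,
    )


@pytest.fixture
def noiseless():
    return NoiseModel(rel_sd=0.0, seed=0)


def ols_slope_intercept(x, y):
    """Independent two-pass OLS oracle (centered sums, no library call)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    return slope, ym - slope * xm
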