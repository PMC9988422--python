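import numpy as np
import pytest

from transwellbench import InsertGeometry, SimulationConfig
from transwellbench.datasets import load_reference_efflux


@pytest.fixture(scope="session")
def geometry() -> InsertGeometry:
    return InsertGeometry(membrane_area=0.33, luminal_volume=400.0, abluminal_volume=600.0)


@pytest.fixture(scope="session")
def reference_efflux():
    return load_reference_efflux()


@pytest.fixture()
def noise_free_config(geometry) -> SimulationConfig:
    return SimulationConfig(geometry=geometry, noise_cv=0.0, replicates=1)


def ols_slope_intercept(x, y):
    """Normal-equations least-squares line, independent of the fitting code."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    slope = float(np.dot(xc, y) / np.dot(xc, xc))
    return slope, float(y.mean() - slope * x.mean())


def pooled_t(a, b):
    """Two-sample equal-variance t statistic and two-tailed p, from the textbook
    formula and the t distribution tail (independent of scipy.stats.ttest_ind)."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return float(t), float(p)
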