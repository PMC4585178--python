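import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fermopt import datasets, fit_quadratic

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# the reciprocal criteria matrix reconstructed from importance ranks (1,2,3,4)
CRITERIA_MATRIX = np.array([
    [1, 1 / 2, 1 / 3, 1 / 4],
    [2, 1, 1 / 2, 1 / 2],
    [3, 2, 1, 1 / 2],
    [4, 2, 2, 1],
], dtype=float)

# published second-order model in actual units (g/L), term order:
# intercept, x1, x2, x3, x1:x2, x1:x3, x2:x3, x1^2, x2^2, x3^2
ACTUAL_UNITS_COEF = np.array([
    -0.090205, 9.13708e-3, 0.014698, 2.88754e-3,
    -4.22917e-4, -2.83125e-4, -1.08750e-4,
    -3.75750e-5, -4.37036e-4, -4.68498e-6,
])


@pytest.fixture(scope="session")
def criteria_matrix():
    return CRITERIA_MATRIX.copy()


@pytest.fixture(scope="session")
def ccd_table():
    return datasets.load_ccd_runs()


@pytest.fixture(scope="session")
def ccd_fit(ccd_table):
    X = ccd_table[["x1", "x2", "x3"]].to_numpy()
    y = ccd_table["response"].to_numpy()
    return fit_quadratic(X, y)


@pytest.fixture(scope="session")
def actual_units_coef():
    return ACTUAL_UNITS_COEF.copy()
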