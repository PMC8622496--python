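import numpy as np
import pytest

from swimstack.containers import ChamberGeometry, DetectionModel
from swimstack.synthetic import make_benchmark_dataset


@pytest.fixture(scope="session")
def geom():
    return ChamberGeometry()


@pytest.fixture(scope="session")
def det():
    return DetectionModel()


@pytest.fixture(scope="session")
def geom5():
    """Tiny 5-slice chamber for enumerable stationary laws."""
    return ChamberGeometry(depth=200.0, slice_interval=50.0)


@pytest.fixture(scope="session")
def benchmark():
    """Seeded benchmark table with ground truth alpha = (4, 2), ~1e4 cells."""
    counts, truth = make_benchmark_dataset(4.0, 2.0, 3.0e5, seed=7)
    return counts, truth


def dtmc_stationary_oracle(m, rate=0.1, dt=1.0):
    """Independent stationary-law oracle for the agent chain.

    Builds the literal transition matrix of the fixed-step walk (move
    probability rate*m_j*dt per available direction) and power-iterates it;
    no swimstack code involved.
    """
    m = np.asarray(m, dtype=float)
    J = m.size
    P = np.zeros((J, J))
    for j in range(J):
        p = rate * m[j] * dt
        if j > 0:
            P[j, j - 1] = p
        if j < J - 1:
            P[j, j + 1] = p
        P[j, j] = 1.0 - P[j].sum()
    pi = np.full(J, 1.0 / J)
    for _ in range(200000):
        new = pi @ P
        if np.abs(new - pi).max() < 1e-15:
            return new
        pi = new
    return pi
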