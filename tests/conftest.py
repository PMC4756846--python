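import numpy as np
import pytest

from gatefit import ANDGateParams, FourPLParams, NoiseModel, default_levels, simulate_matrix


@pytest.fixture
def fourpl_ref() -> FourPLParams:
    """Reference activating 4PL curve used across fitting tests."""
    return FourPLParams(y0=100.0, ymax=10100.0, ec50=50.0, n=1.0)


@pytest.fixture
def gate_ref() -> ANDGateParams:
    """Reference leaky AND gate: K1=120 uM, K2=66 uM, 12-fold enhancement."""
    return ANDGateParams(y0=100.0, dy=10000.0, n=1.0, k1=120.0, k2=66.0, f1=1.0 / 12.0)


@pytest.fixture
def noiseless_matrix(gate_ref):
    """Noiseless 12x12 induction matrix (zero plus 11 log-spaced levels
    spanning 0.01-100x each half-maximal constant)."""
    return simulate_matrix(
        gate_ref,
        i_levels=default_levels(gate_ref.k1, 11),
        p_levels=default_levels(gate_ref.k2, 11),
        replicates=1,
        noise=NoiseModel(kind="none"),
    )


def log_points(ec50: float, n_points: int = 10) -> np.ndarray:
    """Log-spaced titration points spanning 0.01-100x an EC50."""
    return np.geomspace(0.01 * ec50, 100.0 * ec50, n_points)
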