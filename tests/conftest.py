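import numpy as np
import pytest

from irfakit import (
    BindingParameters,
    KineticSettings,
    build_antigen_series,
    distort_grid,
    generate_ideal_grid,
    DEFAULT_KD_AXIS,
)


@pytest.fixture(scope="session")
def params():
    """Study defaults: r = 70%, T = 0.1 nM, kon = 1.444e-4 nM^-1 min^-1."""
    return BindingParameters()


@pytest.fixture(scope="session")
def antigen():
    return build_antigen_series("unsaturated")


@pytest.fixture(scope="session")
def ideal_grid(params, antigen):
    """Noise-free equilibrium grid over the nine-K_D axis."""
    return generate_ideal_grid(DEFAULT_KD_AXIS, antigen, params)


@pytest.fixture(scope="session")
def distorted_grid(ideal_grid):
    """The same grid under kinetic distortion at t = 1200 min."""
    return distort_grid(ideal_grid, KineticSettings())


def fixed_point_bound_fraction(ag0, r, kd, T, n_iter=20000):
    """Independent oracle: iterate the mass balance B <- r*T*(ag0-B)/((ag0-B)+KD)."""
    B = 0.0
    for _ in range(n_iter):
        B = r * T * (ag0 - B) / ((ag0 - B) + kd)
    return B / T
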