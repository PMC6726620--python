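"""Shared fixtures: canonical constructs, protocols, and analytic oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from tweezfold.constructs import (
    cnb_a,
    cnb_b,
    default_protocol,
    domain_from_delta_lc,
    kinetics_for_clamp,
    n3a_motif,
)
from tweezfold.forcekinetics import KineticParams


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def apo_kinetics():
    """Bell parameters inside the measured apo ranges."""
    return KineticParams(tau0=1.3e3, dx_ddagger=4.5)


@pytest.fixture(scope="session")
def camp_cnba_domain():
    return cnb_a("camp")


@pytest.fixture(scope="session")
def wt_hopping_domain():
    """N3A-like hopping unit at the wild-type contour-length change."""
    unfold, refold = kinetics_for_clamp(0.5, 0.3, clamp_force=11.0)
    return domain_from_delta_lc(
        "N3A-WT", 9.5, unfold, refold, n_residues=30, reversible=True
    )


def bell_mean_rupture_force(kin: KineticParams, loading_rate: float) -> float:
    """Quadrature oracle: mean of the Bell–Evans first-passage density."""

    def hazard_integral(F):
        return quad(
            lambda f: 1.0 / (loading_rate * kin.lifetime(f)), 0.0, F, limit=200
        )[0]

    def survival(F):
        return np.exp(-hazard_integral(F))

    return quad(survival, 0.0, 60.0, limit=200)[0]


def analytic_density(kin: KineticParams, loading_rate: float, grid):
    """Oracle p(F) on a grid by direct hazard integration (independent of
    the package's reconstruction routine)."""
    out = np.empty(len(grid))
    for i, F in enumerate(grid):
        h = quad(
            lambda f: 1.0 / (loading_rate * kin.lifetime(f)), 0.0, F, limit=200
        )[0]
        out[i] = np.exp(-h) / (loading_rate * kin.lifetime(F))
    return out
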