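import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from helicalct import (
    AnalyticPhantom,
    Ellipsoid,
    FanDetector,
    HelixGeometry,
    make_knee_phantom,
    simulate_projections,
)
from helicalct.geometry import TWO_PI, uniform_phases

settings.register_profile(
    "det", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")


def make_geom(n_sources=1, pitch=12.0, n_gamma=33, fan_half=0.38, n_rows=1,
              row_pitch=3.0, rho=300.0):
    det = FanDetector.equiangular(n_gamma, fan_half, n_rows=n_rows, row_pitch=row_pitch)
    return HelixGeometry(
        rho=rho, omega=TWO_PI, phases=uniform_phases(n_sources), pitch=pitch, detector=det
    )


def scan(phantom, geom, turns=5, n_beta_per_turn=72):
    beta = np.linspace(0.0, TWO_PI * turns, turns * n_beta_per_turn, endpoint=False)
    return simulate_projections(phantom, geom, beta)


def commensurate_geom(n_sources=1, pitch=12.0, n_beta_per_turn=144, half_bins=16,
                      n_rows=1, row_pitch=3.0, rho=300.0):
    """Geometry whose fan-angle spacing is half the beta spacing, so both
    direct and complementary partner angles land exactly on stored samples."""
    dbeta = TWO_PI / n_beta_per_turn
    det = FanDetector.equiangular(2 * half_bins + 1, half_bins * dbeta / 2.0,
                                  n_rows=n_rows, row_pitch=row_pitch)
    return HelixGeometry(
        rho=rho, omega=TWO_PI, phases=uniform_phases(n_sources), pitch=pitch, detector=det
    )


@pytest.fixture(scope="session")
def smooth_phantom():
    """A single large off-center ellipsoid: smooth attenuation in z."""
    return AnalyticPhantom(
        ellipsoids=[Ellipsoid(center=(5, -8, 10), semi_axes=(50, 40, 70), attenuation_delta=0.02)],
        bounding_radius=100,
    )


@pytest.fixture(scope="session")
def sphere_phantom():
    return AnalyticPhantom(
        ellipsoids=[Ellipsoid(center=(0, 0, 0), semi_axes=(30, 30, 30), attenuation_delta=0.02)],
        bounding_radius=50,
    )


@pytest.fixture(scope="session")
def disk_phantom():
    """Effectively a cylinder: a disk of radius 40 mm, mu = 0.02/mm, in any
    plane near z = 0."""
    return AnalyticPhantom(
        ellipsoids=[Ellipsoid(center=(0, 0, 0), semi_axes=(40, 40, 500), attenuation_delta=0.02)],
        bounding_radius=550,
    )


@pytest.fixture(scope="session")
def knee_phantom():
    return make_knee_phantom(seed=0)
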