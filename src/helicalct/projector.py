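"""Fan-beam forward projection of analytic phantoms along helical orbits.

Projection values are exact line integrals through the analytic phantom —
not ray-marching through a voxel grid — so the simulator doubles as its own
oracle and discretization never confounds interpolation experiments.  A
Siddon-style voxel projector is provided separately for voxelized volumes.

Ray convention: the ray (i, beta, gamma, q) starts at source i's position at
rotation angle beta, displaced to row q's z plane (cone angle ignored), and
points at in-plane angle ``theta + pi + gamma`` where ``theta`` is the
source's lab angular position — positive gamma rotates the ray toward the
increasing-beta side.  This yields the classic complementary-ray identity
(beta + 2*gamma + pi, -gamma) for the opposed ray.

Noise model: monochromatic Beer–Lambert with Poisson counting statistics —
counts ~ Poisson(I0 * exp(-p)) clamped to >= 1, then p = ln(I0 / counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .geometry import HelixGeometry
from .phantom import AnalyticPhantom, VoxelVolume, analytic_line_integrals
from .zinterp import PlanarFan

__all__ = [
    "SourceSinogram",
    "ray_of",
    "simulate_projections",
    "simulate_planar_fan",
    "project_voxels",
]


@dataclass
class SourceSinogram:
    """Projections of one source: values[beta, gamma, q] in attenuation*mm."""

    values: np.ndarray
    beta_grid: np.ndarray
    gamma_grid: np.ndarray
    source_index: int
    geometry: Optional[HelixGeometry] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.beta_grid = np.asarray(self.beta_grid, dtype=float)
        self.gamma_grid = np.asarray(self.gamma_grid, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("sinogram values must be (beta, gamma, q)")
        if self.values.shape[0] != self.beta_grid.size or self.values.shape[1] != self.gamma_grid.size:
            raise ValidationError("grid sizes do not match the value array")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("sinogram values must be finite")
        if self.beta_grid.size > 1:
            db = np.diff(self.beta_grid)
            if np.any(np.abs(db - db[0]) > 1e-12 * max(1.0, abs(db[0]))):
                raise ValidationError("beta_grid must be uniform")

    @property
    def dbeta(self) -> float:
        return float(self.beta_grid[1] - self.beta_grid[0])


def ray_of(geom: HelixGeometry, i: int, beta: float, gamma: float, q: int):
    """(origin, unit direction) of the ray (i, beta, gamma, q)."""
    theta = float(geom.angular_position(i, beta))
    z = float(geom.row_z(i, beta, q))
    origin = np.array([geom.rho * np.cos(theta), geom.rho * np.sin(theta), z])
    ang = theta + np.pi + gamma
    direction = np.array([np.cos(ang), np.sin(ang), 0.0])
    return origin, direction


def _fan_rays(geom: HelixGeometry, theta: np.ndarray, z: np.ndarray, gamma_grid: np.ndarray):
    """Origins/directions for a (n_beta, n_gamma) fan family (flattened)."""
    B, G = theta.size, gamma_grid.size
    ox = geom.rho * np.cos(theta)
    oy = geom.rho * np.sin(theta)
    origins = np.stack(
        [np.repeat(ox, G), np.repeat(oy, G), np.repeat(z, G)], axis=1
    )
    ang = theta[:, None] + np.pi + gamma_grid[None, :]
    directions = np.stack(
        [np.cos(ang).ravel(), np.sin(ang).ravel(), np.zeros(B * G)], axis=1
    )
    return origins, directions


def simulate_projections(
    phantom: AnalyticPhantom,
    geom: HelixGeometry,
    beta_grid: np.ndarray,
    noise: Optional[tuple[float, int]] = None,
) -> list[SourceSinogram]:
    """Simulate G_i(beta, gamma, q) for every source along the helix.

    ``noise``: optional (I0, seed) pair; I0 is the unattenuated photon
    count per ray.  Noise draws are made source-by-source, row-by-row, in
    index order, from one generator seeded with ``seed``.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if beta_grid.size == 0:
        raise ValidationError("beta_grid must not be empty")
    rng = None
    if noise is not None:
        i0, seed = noise
        if i0 <= 0:
            raise ValidationError("photon count I0 must be positive")
        rng = np.random.default_rng(seed)

    gamma_grid = geom.detector.gamma_grid
    B, G, Q = beta_grid.size, gamma_grid.size, geom.detector.n_rows
    out = []
    for i in range(1, geom.n_sources + 1):
        theta = geom.angular_position(i, beta_grid)
        z_src = np.broadcast_to(geom.z_at(beta_grid), theta.shape)
        vals = np.empty((B, G, Q))
        for qi, off in enumerate(geom.detector.row_offsets):
            origins, directions = _fan_rays(geom, theta, z_src + off, gamma_grid)
            p = analytic_line_integrals(phantom, origins, directions).reshape(B, G)
            if rng is not None:
                counts = rng.poisson(i0 * np.exp(-p))
                counts = np.maximum(counts, 1)
                p = np.log(i0 / counts)
            vals[:, :, qi] = p
        out.append(
            SourceSinogram(
                values=vals,
                beta_grid=beta_grid.copy(),
                gamma_grid=gamma_grid.copy(),
                source_index=i,
                geometry=geom,
            )
        )
    return out


def simulate_planar_fan(
    phantom: AnalyticPhantom,
    geom: HelixGeometry,
    z_plane: float,
    n_beta: int,
    beta_R: Optional[float] = None,
) -> PlanarFan:
    """The *true* single-plane fan sinogram at ``z_plane`` — a virtual
    source circling in that plane.  Serves as the oracle the helical
    interpolation is judged against (its zero-pitch limit)."""
    from .geometry import TWO_PI

    if beta_R is None:
        beta_R = geom.beta_of_plane(z_plane, 1)
    beta = beta_R + TWO_PI * np.arange(n_beta) / n_beta
    gamma_grid = geom.detector.gamma_grid
    z = np.full(beta.shape, float(z_plane))
    origins, directions = _fan_rays(geom, beta, z, gamma_grid)
    vals = analytic_line_integrals(phantom, origins, directions).reshape(n_beta, gamma_grid.size)
    return PlanarFan(
        values=vals,
        z_plane=float(z_plane),
        beta_R=float(beta_R),
        beta_grid=beta,
        gamma_grid=gamma_grid,
        rho=float(geom.rho),
        mode="true",
        provenance=None,
    )


def project_voxels(volume: VoxelVolume, origins: np.ndarray, directions: np.ndarray,
                   step: float = 0.25) -> np.ndarray:
    """Line integrals through a voxelized volume by dense sampling along the
    ray (trapezoid in steps of ``step`` mm).  Secondary path — the analytic
    projector is the reference; this exists for voxel-domain checks."""
    from scipy.ndimage import map_coordinates

    o = np.atleast_2d(origins)
    d = np.atleast_2d(directions)
    ext = np.linalg.norm(np.asarray(volume.shape) * np.asarray(volume.spacing))
    n_steps = int(np.ceil(2 * ext / step)) + 1
    t = np.linspace(-ext, ext, n_steps)
    out = np.empty(o.shape[0])
    sp = np.asarray(volume.spacing)
    og = np.asarray(volume.origin)
    for r in range(o.shape[0]):
        pts = o[r][None, :] + t[:, None] * d[r][None, :]
        idx = ((pts - og) / sp).T
        samples = map_coordinates(volume.values, idx, order=1, mode="constant", cval=0.0)
        out[r] = np.trapezoid(samples, t)
    return out
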