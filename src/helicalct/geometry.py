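"""Multi-source helical scan geometry.

The scanner model: N X-ray sources ride on a ring of radius ``rho`` around
the bed axis (z), rotating with angular velocity ``omega`` while the bed
translates along z.  Source *i* starts at initial phase ``phases[i-1]``; its
lab-frame angular position after rotating through a (shared) angle
``beta = omega * t`` is ``beta + phases[i-1]``.  The bed position is

* fixed pitch:    ``z(beta) = h * beta / (2*pi)`` with ``h`` the bed advance
  per rotation (mm/rev);
* variable pitch: ``z(beta) = (1/2*pi) * Int_0^beta h(b) db`` with a
  tabulated speed profile ``h(b)`` (mm/rev as a function of rotation angle),
  integrated by cumulative trapezoid (exact for piecewise-linear profiles).

Each source carries a fan-beam detector with Q rows offset along z.  The
cone angle is ignored: every row is treated as an independent in-plane fan
at ``z_source + row_offset`` — this is precisely the approximation the
cross-helix z-interpolation method relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .errors import CoverageError, ValidationError

TWO_PI = 2.0 * np.pi

__all__ = ["FanDetector", "TableSpeed", "HelixGeometry", "uniform_phases", "TWO_PI"]


def uniform_phases(n_sources: int) -> tuple[float, ...]:
    """Default initial phases 2*pi*(i-1)/N, i = 1..N (uniform interleave)."""
    if n_sources < 1:
        raise ValidationError("n_sources must be >= 1")
    return tuple(TWO_PI * i / n_sources for i in range(n_sources))


@dataclass(frozen=True)
class FanDetector:
    """Equiangular fan-beam detector with Q rows offset along z.

    Parameters
    ----------
    gamma_grid : strictly increasing fan angles (rad), symmetric about 0.
    n_rows : number of detector rows Q.
    row_pitch : z spacing of the rows measured at isocenter (mm).
    source_detector_distance : source-to-detector distance (mm); metadata
        only — rays are parameterized by the fan angle.
    """

    gamma_grid: np.ndarray
    n_rows: int = 1
    row_pitch: float = 1.0
    source_detector_distance: float = 1000.0

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma_grid, dtype=float)
        object.__setattr__(self, "gamma_grid", g)
        if g.ndim != 1 or g.size < 1:
            raise ValidationError("gamma_grid must be a 1-D array")
        if g.size > 1 and not np.all(np.diff(g) > 0):
            raise ValidationError("gamma_grid must be strictly increasing")
        if not np.allclose(g + g[::-1], 0.0, atol=1e-12):
            raise ValidationError("gamma_grid must be symmetric about 0")
        if self.n_rows < 1:
            raise ValidationError("n_rows must be >= 1")
        if self.row_pitch <= 0:
            raise ValidationError("row_pitch must be positive")

    @classmethod
    def equiangular(
        cls,
        n_gamma: int,
        fan_half_angle: float,
        n_rows: int = 1,
        row_pitch: float = 1.0,
        **kwargs,
    ) -> "FanDetector":
        """Symmetric equiangular grid of ``n_gamma`` samples spanning
        [-fan_half_angle, +fan_half_angle]."""
        if n_gamma < 1:
            raise ValidationError("n_gamma must be >= 1")
        if n_gamma == 1:
            grid = np.zeros(1)
        else:
            grid = np.linspace(-fan_half_angle, fan_half_angle, n_gamma)
            grid = grid - (grid[0] + grid[-1]) / 2.0  # enforce exact symmetry
        return cls(gamma_grid=grid, n_rows=n_rows, row_pitch=row_pitch, **kwargs)

    @property
    def row_offsets(self) -> np.ndarray:
        """z offsets of rows q = 1..Q relative to the source plane,
        (q - (Q+1)/2) * row_pitch — rows centered on the source."""
        q = np.arange(1, self.n_rows + 1, dtype=float)
        return (q - (self.n_rows + 1) / 2.0) * self.row_pitch

    @property
    def dgamma(self) -> float:
        if self.gamma_grid.size < 2:
            return 0.0
        return float(self.gamma_grid[1] - self.gamma_grid[0])


@dataclass(frozen=True)
class TableSpeed:
    """Variable-pitch bed-speed profile h(beta), sampled on a rotation-angle
    grid, with exact piecewise-quadratic cumulative bed position.

    ``h`` is in mm per rotation; z(beta) = Int_0^beta h(b) db / (2*pi).
    """

    beta_grid: np.ndarray  # rad, increasing, starting at 0
    h_values: np.ndarray   # mm/rev, >= 0

    def __post_init__(self) -> None:
        b = np.asarray(self.beta_grid, dtype=float)
        h = np.asarray(self.h_values, dtype=float)
        object.__setattr__(self, "beta_grid", b)
        object.__setattr__(self, "h_values", h)
        if b.ndim != 1 or b.size < 2 or h.shape != b.shape:
            raise ValidationError("beta_grid and h_values must be matching 1-D arrays (>= 2 samples)")
        if not np.all(np.diff(b) > 0):
            raise ValidationError("beta_grid must be strictly increasing")
        if abs(b[0]) > 1e-12:
            raise ValidationError("beta_grid must start at 0")
        if np.any(h < 0):
            raise ValidationError("table speed must be non-negative")
        seg = 0.5 * (h[1:] + h[:-1]) * np.diff(b) / TWO_PI
        z_cum = np.concatenate([[0.0], np.cumsum(seg)])
        object.__setattr__(self, "_z_cum", z_cum)

    @property
    def z_cum(self) -> np.ndarray:
        return self._z_cum

    def z_of(self, beta) -> np.ndarray:
        """Bed position at rotation angle(s) beta (exact piecewise quadratic)."""
        beta = np.asarray(beta, dtype=float)
        b, h, zc = self.beta_grid, self.h_values, self._z_cum
        if np.any(beta < b[0] - 1e-9) or np.any(beta > b[-1] + 1e-9):
            raise CoverageError("beta outside the tabulated table-speed range")
        idx = np.clip(np.searchsorted(b, beta, side="right") - 1, 0, b.size - 2)
        db = beta - b[idx]
        slope = (h[idx + 1] - h[idx]) / (b[idx + 1] - b[idx])
        return zc[idx] + (h[idx] * db + 0.5 * slope * db * db) / TWO_PI

    def beta_of_z(self, z: float) -> float:
        """Smallest beta with z(beta) == z, by per-segment quadratic inversion.

        Ties on zero-speed (flat) segments resolve to the segment start.
        """
        zc = self._z_cum
        if z < zc[0] - 1e-9 or z > zc[-1] + 1e-9:
            raise CoverageError(f"plane z={z} outside swept range [{zc[0]}, {zc[-1]}]")
        z = float(np.clip(z, zc[0], zc[-1]))
        # first segment whose right endpoint reaches z -> smallest beta
        j = int(np.searchsorted(zc, z, side="left"))
        if j == 0:
            return float(self.beta_grid[0])
        j -= 1  # segment [j, j+1]
        b, h = self.beta_grid, self.h_values
        dz = z - zc[j]
        if dz <= 0:
            return float(b[j])
        h0 = h[j]
        slope = (h[j + 1] - h[j]) / (b[j + 1] - b[j])
        big_d = TWO_PI * dz
        disc = h0 * h0 + 2.0 * slope * big_d
        disc = max(disc, 0.0)
        denom = h0 + np.sqrt(disc)
        if denom <= 0:
            return float(b[j])
        return float(b[j] + 2.0 * big_d / denom)


Pitch = Union[float, TableSpeed]


@dataclass(frozen=True)
class HelixGeometry:
    """N-source helical trajectory plus fan detector layout."""

    rho: float
    omega: float
    phases: tuple[float, ...]
    pitch: Pitch
    detector: FanDetector = field(default_factory=lambda: FanDetector.equiangular(64, 0.4))

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValidationError("rho must be positive")
        if self.omega <= 0:
            raise ValidationError("omega must be positive")
        if len(self.phases) < 1:
            raise ValidationError("at least one source phase required")
        object.__setattr__(self, "phases", tuple(float(p) for p in self.phases))
        if not self.is_variable and float(self.pitch) <= 0:
            raise ValidationError("constant pitch must be positive")

    @property
    def n_sources(self) -> int:
        return len(self.phases)

    @property
    def is_variable(self) -> bool:
        return isinstance(self.pitch, TableSpeed)

    def _check_source(self, i: int) -> None:
        if not 1 <= i <= self.n_sources:
            raise IndexError(f"source index {i} out of range 1..{self.n_sources}")

    def angular_position(self, i: int, beta) -> np.ndarray:
        """Lab-frame angular position of source i at rotation angle beta."""
        self._check_source(i)
        return np.asarray(beta, dtype=float) + self.phases[i - 1]

    def z_at(self, beta) -> np.ndarray:
        """Bed (source-plane) z position at rotation angle beta.

        Shared by all sources — the bed carries the whole gantry.
        """
        beta = np.asarray(beta, dtype=float)
        if np.any(beta < -1e-9):
            raise CoverageError("beta must be non-negative (scan starts at t=0)")
        if self.is_variable:
            return self.pitch.z_of(beta)
        return float(self.pitch) * beta / TWO_PI

    def source_position(self, i: int, t) -> np.ndarray:
        """World position of source i at time t (seconds): shape (..., 3)."""
        self._check_source(i)
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValidationError("t must be >= 0")
        beta = self.omega * t
        theta = beta + self.phases[i - 1]
        z = self.z_at(beta)
        return np.stack(
            [self.rho * np.cos(theta), self.rho * np.sin(theta), np.broadcast_to(z, theta.shape)],
            axis=-1,
        )

    def beta_of_plane(self, z_plane: float, i: int = 1) -> float:
        """Rotation angle at which source i's own plane crosses z_plane.

        Fixed pitch: exactly 2*pi*z/h. Variable pitch: monotone inversion of
        the cumulative bed position to |z - z_plane| < 1e-6 mm (the
        piecewise-quadratic solve is analytic); flat-speed ties resolve to
        the smallest beta.
        """
        self._check_source(i)
        if self.is_variable:
            return self.pitch.beta_of_z(z_plane)
        beta = TWO_PI * float(z_plane) / float(self.pitch)
        if beta < -1e-9:
            raise CoverageError(f"plane z={z_plane} is before the scan start")
        return max(beta, 0.0)

    def row_z(self, i: int, beta, q: int) -> np.ndarray:
        """z position of detector row q of source i at rotation angle beta."""
        self._check_source(i)
        if not 1 <= q <= self.detector.n_rows:
            raise IndexError(f"row index {q} out of range 1..{self.detector.n_rows}")
        return self.z_at(beta) + self.detector.row_offsets[q - 1]
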