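"""Analytic knee-like phantoms with exact line integrals.

The test object stands in for a knee: large smooth "bone" ellipsoids
embedded in a soft-tissue ellipsoid, optionally cut by a sub-voxel-thin
low-attenuation slab — the "occult fracture".  The crack is a plane of
finite thickness clipped to the union of the bone ellipsoids, so every shape
has an exact ray chord length and the phantom doubles as the oracle for the
fan-beam projector.

World frame: z is the bed/rotation axis, x-y the gantry plane,
right-handed.  All lengths in mm; attenuation in 1/mm.  Voxel ``origin`` is
the world coordinate of the CENTER of voxel index (0, 0, 0); array axis
order is (x, y, z).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .errors import ValidationError

__all__ = [
    "Ellipsoid",
    "Crack",
    "AnalyticPhantom",
    "VoxelVolume",
    "BinaryMask",
    "make_knee_phantom",
    "rasterize",
    "ground_truth_masks",
    "analytic_line_integral",
    "analytic_line_integrals",
    "DEFAULT_KNEE_SPEC",
]


@dataclass(frozen=True)
class Ellipsoid:
    """A rotated ellipsoid contributing ``attenuation_delta`` inside itself.

    ``rotation`` is intrinsic x-y-z Euler angles (radians). ``label`` tags
    the anatomical role ('bone' or 'soft') used to derive ground-truth masks.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    attenuation_delta: float = 0.02
    label: str = "bone"

    def __post_init__(self) -> None:
        if len(self.center) != 3 or len(self.semi_axes) != 3 or len(self.rotation) != 3:
            raise ValidationError("center, semi_axes, rotation must be length-3")
        if any(a <= 0 for a in self.semi_axes):
            raise ValidationError("semi_axes must be strictly positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "semi_axes", tuple(float(a) for a in self.semi_axes))
        object.__setattr__(self, "rotation", tuple(float(r) for r in self.rotation))

    @property
    def rotation_matrix(self) -> np.ndarray:
        R = Rotation.from_euler("xyz", self.rotation).as_matrix()
        # orthonormality is guaranteed by construction; assert the invariant
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-10)
        return R

    def _to_unit_sphere(self) -> np.ndarray:
        """Affine map M such that |M (x - center)| <= 1 iff x is inside."""
        return np.diag(1.0 / np.asarray(self.semi_axes)) @ self.rotation_matrix.T

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        q = (pts - np.asarray(self.center)) @ self._to_unit_sphere().T
        return np.einsum("ij,ij->i", q, q) <= 1.0

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "semi_axes": list(self.semi_axes),
            "rotation": list(self.rotation),
            "attenuation_delta": float(self.attenuation_delta),
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Ellipsoid":
        return cls(
            center=tuple(d["center"]),
            semi_axes=tuple(d["semi_axes"]),
            rotation=tuple(d.get("rotation", (0.0, 0.0, 0.0))),
            attenuation_delta=float(d.get("attenuation_delta", 0.02)),
            label=d.get("label", "bone"),
        )


@dataclass(frozen=True)
class Crack:
    """Thin slab |n . (x - point)| <= thickness/2, clipped to the bone union.

    ``attenuation_delta`` must be <= 0: a fracture is a density deficit.
    """

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    thickness: float = 0.3
    attenuation_delta: float = -0.02

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            raise ValidationError("crack normal must be non-zero")
        object.__setattr__(self, "normal", tuple(float(x) for x in n / nn))
        object.__setattr__(self, "point", tuple(float(p) for p in self.point))
        if self.thickness <= 0:
            raise ValidationError("crack thickness must be positive")
        if self.attenuation_delta > 0:
            raise ValidationError("crack attenuation_delta must be <= 0 (density deficit)")

    def to_dict(self) -> dict:
        return {
            "point": list(self.point),
            "normal": list(self.normal),
            "thickness": float(self.thickness),
            "attenuation_delta": float(self.attenuation_delta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Crack":
        return cls(
            point=tuple(d["point"]),
            normal=tuple(d["normal"]),
            thickness=float(d.get("thickness", 0.3)),
            attenuation_delta=float(d.get("attenuation_delta", -0.02)),
        )


@dataclass(frozen=True)
class AnalyticPhantom:
    ellipsoids: tuple[Ellipsoid, ...]
    crack: Optional[Crack] = None
    bounding_radius: float = 120.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ellipsoids", tuple(self.ellipsoids))
        if self.bounding_radius <= 0:
            raise ValidationError("bounding_radius must be positive")
        for e in self.ellipsoids:
            reach = np.linalg.norm(e.center) + max(e.semi_axes)
            if reach > self.bounding_radius + 1e-9:
                raise ValidationError(
                    f"ellipsoid at {e.center} extends beyond bounding_radius {self.bounding_radius}"
                )

    @property
    def bone_ellipsoids(self) -> tuple[Ellipsoid, ...]:
        return tuple(e for e in self.ellipsoids if e.label == "bone")

    def attenuation_at(self, points: np.ndarray) -> np.ndarray:
        """Total attenuation at world points, shape (M, 3) -> (M,)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        mu = np.zeros(pts.shape[0])
        for e in self.ellipsoids:
            mu += e.attenuation_delta * e.contains(pts)
        if self.crack is not None:
            mu += self.crack.attenuation_delta * self.crack_contains(pts)
        return mu

    def crack_contains(self, points: np.ndarray) -> np.ndarray:
        """Inside the crack slab AND inside some bone ellipsoid."""
        if self.crack is None:
            return np.zeros(np.atleast_2d(points).shape[0], dtype=bool)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = np.asarray(self.crack.normal)
        d = np.abs((pts - np.asarray(self.crack.point)) @ n)
        in_slab = d <= self.crack.thickness / 2.0
        in_bone = np.zeros(pts.shape[0], dtype=bool)
        for e in self.bone_ellipsoids:
            in_bone |= e.contains(pts)
        return in_slab & in_bone

    def check_nonnegative(self, n_samples: int = 20000, seed: int = 0) -> None:
        """Verify total attenuation >= 0 on a dense random sample."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-self.bounding_radius, self.bounding_radius, size=(n_samples, 3))
        if np.any(self.attenuation_at(pts) < -1e-12):
            raise ValidationError("phantom total attenuation is negative somewhere")

    def to_dict(self) -> dict:
        d = {
            "ellipsoids": [e.to_dict() for e in self.ellipsoids],
            "bounding_radius": float(self.bounding_radius),
        }
        if self.crack is not None:
            d["crack"] = self.crack.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalyticPhantom":
        return cls(
            ellipsoids=tuple(Ellipsoid.from_dict(e) for e in d["ellipsoids"]),
            crack=Crack.from_dict(d["crack"]) if d.get("crack") else None,
            bounding_radius=float(d.get("bounding_radius", 120.0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalyticPhantom":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class VoxelVolume:
    """3-D scalar grid; ``origin`` is the world center of voxel (0,0,0)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("volume values must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.values.shape[a])
            for a in range(3)
        )


@dataclass
class BinaryMask:
    values: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


# --- phantom construction -------------------------------------------------

#: Default knee-like phantom: soft-tissue envelope, femoral and tibial
#: condyle ellipsoids, patella, and a thin tilted crack through the tibial
#: plateau.  Attenuations loosely follow soft tissue ~0.02/mm and cortical
#: bone ~0.05/mm at diagnostic energies; the crack deficit returns the bone
#: locally to soft-tissue density.
DEFAULT_KNEE_SPEC: dict = {
    "bounding_radius": 110.0,
    "ellipsoids": [
        {"center": [0.0, 0.0, 0.0], "semi_axes": [60.0, 55.0, 95.0],
         "rotation": [0.0, 0.0, 0.0], "attenuation_delta": 0.02, "label": "soft"},
        {"center": [0.0, 8.0, 38.0], "semi_axes": [28.0, 24.0, 34.0],
         "rotation": [0.05, 0.0, 0.0], "attenuation_delta": 0.03, "label": "bone"},
        {"center": [0.0, -4.0, -38.0], "semi_axes": [26.0, 22.0, 34.0],
         "rotation": [-0.04, 0.0, 0.0], "attenuation_delta": 0.03, "label": "bone"},
        {"center": [0.0, 42.0, 30.0], "semi_axes": [10.0, 6.0, 14.0],
         "rotation": [0.0, 0.0, 0.0], "attenuation_delta": 0.03, "label": "bone"},
    ],
    "crack": {"point": [0.0, -4.0, -12.0], "normal": [0.12, 0.05, 1.0],
              "thickness": 0.3, "attenuation_delta": -0.03},
    "jitter": 0.0,
}


def make_knee_phantom(spec: Optional[dict] = None, seed: int = 0) -> AnalyticPhantom:
    """Build the knee-like phantom from a spec dict (DEFAULT_KNEE_SPEC keys).

    Deterministic for fixed (spec, seed).  If ``spec['jitter'] > 0``,
    ellipsoid centers are perturbed by N(0, jitter^2) draws taken from a
    single generator seeded with ``seed``, in listed ellipsoid order,
    three draws (x, y, z) per ellipsoid.
    """
    merged = dict(DEFAULT_KNEE_SPEC)
    if spec:
        merged.update(spec)
    jitter = float(merged.get("jitter", 0.0))
    rng = np.random.default_rng(seed)
    ellipsoids = []
    for ed in merged["ellipsoids"]:
        e = Ellipsoid.from_dict(ed)
        if jitter > 0:
            delta = rng.normal(0.0, jitter, size=3)
            e = replace(e, center=tuple(np.asarray(e.center) + delta))
        ellipsoids.append(e)
    crack = Crack.from_dict(merged["crack"]) if merged.get("crack") else None
    return AnalyticPhantom(
        ellipsoids=tuple(ellipsoids),
        crack=crack,
        bounding_radius=float(merged.get("bounding_radius", 120.0)),
    )


# --- rasterization --------------------------------------------------------

def _grid_points(shape, spacing, origin, iz: np.ndarray) -> np.ndarray:
    nx, ny = shape[0], shape[1]
    xs = origin[0] + spacing[0] * np.arange(nx)
    ys = origin[1] + spacing[1] * np.arange(ny)
    zs = origin[2] + spacing[2] * iz
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


def rasterize(
    phantom: AnalyticPhantom,
    shape: Sequence[int],
    spacing: Sequence[float],
    origin: Optional[Sequence[float]] = None,
    supersample: int = 1,
) -> VoxelVolume:
    """Voxelize: each voxel takes the summed delta of the shapes containing
    its center (or the mean over ``supersample``^3 sub-points)."""
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in shape) or any(s <= 0 for s in spacing):
        raise ValidationError("shape and spacing must be positive")
    if origin is None:
        origin = tuple(-(n - 1) / 2.0 * d for n, d in zip(shape, spacing))
    origin = tuple(float(o) for o in origin)
    s = int(supersample)
    if s < 1:
        raise ValidationError("supersample must be >= 1")

    out = np.zeros(shape)
    # chunk over z to bound memory
    z_chunk = max(1, int(2e6 // (shape[0] * shape[1] * s * s * max(s, 1))))
    if s == 1:
        offsets = [np.zeros(3)]
    else:
        sub = (np.arange(s) + 0.5) / s - 0.5
        offsets = [np.array([a, b, c]) for a in sub for b in sub for c in sub]
        offsets = [o * np.asarray(spacing) for o in offsets]
    for z0 in range(0, shape[2], z_chunk):
        iz = np.arange(z0, min(z0 + z_chunk, shape[2]))
        pts = _grid_points(shape, spacing, origin, iz)
        acc = np.zeros(pts.shape[0])
        for off in offsets:
            acc += phantom.attenuation_at(pts + off)
        acc /= len(offsets)
        out[:, :, iz] = acc.reshape(shape[0], shape[1], iz.size)
    return VoxelVolume(values=out, spacing=spacing, origin=origin)


def ground_truth_masks(
    phantom: AnalyticPhantom,
    shape: Sequence[int],
    spacing: Sequence[float],
    origin: Optional[Sequence[float]] = None,
) -> dict[str, BinaryMask]:
    """Ground-truth 'bone' (union of bone ellipsoids) and 'fracture'
    (crack slab clipped to bone) masks on the given grid."""
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    if origin is None:
        origin = tuple(-(n - 1) / 2.0 * d for n, d in zip(shape, spacing))
    origin = tuple(float(o) for o in origin)
    bone = np.zeros(shape, dtype=bool)
    frac = np.zeros(shape, dtype=bool)
    z_chunk = max(1, int(4e6 // (shape[0] * shape[1])))
    for z0 in range(0, shape[2], z_chunk):
        iz = np.arange(z0, min(z0 + z_chunk, shape[2]))
        pts = _grid_points(shape, spacing, origin, iz)
        b = np.zeros(pts.shape[0], dtype=bool)
        for e in phantom.bone_ellipsoids:
            b |= e.contains(pts)
        bone[:, :, iz] = b.reshape(shape[0], shape[1], iz.size)
        frac[:, :, iz] = phantom.crack_contains(pts).reshape(shape[0], shape[1], iz.size)
    return {
        "bone": BinaryMask(bone, spacing, origin),
        "fracture": BinaryMask(frac, spacing, origin),
    }


# --- exact line integrals -------------------------------------------------

def _ellipsoid_intervals(e: Ellipsoid, origins: np.ndarray, dirs: np.ndarray):
    """Ray-parameter entry/exit (t0, t1) per ray; t1 < t0 where missed."""
    M = e._to_unit_sphere()
    o = (origins - np.asarray(e.center)) @ M.T
    d = dirs @ M.T
    a = np.einsum("ij,ij->i", d, d)
    b = np.einsum("ij,ij->i", o, d)
    c = np.einsum("ij,ij->i", o, o) - 1.0
    disc = b * b - a * c
    hit = disc > 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t0 = np.where(hit, (-b - sq) / a, np.inf)
    t1 = np.where(hit, (-b + sq) / a, -np.inf)
    return t0, t1


def _slab_intervals(crack: Crack, origins: np.ndarray, dirs: np.ndarray):
    n = np.asarray(crack.normal)
    half = crack.thickness / 2.0
    num = (origins - np.asarray(crack.point)) @ n
    den = dirs @ n
    parallel = np.abs(den) < 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (-half - num) / den
        tb = (half - num) / den
    t0 = np.minimum(ta, tb)
    t1 = np.maximum(ta, tb)
    inside = np.abs(num) <= half
    t0 = np.where(parallel, np.where(inside, -np.inf, np.inf), t0)
    t1 = np.where(parallel, np.where(inside, np.inf, -np.inf), t1)
    return t0, t1


def analytic_line_integrals(
    phantom: AnalyticPhantom, origins: np.ndarray, directions: np.ndarray
) -> np.ndarray:
    """Exact line integrals of the phantom along rays (origins, unit dirs).

    Vectorized over rays: shape (M, 3) inputs -> (M,) attenuation*mm.  The
    crack contribution uses inclusion–exclusion over the bone-ellipsoid
    intervals so overlapping bones are not double-counted.
    """
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    if o.shape != d.shape or o.shape[1] != 3:
        raise ValidationError("origins and directions must be (M, 3) and matching")
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise ValidationError("zero-length ray direction")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValidationError("ray directions must be unit vectors")

    total = np.zeros(o.shape[0])
    bone_ivals = []
    for e in phantom.ellipsoids:
        t0, t1 = _ellipsoid_intervals(e, o, d)
        total += e.attenuation_delta * np.maximum(t1 - t0, 0.0)
        if e.label == "bone":
            bone_ivals.append((t0, t1))

    if phantom.crack is not None and bone_ivals:
        s0, s1 = _slab_intervals(phantom.crack, o, d)
        # |slab ∩ (union of bones)| by inclusion–exclusion; each per-shape
        # interval is connected so every subset intersection is an interval.
        length = np.zeros(o.shape[0])
        m = len(bone_ivals)
        for r in range(1, m + 1):
            for subset in itertools.combinations(range(m), r):
                lo, hi = s0.copy(), s1.copy()
                for j in subset:
                    lo = np.maximum(lo, bone_ivals[j][0])
                    hi = np.minimum(hi, bone_ivals[j][1])
                length += ((-1.0) ** (r + 1)) * np.maximum(hi - lo, 0.0)
        total += phantom.crack.attenuation_delta * length
    return total


def analytic_line_integral(phantom: AnalyticPhantom, origin, direction) -> float:
    """Scalar convenience wrapper around :func:`analytic_line_integrals`."""
    return float(analytic_line_integrals(phantom, np.asarray(origin)[None], np.asarray(direction)[None])[0])
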