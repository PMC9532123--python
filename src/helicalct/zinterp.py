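"""Cross-helix z-axis interpolation of multi-source fan-beam projections.

This is the heart of the package.  A helical scan never measures a complete
fan sinogram in any single z plane; to reconstruct the slice at ``Z_R`` the
missing rays are estimated, per fan coordinate (beta, gamma), by linearly
interpolating the two acquired rays that are (approximately) parallel to the
query ray and closest to the plane in z — one at-or-above, one at-or-below.
With N interleaved sources the candidate rays come from every source's
helix, every detector row, and both the *direct* (gamma' = gamma) and
*complementary* (opposed, gamma' = -gamma) branches:

    direct:        beta' = beta + 2*k*pi          - phi_i,   gamma' =  gamma
    complementary: beta' = beta + 2*gamma + (2k-1)*pi - phi_i, gamma' = -gamma

for integer k and source phases phi_i (the single-source N=1, phi=0 case
reduces to the classical half-turn multi-slice linear interpolation, 180MLI).

Two selection pipelines are provided:

* fixed pitch — global nearest neighbor at-or-above (A) and at-or-below (B)
  over all (source, k, branch, row) candidates, then linear interpolation
  with the node-exact weight w_A = (Z_R - z_B) / (z_A - z_B);
* variable pitch — the four (branch x side) candidate families are searched
  separately, the per-side winner is the closer of its two family winners
  with the direct family preferred on ties, and interpolation uses
  w = (z_above - Z_R) / (z_above - z_below) applied to the below neighbor.
  Note the naming flips: in this formulation A is the below-plane neighbor.

Candidates are snapped to the nearest stored beta sample (both the z
position and the value come from that stored ray) when within ``snap_frac``
bins — the default 0.5 accepts every in-range candidate, so the selection is
a search over stored rays and can be checked against an exhaustive
brute-force scan.  Setting ``snap_frac < 0.5`` switches out-of-tolerance
candidates to linear interpolation along beta at the exact partner angle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import CoverageError, ValidationError
from .geometry import TWO_PI, HelixGeometry

__all__ = [
    "NeighborCandidate",
    "PlanarFan",
    "parallel_partners",
    "select_neighbors_fixed",
    "interpolate_fixed",
    "candidate_sets_variable",
    "select_neighbors_variable",
    "interpolate_variable",
    "build_planar_fan",
]

_Z_TOL = 1e-9  # mm; side-membership tolerance for z comparisons


@dataclass(frozen=True)
class NeighborCandidate:
    """One acquired ray considered for interpolation at a plane."""

    source: int
    beta_p: float
    gamma_p: float
    q: int
    z: float
    value: float
    branch: str  # 'direct' | 'complementary'
    side: str    # 'above' | 'below'


@dataclass
class PlanarFan:
    """Complete single-plane fan sinogram over beta in [beta_R, beta_R+2pi).

    ``provenance`` (when present) maps 'above'/'below' to dicts of per-bin
    arrays (z, value, source, beta, gamma, q, branch) plus 'weight_above',
    the interpolation weight given to the at-or-above neighbor.
    """

    values: np.ndarray        # (n_beta, n_gamma)
    z_plane: float
    beta_R: float
    beta_grid: np.ndarray     # absolute angles, uniform, [beta_R, beta_R+2pi)
    gamma_grid: np.ndarray
    rho: float
    mode: str = "fixed"
    provenance: Optional[dict] = None

    @property
    def dbeta(self) -> float:
        return float(self.beta_grid[1] - self.beta_grid[0])


def parallel_partners(
    beta: float,
    gamma: float,
    geom: HelixGeometry,
    k_range: int = 2,
    beta_range: Optional[tuple[float, float]] = None,
):
    """Enumerate the (source, beta', gamma', branch) rays parallel to the
    query ray (beta, gamma), for every source and |k| <= k_range.

    If ``beta_range`` is given, partners outside it are dropped (partners
    must lie within the acquired angles to be usable).
    """
    out = []
    for i in range(1, geom.n_sources + 1):
        phi = geom.phases[i - 1]
        for k in range(-k_range, k_range + 1):
            bd = beta + TWO_PI * k - phi
            bc = beta + 2.0 * gamma + (2 * k - 1) * np.pi - phi
            for bp, gp, branch in ((bd, gamma, "direct"), (bc, -gamma, "complementary")):
                if beta_range is not None and not (beta_range[0] - 1e-12 <= bp <= beta_range[1] + 1e-12):
                    continue
                out.append((i, float(bp), float(gp), branch))
    return out


# --- vectorized candidate gathering ---------------------------------------

def _mirror_index(n_gamma: int) -> np.ndarray:
    # gamma grids are symmetric by construction: -gamma_grid[j] == gamma_grid[n-1-j]
    return np.arange(n_gamma)[::-1].copy()


def _gather_candidates(
    z_plane: float,
    beta: np.ndarray,       # (B,) query angles
    gamma_grid: np.ndarray,  # (G,)
    sinograms: Sequence,
    geom: HelixGeometry,
    k_range: int,
    snap_frac: float,
):
    """Enumerate every (source, k, branch, row) candidate on the (B, G) query
    grid.  Returns per-candidate stacked arrays plus metadata rows."""
    if not sinograms:
        raise ValidationError("no sinograms supplied")
    B, G = beta.size, gamma_grid.size
    mirror = _mirror_index(G)
    ks = range(-k_range, k_range + 1)
    z_list, val_list, bp_list, gp_list, ok_list, meta = [], [], [], [], [], []

    by_source = {s.source_index: s for s in sinograms}
    for i in range(1, geom.n_sources + 1):
        sino = by_source.get(i)
        if sino is None:
            continue
        vals = sino.values
        bg = sino.beta_grid
        db = float(bg[1] - bg[0]) if bg.size > 1 else 1.0
        nb = bg.size
        phi = geom.phases[i - 1]
        for k in ks:
            for branch in ("direct", "complementary"):
                if branch == "direct":
                    bp = beta + TWO_PI * k - phi                      # (B,)
                    bp = np.broadcast_to(bp[:, None], (B, G)).copy()
                    jcol = np.broadcast_to(np.arange(G)[None, :], (B, G))
                    gp = np.broadcast_to(gamma_grid[None, :], (B, G))
                else:
                    bp = beta[:, None] + 2.0 * gamma_grid[None, :] + (2 * k - 1) * np.pi - phi
                    jcol = np.broadcast_to(mirror[None, :], (B, G))
                    gp = np.broadcast_to(-gamma_grid[None, :], (B, G))

                u = (bp - bg[0]) / db
                m = np.floor(u + 0.5)
                near = np.abs(u - m) <= snap_frac + 1e-9
                snap_ok = near & (m >= 0) & (m <= nb - 1)
                lin_ok = (~near) & (u >= 0) & (u <= nb - 1) & (snap_frac < 0.5)

                z = np.full((B, G), np.nan)
                v = np.full((B, G), np.nan)
                bp_used = np.full((B, G), np.nan)

                if np.any(snap_ok):
                    mi = m[snap_ok].astype(int)
                    jj = jcol[snap_ok]
                    bsnap = bg[mi]
                    z[snap_ok] = geom.z_at(bsnap)
                    v[snap_ok] = vals[mi, jj, 0]  # row offset added per q below
                    bp_used[snap_ok] = bsnap
                if np.any(lin_ok):
                    u0 = np.floor(u[lin_ok]).astype(int)
                    u1 = np.minimum(u0 + 1, nb - 1)
                    f = u[lin_ok] - u0
                    jj = jcol[lin_ok]
                    z[lin_ok] = geom.z_at(bp[lin_ok])
                    v[lin_ok] = (1 - f) * vals[u0, jj, 0] + f * vals[u1, jj, 0]
                    bp_used[lin_ok] = bp[lin_ok]
                ok = snap_ok | lin_ok

                # expand over detector rows: value per row, z shifted per row
                for qi, off in enumerate(geom.detector.row_offsets):
                    vq = np.full((B, G), np.nan)
                    if np.any(snap_ok):
                        mi = m[snap_ok].astype(int)
                        jj = jcol[snap_ok]
                        vq[snap_ok] = vals[mi, jj, qi]
                    if np.any(lin_ok):
                        u0 = np.floor(u[lin_ok]).astype(int)
                        u1 = np.minimum(u0 + 1, nb - 1)
                        f = u[lin_ok] - u0
                        jj = jcol[lin_ok]
                        vq[lin_ok] = (1 - f) * vals[u0, jj, qi] + f * vals[u1, jj, qi]
                    z_list.append(z + off)
                    val_list.append(vq)
                    bp_list.append(bp_used)
                    gp_list.append(gp)
                    ok_list.append(ok)
                    meta.append((i, k, branch, qi + 1))

    return {
        "z": np.stack(z_list),          # (C, B, G)
        "value": np.stack(val_list),
        "beta_p": np.stack(bp_list),
        "gamma_p": np.stack(gp_list),
        "ok": np.stack(ok_list),
        "meta": meta,                    # list of (source, k, branch, q)
    }


def _lex_argmin(primary: np.ndarray, tie_keys: Sequence[np.ndarray]):
    """Argmin along axis 0 with lexicographic tie-breaking (exact equality).

    Returns (index array, min primary).  Entries that are inf everywhere get
    primary == inf in the output.
    """
    best = np.min(primary, axis=0)
    tie = primary == best[None]
    for key in tie_keys:
        masked = np.where(tie, key, np.inf)
        kbest = np.min(masked, axis=0)
        tie = tie & (masked == kbest[None])
    idx = np.argmax(tie, axis=0)
    return idx, best


def _side_winner(cand: dict, z_plane: float, beta: np.ndarray, side: str, subset: Optional[np.ndarray] = None):
    """Nearest candidate on one side of the plane.

    Exact-distance ties break lexicographically by (direct before
    complementary, smaller source index, smaller |beta' - beta|).  The
    direct branch goes first so that the global selection agrees with the
    variable-pitch family-merge rule, which prefers the direct family on
    ties; with snapped lookups an even-N geometry produces such ties at
    every bin (source i's complementary partner and source i+N/2's direct
    partner can snap to the same stored angle)."""
    z = cand["z"]
    ok = cand["ok"]
    if subset is not None:
        sel = np.zeros(z.shape[0], dtype=bool)
        sel[subset] = True
        ok = ok & sel[:, None, None]
    if side == "above":
        on_side = z >= z_plane - _Z_TOL
        dist = z - z_plane
    else:
        on_side = z <= z_plane + _Z_TOL
        dist = z_plane - z
    valid = ok & on_side
    dist = np.where(valid, np.maximum(dist, 0.0), np.inf)

    C = z.shape[0]
    src = np.array([m[0] for m in cand["meta"]], dtype=float)[:, None, None]
    br = np.array([0.0 if m[2] == "direct" else 1.0 for m in cand["meta"]])[:, None, None]
    dbq = np.abs(cand["beta_p"] - beta[None, :, None])
    dbq = np.where(valid, dbq, np.inf)
    src_b = np.broadcast_to(src, z.shape)
    br_b = np.broadcast_to(br, z.shape)
    src_b = np.where(valid, src_b, np.inf)
    br_b = np.where(valid, br_b, np.inf)
    idx, best = _lex_argmin(dist, [br_b, src_b, dbq])
    return idx, best


def _take(cand: dict, idx: np.ndarray):
    """Gather per-bin winner fields given candidate indices (B, G)."""
    B, G = idx.shape
    bb, gg = np.meshgrid(np.arange(B), np.arange(G), indexing="ij")
    out = {k: cand[k][idx, bb, gg] for k in ("z", "value", "beta_p", "gamma_p")}
    meta = cand["meta"]
    out["source"] = np.array([m[0] for m in meta])[idx]
    out["branch"] = np.array([0 if m[2] == "direct" else 1 for m in meta])[idx]
    out["q"] = np.array([m[3] for m in meta])[idx]
    return out


# --- scalar APIs ----------------------------------------------------------

def _scalar_candidates(z_plane, beta, gamma, sinograms, geom, k_range, snap_frac, gamma_grid=None):
    if gamma_grid is None:
        gamma_grid = geom.detector.gamma_grid
    j = int(np.argmin(np.abs(gamma_grid - gamma)))
    if abs(gamma_grid[j] - gamma) > 1e-9:
        raise ValidationError("gamma must be one of the detector fan angles")
    cand = _gather_candidates(
        z_plane, np.asarray([beta], dtype=float), gamma_grid, sinograms, geom, k_range, snap_frac
    )
    return cand, j


def _candidate_from(cand: dict, idx: int, j: int, side: str) -> NeighborCandidate:
    m = cand["meta"][idx]
    return NeighborCandidate(
        source=int(m[0]),
        beta_p=float(cand["beta_p"][idx, 0, j]),
        gamma_p=float(cand["gamma_p"][idx, 0, j]),
        q=int(m[3]),
        z=float(cand["z"][idx, 0, j]),
        value=float(cand["value"][idx, 0, j]),
        branch=m[2],
        side=side,
    )


def select_neighbors_fixed(
    z_plane: float,
    beta: float,
    gamma: float,
    sinograms: Sequence,
    geom: HelixGeometry,
    k_range: int = 2,
    snap_frac: float = 0.5,
) -> tuple[NeighborCandidate, NeighborCandidate]:
    """Fixed-pitch neighbor pair: A at-or-above, B at-or-below the plane,
    each the global nearest over all sources, turns, branches, and rows."""
    cand, j = _scalar_candidates(z_plane, beta, gamma, sinograms, geom, k_range, snap_frac)
    beta_arr = np.asarray([beta], dtype=float)
    idx_a, best_a = _side_winner(cand, z_plane, beta_arr, "above")
    idx_b, best_b = _side_winner(cand, z_plane, beta_arr, "below")
    if not np.isfinite(best_a[0, j]):
        raise CoverageError(f"no candidate at-or-above z={z_plane} for (beta={beta}, gamma={gamma})")
    if not np.isfinite(best_b[0, j]):
        raise CoverageError(f"no candidate at-or-below z={z_plane} for (beta={beta}, gamma={gamma})")
    A = _candidate_from(cand, int(idx_a[0, j]), j, "above")
    B = _candidate_from(cand, int(idx_b[0, j]), j, "below")
    return A, B


def interpolate_fixed(A: NeighborCandidate, B: NeighborCandidate, z_plane: float):
    """Node-exact linear interpolation between the above (A) and below (B)
    neighbors: value = w_A*G_A + (1-w_A)*G_B, w_A = (Z_R - z_B)/(z_A - z_B)."""
    if A.z < z_plane - _Z_TOL or B.z > z_plane + _Z_TOL:
        raise RuntimeError("neighbor z ordering violated (A must be above, B below)")
    dz = A.z - B.z
    if dz <= _Z_TOL:
        return A.value, 1.0
    w = (z_plane - B.z) / dz
    return w * A.value + (1.0 - w) * B.value, float(w)


_FAMILIES = ("direct_below", "complementary_below", "direct_above", "complementary_above")


def candidate_sets_variable(
    z_plane: float,
    beta: float,
    gamma: float,
    sinograms: Sequence,
    geom: HelixGeometry,
    k_range: int = 2,
    snap_frac: float = 0.5,
) -> dict[str, Optional[NeighborCandidate]]:
    """Winners of the four (branch x side) candidate families: the direct
    full-turn families and the complementary half-turn families, below and
    above the plane.  Empty families map to None; both families empty on a
    side raises a coverage error."""
    cand, j = _scalar_candidates(z_plane, beta, gamma, sinograms, geom, k_range, snap_frac)
    beta_arr = np.asarray([beta], dtype=float)
    branches = np.array([0 if m[2] == "direct" else 1 for m in cand["meta"]])
    out: dict[str, Optional[NeighborCandidate]] = {}
    for fam in _FAMILIES:
        branch, side = fam.rsplit("_", 1)
        want = 0 if branch == "direct" else 1
        subset = np.nonzero(branches == want)[0]
        idx, best = _side_winner(cand, z_plane, beta_arr, side, subset=subset)
        out[fam] = None if not np.isfinite(best[0, j]) else _candidate_from(cand, int(idx[0, j]), j, side)
    for side in ("below", "above"):
        if out[f"direct_{side}"] is None and out[f"complementary_{side}"] is None:
            raise CoverageError(f"no candidate {side} z={z_plane} for (beta={beta}, gamma={gamma})")
    return out


def select_neighbors_variable(
    families: dict[str, Optional[NeighborCandidate]], z_plane: float
) -> tuple[NeighborCandidate, NeighborCandidate]:
    """Pick A (below) and B (above) from the four family winners: per side,
    the closer of the direct and complementary winners, with the direct
    family preferred on exact ties ('<=' branch)."""

    def pick(side: str) -> NeighborCandidate:
        d = families.get(f"direct_{side}")
        c = families.get(f"complementary_{side}")
        if d is None and c is None:
            raise CoverageError(f"no candidate {side} the plane z={z_plane}")
        if d is None:
            return c
        if c is None:
            return d
        return d if abs(z_plane - d.z) <= abs(z_plane - c.z) else c

    return pick("below"), pick("above")


def interpolate_variable(A: NeighborCandidate, B: NeighborCandidate, z_plane: float):
    """Variable-pitch interpolation: A below, B above;
    value = w*G_A + (1-w)*G_B with w = (z_B - Z_R)/(z_B - z_A)."""
    if A.z > z_plane + _Z_TOL or B.z < z_plane - _Z_TOL:
        raise RuntimeError("neighbor z ordering violated (A must be below, B above)")
    dz = B.z - A.z
    if dz <= _Z_TOL:
        return A.value, 1.0
    w = (B.z - z_plane) / dz
    return w * A.value + (1.0 - w) * B.value, float(w)


# --- full-plane assembly --------------------------------------------------

def build_planar_fan(
    z_plane: float,
    sinograms: Sequence,
    geom: HelixGeometry,
    mode: str = "fixed",
    n_beta: Optional[int] = None,
    k_range: int = 2,
    snap_frac: float = 0.5,
    ref_source: int = 1,
    with_provenance: bool = True,
) -> PlanarFan:
    """Interpolate a complete planar fan sinogram at ``z_plane`` over one
    full turn beta in [beta_R, beta_R + 2*pi)."""
    if mode not in ("fixed", "variable"):
        raise ValidationError("mode must be 'fixed' or 'variable'")
    sino0 = sinograms[0]
    gamma_grid = sino0.gamma_grid
    beta_R = geom.beta_of_plane(z_plane, ref_source)
    if n_beta is None:
        db_src = float(sino0.beta_grid[1] - sino0.beta_grid[0])
        n_beta = int(round(TWO_PI / db_src))
    beta = beta_R + TWO_PI * np.arange(n_beta) / n_beta

    cand = _gather_candidates(z_plane, beta, gamma_grid, sinograms, geom, k_range, snap_frac)

    if mode == "fixed":
        idx_a, best_a = _side_winner(cand, z_plane, beta, "above")
        idx_b, best_b = _side_winner(cand, z_plane, beta, "below")
    else:
        branches = np.array([0 if m[2] == "direct" else 1 for m in cand["meta"]])
        winners = {}
        for fam in _FAMILIES:
            branch, side = fam.rsplit("_", 1)
            want = 0 if branch == "direct" else 1
            subset = np.nonzero(branches == want)[0]
            winners[fam] = _side_winner(cand, z_plane, beta, side, subset=subset)

        def merge(side):
            di, dd = winners[f"direct_{side}"]
            ci, cd = winners[f"complementary_{side}"]
            use_direct = dd <= cd  # '<=': direct preferred on ties
            return np.where(use_direct, di, ci), np.where(use_direct, dd, cd)

        idx_b, best_b = merge("below")
        idx_a, best_a = merge("above")

    for side, best in (("above", best_a), ("below", best_b)):
        bad = ~np.isfinite(best)
        if np.any(bad):
            bi, gi = np.argwhere(bad)[0]
            raise CoverageError(
                f"no candidate {side} z={z_plane} at beta={beta[bi]:.6f}, "
                f"gamma={gamma_grid[gi]:.6f} (and {bad.sum() - 1} more bins)"
            )

    above = _take(cand, idx_a)
    below = _take(cand, idx_b)
    z_a, z_b = above["z"], below["z"]
    dz = z_a - z_b
    degenerate = dz <= _Z_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        w_above = np.where(degenerate, 1.0, (z_plane - z_b) / np.where(degenerate, 1.0, dz))
    w_above = np.clip(w_above, 0.0, 1.0)
    values = w_above * above["value"] + (1.0 - w_above) * below["value"]
    # degenerate z_a == z_b == Z_R: take the path's own A neighbor
    # (above for the fixed formulation, below for the variable one)
    deg_value = above["value"] if mode == "fixed" else below["value"]
    values = np.where(degenerate, deg_value, values)

    provenance = None
    if with_provenance:
        provenance = {"above": above, "below": below, "weight_above": w_above}
    return PlanarFan(
        values=values,
        z_plane=float(z_plane),
        beta_R=float(beta_R),
        beta_grid=beta,
        gamma_grid=gamma_grid,
        rho=float(geom.rho),
        mode=mode,
        provenance=provenance,
    )
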