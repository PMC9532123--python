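"""Independent reference implementations used as oracles.

Everything here is deliberately written as plain loops with its own
formulas (partner angles, bed positions, nearest-neighbor scans) so it
shares no selection code with the package's vectorized fast path.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def z_of_beta_ref(geom, beta: float) -> float:
    """Bed position: closed form for constant pitch, piecewise trapezoid
    integration of the tabulated speed profile otherwise."""
    from helicalct.geometry import TableSpeed

    if isinstance(geom.pitch, TableSpeed):
        tb, th = geom.pitch.beta_grid, geom.pitch.h_values
        total = 0.0
        for j in range(tb.size - 1):
            b0, b1 = tb[j], tb[j + 1]
            if beta <= b0:
                break
            be = min(beta, b1)
            slope = (th[j + 1] - th[j]) / (b1 - b0)
            h_end = th[j] + slope * (be - b0)
            total += 0.5 * (th[j] + h_end) * (be - b0)
        return total / TWO_PI
    return float(geom.pitch) * beta / TWO_PI


def enumerate_stored_candidates(z_plane, beta, gamma, sinograms, geom, k_range=2):
    """Every stored ray satisfying the parallel-partner condition (after
    snapping to the nearest stored angle), as tuples

    (side, dist, branch_rank, source, dbeta_query, z, value, branch, q, beta_stored)
    """
    out = []
    gamma_grid = sinograms[0].gamma_grid
    j_query = int(np.argmin(np.abs(gamma_grid - gamma)))
    j_mirror = gamma_grid.size - 1 - j_query
    for s in sinograms:
        i = s.source_index
        phi = geom.phases[i - 1]
        bg = s.beta_grid
        db = bg[1] - bg[0]
        n_rows = s.values.shape[2]
        for k in range(-k_range, k_range + 1):
            pairs = [
                ("direct", beta + TWO_PI * k - phi, j_query),
                ("complementary", beta + 2.0 * gamma + (2 * k - 1) * np.pi - phi, j_mirror),
            ]
            for branch, bp, j in pairs:
                u = (bp - bg[0]) / db
                m = int(np.floor(u + 0.5))
                if not (0 <= m < bg.size) or abs(u - m) > 0.5 + 1e-9:
                    continue
                z_src = z_of_beta_ref(geom, bg[m])
                for q in range(1, n_rows + 1):
                    z = z_src + (q - (n_rows + 1) / 2.0) * geom.detector.row_pitch
                    val = s.values[m, j, q - 1]
                    for side, dist in (("above", z - z_plane), ("below", z_plane - z)):
                        if dist >= -1e-9:
                            out.append(
                                (side, max(dist, 0.0), 0 if branch == "direct" else 1,
                                 i, abs(bg[m] - beta), z, val, branch, q, bg[m])
                            )
    return out


def brute_force_neighbors(z_plane, beta, gamma, sinograms, geom, k_range=2, families=False):
    """Exhaustive nearest-above / nearest-below search over stored rays with
    the package's tie order (distance, direct-first, source, |dbeta|).

    With ``families=True`` returns the four (branch x side) winners instead.
    """
    cands = enumerate_stored_candidates(z_plane, beta, gamma, sinograms, geom, k_range)
    key = lambda c: (c[1], c[2], c[3], c[4])
    if families:
        result = {}
        for branch_rank, branch in ((0, "direct"), (1, "complementary")):
            for side in ("below", "above"):
                sub = [c for c in cands if c[0] == side and c[2] == branch_rank]
                result[f"{branch}_{side}"] = min(sub, key=key) if sub else None
        return result
    best = {}
    for side in ("above", "below"):
        sub = [c for c in cands if c[0] == side]
        best[side] = min(sub, key=key) if sub else None
    return best


def planar_fan_180mli(z_plane, sinogram, geom, n_beta=None):
    """Classic single-source half-turn multi-slice linear interpolation,
    coded from scratch: direct partners one full turn apart, complementary
    partners (beta + 2*gamma + odd*pi, -gamma), nearest stored ray above and
    below the plane, linear weight (Z_R - z_below)/(z_above - z_below)."""
    h = float(geom.pitch)
    bg = sinogram.beta_grid
    db = bg[1] - bg[0]
    gamma_grid = sinogram.gamma_grid
    if n_beta is None:
        n_beta = int(round(TWO_PI / db))
    beta_R = TWO_PI * z_plane / h
    out = np.empty((n_beta, gamma_grid.size))
    n_rows = sinogram.values.shape[2]
    offs = [(q - (n_rows + 1) / 2.0) * geom.detector.row_pitch for q in range(1, n_rows + 1)]
    for bi in range(n_beta):
        beta = beta_R + TWO_PI * bi / n_beta
        for j, gamma in enumerate(gamma_grid):
            cands = []
            for k in range(-2, 3):
                for rank, (bp, jj) in enumerate(
                    [(beta + TWO_PI * k, j),
                     (beta + 2 * gamma + (2 * k - 1) * np.pi, gamma_grid.size - 1 - j)]
                ):
                    u = (bp - bg[0]) / db
                    m = int(np.floor(u + 0.5))
                    if not (0 <= m < bg.size) or abs(u - m) > 0.5 + 1e-9:
                        continue
                    for qi, off in enumerate(offs):
                        z = h * bg[m] / TWO_PI + off
                        cands.append((z, sinogram.values[m, jj, qi], rank, abs(bg[m] - beta)))
            above = [c for c in cands if c[0] >= z_plane - 1e-9]
            below = [c for c in cands if c[0] <= z_plane + 1e-9]
            za, va, _, _ = min(above, key=lambda c: (c[0] - z_plane, c[2], c[3]))
            zb, vb, _, _ = min(below, key=lambda c: (z_plane - c[0], c[2], c[3]))
            if za - zb <= 1e-9:
                out[bi, j] = va
            else:
                w = (z_plane - zb) / (za - zb)
                out[bi, j] = w * va + (1 - w) * vb
    return out
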