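import numpy as np
import pytest
from hypothesis import given, strategies as st

from helicalct import (
    CoverageError,
    HelixGeometry,
    NeighborCandidate,
    TableSpeed,
    build_planar_fan,
    candidate_sets_variable,
    interpolate_fixed,
    interpolate_variable,
    parallel_partners,
    ray_of,
    select_neighbors_fixed,
    select_neighbors_variable,
)
from helicalct.geometry import TWO_PI
from helicalct.projector import simulate_planar_fan

from _reference import brute_force_neighbors, planar_fan_180mli
from conftest import commensurate_geom, make_geom, scan


def variable_twin(geom, turns):
    """Same geometry with the constant pitch expressed as a table-speed
    profile (exercises the variable-pitch code path)."""
    h = float(geom.pitch)
    ts = TableSpeed(np.array([0.0, TWO_PI * turns]), np.array([h, h]))
    return HelixGeometry(rho=geom.rho, omega=geom.omega, phases=geom.phases,
                         pitch=ts, detector=geom.detector)


class TestParallelPartners:
    def test_identity_partner(self):
        g = make_geom()
        partners = parallel_partners(0.7, 0.1, g, k_range=0)
        direct = [p for p in partners if p[3] == "direct"]
        assert (1, 0.7, 0.1, "direct") in [
            (i, round(b, 12), gp, br) for i, b, gp, br in direct
        ]

    def test_single_source_complementary_relation(self):
        g = make_geom()
        beta, gamma = 0.9, 0.15
        comp = [p for p in parallel_partners(beta, gamma, g, k_range=1) if p[3] == "complementary"]
        expected = {round(beta + 2 * gamma + (2 * k - 1) * np.pi, 9) for k in (-1, 0, 1)}
        assert {round(p[1], 9) for p in comp} == expected
        assert all(p[2] == -gamma for p in comp)

    def test_partners_are_geometrically_parallel(self):
        """Every enumerated partner's ray is (anti-)parallel to the query
        ray in the x-y plane, for a multi-source geometry."""
        g = make_geom(n_sources=3)
        beta, gamma = 1.3, -0.21
        _, d0 = ray_of(g, 1, beta - g.phases[0], gamma, 1)  # query ray direction
        # query ray: lab angular position beta with fan angle gamma
        ang0 = np.arctan2(d0[1], d0[0])
        for i, bp, gp, branch in parallel_partners(beta, gamma, g, k_range=2):
            if bp < 0:
                continue
            _, d = ray_of(g, i, bp, gp, 1)
            ang = np.arctan2(d[1], d[0])
            delta = np.mod(ang - ang0, np.pi)
            assert min(delta, np.pi - delta) < 1e-9

    def test_beta_range_filter(self):
        g = make_geom()
        inside = parallel_partners(0.5, 0.1, g, k_range=2, beta_range=(0.0, TWO_PI))
        assert all(0 <= p[1] <= TWO_PI for p in inside)


class TestInterpolationWeights:
    def _cand(self, z, value, side):
        return NeighborCandidate(source=1, beta_p=0.0, gamma_p=0.0, q=1,
                                 z=z, value=value, branch="direct", side=side)

    def test_fixed_node_exactness(self):
        A = self._cand(10.0, 3.0, "above")
        B = self._cand(6.0, 1.0, "below")
        assert interpolate_fixed(A, B, 10.0) == (3.0, 1.0)
        assert interpolate_fixed(A, B, 6.0) == (1.0, 0.0)
        v, w = interpolate_fixed(A, B, 8.0)
        assert v == pytest.approx(2.0) and w == pytest.approx(0.5)

    def test_variable_node_exactness(self):
        A = self._cand(6.0, 1.0, "below")
        B = self._cand(10.0, 3.0, "above")
        assert interpolate_variable(A, B, 6.0) == (1.0, 1.0)   # w = 1 -> G_A
        assert interpolate_variable(A, B, 10.0) == (3.0, 0.0)  # w = 0 -> G_B
        v, _ = interpolate_variable(A, B, 8.0)
        assert v == pytest.approx(2.0)

    def test_degenerate_equal_z(self):
        A = self._cand(5.0, 2.0, "above")
        B = self._cand(5.0, 2.5, "below")
        assert interpolate_fixed(A, B, 5.0) == (2.0, 1.0)

    def test_ordering_violation_raises(self):
        A = self._cand(4.0, 1.0, "above")
        B = self._cand(6.0, 2.0, "below")
        with pytest.raises(RuntimeError):
            interpolate_fixed(A, B, 5.0)

    @given(
        zb=st.floats(-50, 50), dz=st.floats(0.01, 30),
        frac=st.floats(0, 1), va=st.floats(-5, 5), vb=st.floats(-5, 5),
    )
    def test_weight_bounds_and_betweenness(self, zb, dz, frac, va, vb):
        """For any bracketing pair the weight is in [0,1] and the value lies
        between the neighbor values."""
        za = zb + dz
        zr = zb + frac * dz
        A = self._cand(za, va, "above")
        B = self._cand(zb, vb, "below")
        v, w = interpolate_fixed(A, B, zr)
        assert 0.0 <= w <= 1.0
        assert min(va, vb) - 1e-9 <= v <= max(va, vb) + 1e-9


class TestNeighborSelection:
    @pytest.mark.parametrize("n_sources,n_rows", [(1, 1), (2, 2), (3, 1)])
    def test_fixed_selection_matches_brute_force(self, smooth_phantom, n_sources, n_rows):
        g = make_geom(n_sources=n_sources, pitch=12.0, n_gamma=21, n_rows=n_rows)
        sinos = scan(smooth_phantom, g, turns=5, n_beta_per_turn=36)
        z_plane = 17.3
        beta_R = g.beta_of_plane(z_plane)
        rng = np.random.default_rng(5)
        for _ in range(25):
            beta = beta_R + float(rng.uniform(0, TWO_PI))
            gamma = float(sinos[0].gamma_grid[rng.integers(0, 21)])
            A, B = select_neighbors_fixed(z_plane, beta, gamma, sinos, g)
            ref = brute_force_neighbors(z_plane, beta, gamma, sinos, g)
            assert A.z == pytest.approx(ref["above"][5], abs=1e-9)
            assert A.value == pytest.approx(ref["above"][6], abs=1e-12)
            assert B.z == pytest.approx(ref["below"][5], abs=1e-9)
            assert B.value == pytest.approx(ref["below"][6], abs=1e-12)
            assert B.z - 1e-9 <= z_plane <= A.z + 1e-9

    def test_exact_plane_hit_returned_on_both_sides(self, smooth_phantom):
        g = commensurate_geom(pitch=12.0)
        sinos = scan(smooth_phantom, g, turns=4, n_beta_per_turn=144)
        # pick a stored sample's z as the plane: central row of beta index 200
        z_plane = float(g.z_at(sinos[0].beta_grid[200]))
        beta = float(sinos[0].beta_grid[200])
        A, B = select_neighbors_fixed(z_plane, beta, 0.0, sinos, g)
        assert A.z == pytest.approx(z_plane, abs=1e-12)
        assert B.z == pytest.approx(z_plane, abs=1e-12)
        v, w = interpolate_fixed(A, B, z_plane)
        assert v == A.value

    def test_half_turn_gap_bound(self, smooth_phantom):
        """Single source, single row: the bracketing gap never exceeds the
        complementary-interpolation bound h/2*(1 + 2*gamma_max/pi), plus the
        angle-snapping slack h*dbeta/2pi."""
        h, fan_half = 12.0, 0.38
        g = make_geom(n_sources=1, pitch=h, n_rows=1, fan_half=fan_half)
        sinos = scan(smooth_phantom, g, turns=5, n_beta_per_turn=72)
        fan = build_planar_fan(17.3, sinos, g, mode="fixed")
        gap = fan.provenance["above"]["z"] - fan.provenance["below"]["z"]
        dbeta = TWO_PI / 72
        bound = h / 2 * (1 + 2 * fan_half / np.pi) + h * dbeta / TWO_PI
        assert gap.max() <= bound + 1e-9

    def test_one_sided_coverage_raises(self, smooth_phantom):
        g = make_geom(pitch=12.0)
        sinos = scan(smooth_phantom, g, turns=2, n_beta_per_turn=36)
        with pytest.raises(CoverageError):
            # below the start of the scan: nothing at-or-below
            select_neighbors_fixed(-10.0, TWO_PI, 0.0, sinos, g)


class TestVariablePath:
    def test_constant_speed_families_merge_to_fixed_selection(self, smooth_phantom):
        g = make_geom(n_sources=2, pitch=12.0, n_gamma=21, n_rows=2)
        gv = variable_twin(g, 5)
        sinos = scan(smooth_phantom, g, turns=5, n_beta_per_turn=36)
        z_plane = 17.3
        beta_R = g.beta_of_plane(z_plane)
        rng = np.random.default_rng(9)
        for _ in range(15):
            beta = beta_R + float(rng.uniform(0, TWO_PI))
            gamma = float(sinos[0].gamma_grid[rng.integers(0, 21)])
            fams = candidate_sets_variable(z_plane, beta, gamma, sinos, gv)
            A_var, B_var = select_neighbors_variable(fams, z_plane)
            A_fix, B_fix = select_neighbors_fixed(z_plane, beta, gamma, sinos, g)
            # variable A is below, fixed A is above: match across conventions
            assert A_var.value == pytest.approx(B_fix.value, abs=1e-12)
            assert B_var.value == pytest.approx(A_fix.value, abs=1e-12)
            v_var, _ = interpolate_variable(A_var, B_var, z_plane)
            v_fix, _ = interpolate_fixed(A_fix, B_fix, z_plane)
            assert v_var == pytest.approx(v_fix, abs=1e-12)

    def test_variable_families_match_brute_force(self, smooth_phantom):
        """Accelerating table: the four family winners equal an exhaustive
        scan over stored rays."""
        turns = 6
        grid = np.linspace(0, TWO_PI * turns, 25)
        ts = TableSpeed(grid, 6.0 + 0.25 * grid)  # linear ramp 6 -> ~15.4 mm/rev
        g = make_geom(n_sources=3, n_gamma=21, n_rows=2)
        gv = HelixGeometry(rho=g.rho, omega=g.omega, phases=g.phases, pitch=ts,
                           detector=g.detector)
        sinos = scan(smooth_phantom, gv, turns=turns, n_beta_per_turn=36)
        z_plane = 25.0
        beta_R = gv.beta_of_plane(z_plane)
        rng = np.random.default_rng(2)
        for _ in range(10):
            beta = beta_R + float(rng.uniform(0, TWO_PI))
            gamma = float(sinos[0].gamma_grid[rng.integers(0, 21)])
            fams = candidate_sets_variable(z_plane, beta, gamma, sinos, gv)
            ref = brute_force_neighbors(z_plane, beta, gamma, sinos, gv, families=True)
            for name in ("direct_below", "complementary_below", "direct_above", "complementary_above"):
                got, want = fams[name], ref[name]
                if want is None:
                    assert got is None
                else:
                    assert got is not None
                    assert got.z == pytest.approx(want[5], abs=1e-9)
                    assert got.value == pytest.approx(want[6], abs=1e-9)

    def test_monotone_ramp_candidate_z_increase_with_beta(self):
        grid = np.linspace(0, TWO_PI * 4, 17)
        ts = TableSpeed(grid, 5.0 + 0.3 * grid)
        z = ts.z_of(np.linspace(0, TWO_PI * 4, 300))
        assert np.all(np.diff(z) > 0)

    def test_direct_preferred_on_equidistant_tie(self):
        d = NeighborCandidate(source=1, beta_p=0.0, gamma_p=0.1, q=1,
                              z=4.0, value=1.0, branch="direct", side="below")
        c = NeighborCandidate(source=1, beta_p=0.5, gamma_p=-0.1, q=1,
                              z=4.0, value=2.0, branch="complementary", side="below")
        a = NeighborCandidate(source=1, beta_p=0.0, gamma_p=0.1, q=1,
                              z=6.0, value=3.0, branch="direct", side="above")
        fams = {"direct_below": d, "complementary_below": c,
                "direct_above": a, "complementary_above": None}
        A, B = select_neighbors_variable(fams, 5.0)
        assert A is d  # tie at distance 1 -> direct wins ('<=' branch)
        assert B is a


class TestBuildPlanarFan:
    def test_zero_pitch_limit_recovers_true_fan(self, smooth_phantom):
        """Tiny pitch + commensurate grids: the interpolated planar fan
        equals the true stationary-plane fan sinogram."""
        g = commensurate_geom(pitch=1e-6)
        sinos = scan(smooth_phantom, g, turns=4, n_beta_per_turn=144)
        z_plane = 2e-6  # beta_R = 4*pi, mid-scan
        fan = build_planar_fan(z_plane, sinos, g, mode="fixed")
        true = simulate_planar_fan(smooth_phantom, g, z_plane,
                                   n_beta=fan.beta_grid.size, beta_R=fan.beta_R)
        rel = np.max(np.abs(fan.values - true.values)) / np.max(np.abs(true.values))
        assert rel < 1e-6

    def test_weights_in_unit_interval_and_sides_ordered(self, smooth_phantom):
        g = make_geom(n_sources=2, pitch=12.0, n_rows=2)
        sinos = scan(smooth_phantom, g, turns=5)
        fan = build_planar_fan(17.3, sinos, g, mode="fixed")
        w = fan.provenance["weight_above"]
        assert np.all((0.0 <= w) & (w <= 1.0))
        assert np.all(fan.provenance["above"]["z"] >= 17.3 - 1e-9)
        assert np.all(fan.provenance["below"]["z"] <= 17.3 + 1e-9)
        assert np.all(np.isfinite(fan.values))

    def test_fixed_and_variable_pipelines_agree_at_constant_speed(self, smooth_phantom):
        turns = 5
        g = make_geom(n_sources=2, pitch=12.0, n_rows=2)
        gv = variable_twin(g, turns)
        sinos = scan(smooth_phantom, g, turns=turns)
        ff = build_planar_fan(17.3, sinos, g, mode="fixed")
        fv = build_planar_fan(17.3, sinos, gv, mode="variable")
        np.testing.assert_array_equal(ff.values, fv.values)

    def test_single_source_reproduces_180mli_reference(self, smooth_phantom):
        g = make_geom(n_sources=1, pitch=12.0, n_gamma=21, n_rows=2)
        sinos = scan(smooth_phantom, g, turns=5, n_beta_per_turn=72)
        fan = build_planar_fan(17.3, sinos, g, mode="fixed")
        ref = planar_fan_180mli(17.3, sinos[0], g)
        np.testing.assert_allclose(fan.values, ref, atol=1e-12)

    @pytest.mark.parametrize(
        "sweep",
        [
            [dict(pitch=32.0), dict(pitch=16.0), dict(pitch=8.0)],
            [dict(n_rows=1), dict(n_rows=2, row_pitch=8.0), dict(n_rows=4, row_pitch=8.0)],
            [dict(n_sources=1), dict(n_sources=2), dict(n_sources=3)],
        ],
        ids=["pitch", "rows", "sources"],
    )
    def test_interpolation_error_monotone_sweeps(self, smooth_phantom, sweep):
        """Interpolation error vs the true plane fan decreases with smaller
        pitch, more detector rows, and more interleaved sources."""
        errs = []
        for kw in sweep:
            kw = {"pitch": 32.0, "n_sources": 1, "n_rows": 1, **kw}
            g = make_geom(n_gamma=33, **kw)
            z_plane = 20.0
            turns = int(np.ceil((z_plane + 3 * kw["pitch"]) / kw["pitch"])) + 2
            sinos = scan(smooth_phantom, g, turns=turns, n_beta_per_turn=72)
            fan = build_planar_fan(z_plane, sinos, g, mode="fixed")
            true = simulate_planar_fan(smooth_phantom, g, z_plane,
                                       n_beta=fan.beta_grid.size, beta_R=fan.beta_R)
            errs.append(np.sqrt(np.mean((fan.values - true.values) ** 2)))
        assert errs[0] > errs[1] > errs[2]

    def test_insufficient_coverage_names_plane(self, smooth_phantom):
        g = make_geom(pitch=12.0)
        sinos = scan(smooth_phantom, g, turns=2)
        with pytest.raises(CoverageError, match="z="):
            build_planar_fan(30.0, sinos, g, mode="fixed")
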