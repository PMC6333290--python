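"""Phase averaging, Jeffery machinery and the wall phase plane."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import shearswim as ss
from hypothesis import given, settings
from hypothesis import strategies as st
from shearswim.bem import FlowModel, MobilityProblem
from shearswim import phase as ph


class TestJefferyClosedForms:
    def test_orbit_is_antiderivative_of_rate(self):
        r, g = 4.2, 1.3
        T = ph.jeffery_period(g, r)
        ts = np.linspace(0.0, T, 2001)
        th = ph.jeffery_orbit(ts, g, r, 0.7)
        dnum = np.gradient(th, ts)[5:-5]
        dana = ph.jeffery_theta_dot(th, g, r)[5:-5]
        assert np.abs(dnum - dana).max() < 5e-3 * dana.max()

    def test_sphere_period(self):
        assert ph.jeffery_period(1.0, 1.0) == pytest.approx(4 * math.pi)

    def test_period_equals_rate_quadrature(self):
        """∮ dθ/θ̇ against the closed form 2π(r + 1/r)/γ."""
        r, g = 3.0, 1.0
        T_quad, _ = quad(lambda th: 1.0 / ph.jeffery_theta_dot(th, g, r), 0, 2 * math.pi, limit=200)
        assert T_quad == pytest.approx(2 * math.pi * (r + 1 / r), rel=1e-9)
        assert T_quad == pytest.approx(20.944, rel=1e-3)


class TestJefferyOrbitProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        r=st.floats(1.01, 20.0),
        g=st.floats(0.05, 5.0),
        th0=st.floats(0.0, 2 * math.pi),
    )
    def test_orbit_monotone_and_periodic(self, r, g, th0):
        """θ(t) is strictly increasing, starts at θ0, and advances exactly
        2π per period for any aspect ratio, shear rate and starting angle."""
        T = ph.jeffery_period(g, r)
        ts = np.linspace(0.0, T, 257)
        th = ph.jeffery_orbit(ts, g, r, th0)
        assert th[0] == pytest.approx(th0, abs=1e-9)
        assert np.all(np.diff(th) > 0)
        assert th[-1] - th[0] == pytest.approx(2 * math.pi, abs=1e-8)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(r=st.floats(1.0, 30.0), g=st.floats(0.05, 5.0))
    def test_fit_inverts_period_law(self, r, g):
        fit = ph.fit_jeffery_ratio([(g, ph.jeffery_period(g, r)), (2 * g, ph.jeffery_period(2 * g, r))])
        assert fit.r == pytest.approx(r, rel=1e-6)


class TestFitJefferyRatio:
    def test_exact_inverse_consistency(self):
        r_true = 3.0
        pts = [(g, ph.jeffery_period(g, r_true)) for g in (0.2, 0.5, 1.0, 2.0)]
        fit = ph.fit_jeffery_ratio(pts)
        assert fit.r == pytest.approx(r_true, abs=1e-10)
        assert fit.residual < 1e-8

    def test_reciprocal_branch_resolved_above_one(self):
        # data generated from r = 1/3 has identical periods; convention r ≥ 1
        pts = [(g, ph.jeffery_period(g, 1.0 / 3.0)) for g in (0.5, 1.0)]
        assert ph.fit_jeffery_ratio(pts).r == pytest.approx(3.0, abs=1e-8)

    def test_impossible_period_rejected(self):
        with pytest.raises(ValueError):
            ph.fit_jeffery_ratio([(1.0, 1.0)])  # γT/2π < 2


class TestPhaseAverage:
    def test_passive_body_average_independent_of_phase_count(self):
        cfg = ss.SwimmerConfig(beat_amplitude=0.0)
        flow = FlowModel(gamma_d=1.0)
        U2, W2 = ph.phase_average(cfg, 0.5, flow, n_phases=2, refinement=0)
        U4, W4 = ph.phase_average(cfg, 0.5, flow, n_phases=4, refinement=0)
        assert np.allclose(U2, U4, atol=1e-12)
        assert np.allclose(W2, W4, atol=1e-12)

    def test_affine_decomposition_in_shear(self, promastigote):
        """Phase average at γ equals swim part + γ × unit-shear response."""
        sols = {
            g: ph.phase_average(promastigote, 0.8, FlowModel(gamma_d=g), n_phases=4, refinement=0)
            for g in (0.0, 1.0, 2.0)
        }
        for comp in (0, 1):
            v = {g: sols[g][comp] for g in sols}
            lin_err = np.abs(v[2.0] - 2 * v[1.0] + v[0.0]).max()
            assert lin_err < 1e-6 * max(np.abs(v[2.0]).max(), 1e-12)

    def test_table_matches_direct_average(self, promastigote, coarse_table):
        U_d, W_d = ph.phase_average(promastigote, 0.7, FlowModel(gamma_d=1.0), n_phases=8, refinement=0)
        U_t, W_t = coarse_table.average(0.7, 1.0)
        assert np.allclose(U_d, U_t, atol=1e-10)
        assert np.allclose(W_d, W_t, atol=1e-10)

    def test_phase_resolution_converged_at_20(self, promastigote):
        """20 vs 40 beat phases differ by under 1% (coarse mesh)."""
        a = ph.phase_average(promastigote, 0.0, FlowModel(gamma_d=1.0), n_phases=20, refinement=0)
        b = ph.phase_average(promastigote, 0.0, FlowModel(gamma_d=1.0), n_phases=40, refinement=0)
        assert np.linalg.norm(a[0] - b[0]) < 0.01 * np.linalg.norm(b[0])
        assert abs(a[1][2] - b[1][2]) < 0.01 * abs(b[1][2]) + 1e-4


class TestBulkRotation:
    def test_rate_positive_everywhere_at_unit_shear(self, promastigote, coarse_table):
        thetas = np.linspace(0, 2 * math.pi, 24, endpoint=False)
        rates = coarse_table.theta_dot(thetas, 1.0)
        assert np.all(rates > 0)  # full tumbling, no bulk fixed point

    def test_out_of_plane_leakage_guard(self, promastigote, coarse_table):
        # healthy planar problem passes the symmetry check
        rate = ph.bulk_angular_rate(0.4, 1.0, promastigote, table=coarse_table)
        assert rate > 0

    def test_period_scaling_with_shear_rate(self, promastigote, coarse_table):
        """γ·T constant across the scanned range (Jeffery-like scaling)."""
        prods = []
        for g in (0.2, 0.5, 1.0):
            T = ph.rotation_period(g, promastigote, table=coarse_table)
            prods.append(g * T)
        assert max(prods) / min(prods) - 1 < 0.02

    def test_pusher_and_puller_share_aspect_ratio(self, promastigote, coarse_table, pusher, pusher_table):
        def fit(cfg, table):
            pts = [(g, ph.rotation_period(g, cfg, table=table)) for g in (0.5, 1.0)]
            return ph.fit_jeffery_ratio(pts).r

        r_pull = fit(promastigote, coarse_table)
        r_push = fit(pusher, pusher_table)
        assert r_push == pytest.approx(r_pull, rel=0.02)


class TestWallField:
    def test_affine_in_gamma_against_direct_solve(self, promastigote, wall_field):
        """Field reconstruction at γ=2 equals a direct wall phase average."""
        it, ih = 3, 4
        th, h = wall_field.theta_grid[it], wall_field.h_grid[ih]
        assert wall_field.valid[it, ih]
        state = ss.SwimmerState.from_wall_coordinates(th, h)
        U_d, W_d = ph.phase_average(
            promastigote, state, FlowModel(gamma_d=2.0, geometry="wall_shear", wall_present=True),
            n_phases=wall_field.n_phases, refinement=0,
        )
        assert np.allclose(wall_field.U_avg(2.0)[it, ih], U_d, atol=1e-9)
        assert np.allclose(wall_field.W_avg(2.0)[it, ih], W_d, atol=1e-9)

    def test_far_row_approaches_bulk(self, wall_field, coarse_table):
        """At h ≈ 50 μm the wall influence on the rotation rate is small.

        The wall-shear flow axis (−x̂2) is rotated 90° from the bulk-shear
        axis (x̂1), so the bulk rate is evaluated at θ − π/2.
        """
        ih = int(np.argmin(np.abs(wall_field.h_grid - 50.0)))
        for it in (0, 4, 8, 12):
            th = wall_field.theta_grid[it]
            td_wall = wall_field.reduced_rates(1.0)[0][it, ih]
            td_bulk = float(coarse_table.theta_dot(th - math.pi / 2, 1.0))
            assert td_wall == pytest.approx(td_bulk, rel=0.04, abs=0.01)

    def test_invalid_nodes_flagged_near_wall(self, wall_field):
        assert (~wall_field.valid).any()
        # the closest row contains penetrating orientations (swimmer longer than h)
        assert (~wall_field.valid[:, 0]).any()
        assert wall_field.valid[:, -1].all()


class TestSaddleAndSeparatrix:
    def test_saddle_exists_with_opposite_sign_eigenvalues(self, wall_field):
        s = ph.find_saddle(wall_field, 1.0)
        assert s.found
        assert s.is_saddle
        ev = np.real(s.eigenvalues)
        assert ev.min() < 0 < ev.max()
        assert np.abs(np.imag(s.eigenvalues)).max() < 1e-10

    def test_shear_reversal_mirrors_saddle(self, wall_field):
        s_pos = ph.find_saddle(wall_field, 1.0)
        s_neg = ph.find_saddle(wall_field, -1.0)
        assert s_pos.found and s_neg.found
        assert s_neg.theta == pytest.approx(2 * math.pi - s_pos.theta, abs=1e-3)
        assert s_neg.h == pytest.approx(s_pos.h, rel=1e-3)

    def test_saddle_height_decreases_with_shear(self, wall_field):
        hs = [ph.find_saddle(wall_field, g).h for g in (0.5, 1.0, 2.0)]
        assert hs[0] > hs[1] > hs[2]

    def test_separatrix_rises_as_shear_drops(self, wall_field):
        """Pointwise in θ, the weaker-shear separatrix sits higher."""
        a_lo = ph.compute_separatrix(wall_field, ph.find_saddle(wall_field, 0.5), 0.5)
        a_hi = ph.compute_separatrix(wall_field, ph.find_saddle(wall_field, 1.0), 1.0)
        lo_span = np.mod(a_lo.separatrix[:, 0], 2 * math.pi)
        hi_span = np.mod(a_hi.separatrix[:, 0], 2 * math.pi)
        common = [
            t
            for t in np.linspace(0, 2 * math.pi, 13)
            if lo_span.min() < t < lo_span.max() and hi_span.min() < t < hi_span.max()
        ]
        assert len(common) >= 3
        higher = sum(a_lo.separatrix_height(t) > a_hi.separatrix_height(t) for t in common)
        assert higher == len(common)

    def test_separatrix_mirror_under_reversal(self, wall_field):
        a_pos = ph.compute_separatrix(wall_field, ph.find_saddle(wall_field, 1.0), 1.0)
        a_neg = ph.compute_separatrix(wall_field, ph.find_saddle(wall_field, -1.0), -1.0)
        for t in np.linspace(0.2, 1.2, 4):
            th_probe = a_pos.saddle.theta - t
            h_pos = a_pos.separatrix_height(th_probe)
            h_neg = a_neg.separatrix_height(2 * math.pi - th_probe)
            assert h_neg == pytest.approx(h_pos, rel=0.02)

    def test_two_sided_collision_escape_dichotomy(self, wall_field):
        """Probes just below the separatrix collide; just above escape."""
        ana = ph.compute_separatrix(wall_field, ph.find_saddle(wall_field, 1.0), 1.0)
        span = ana.separatrix[:, 0]
        probes = np.linspace(span.min() + 0.15, span.max() - 0.15, 10)
        for t in probes:
            hsep = float(np.interp(t, span[::-1], ana.separatrix[::-1, 1]) if span[0] > span[-1] else np.interp(t, span, ana.separatrix[:, 1]))
            if not (wall_field.h_grid.min() * 1.3 < hsep < wall_field.h_grid.max() * 0.7):
                continue
            below = ph.classify_configuration(wall_field, t, hsep * 0.88, 1.0)
            above = ph.classify_configuration(wall_field, t, hsep * 1.12, 1.0)
            assert below == "collision"
            assert above == "escape"


class TestCriticalShear:
    def test_saddle_height_monotone_on_scan(self, wall_field):
        gs = np.array([0.5, 1.0, 1.5, 2.0])
        hs = []
        for g in gs:
            s = ph.find_saddle(wall_field, g)
            hs.append(s.h if s.found else 0.0)
        hs = np.array(hs)
        found = hs > 0
        assert np.all(np.diff(hs[found]) < 0)
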