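"""Laplace-space solution: eigenvalues, closure, coefficients, concentration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cleftflux import (
    CleftGeometry,
    Jhat,
    Qhat,
    SeriesConfig,
    TransportParams,
    concentration_hat,
    disk_average_concentration_hat,
    gamma_lm,
    solve_series_coefficients,
    uhat_exponential,
)
from cleftflux.coefficients import cached_table, epsilon_grid
from cleftflux.laplace_core import release_bc_residual, sink_bc_residual


class TestGamma:
    def test_fundamental_mode_is_sqrt_s_over_D(self, geometry):
        assert gamma_lm(0, 0, 2.0, 1e5, geometry) == pytest.approx(
            math.sqrt(2.0 / 1e5), rel=1e-14
        )

    def test_zero_s_lateral_mode(self, geometry):
        assert gamma_lm(1, 0, 0.0, 1e5, geometry) == pytest.approx(
            2 * math.pi / 500.0, rel=1e-14
        )

    def test_mixed_mode_value(self, geometry):
        expected = math.sqrt(1e-5 + 2 * (2 * math.pi / 500.0) ** 2)
        assert gamma_lm(1, 1, 1.0, 1e5, geometry) == pytest.approx(expected, rel=1e-14)

    def test_degenerate_origin_raises(self, geometry):
        with pytest.raises(ValueError):
            gamma_lm(0, 0, 0.0, 1e5, geometry)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        l=st.integers(min_value=0, max_value=20),
        m=st.integers(min_value=0, max_value=20),
        s=st.floats(min_value=1e-6, max_value=1e4),
    )
    def test_monotone_in_mode_indices(self, l, m, s):
        g = CleftGeometry()
        base = gamma_lm(l, m, s, 1e5, g)
        assert gamma_lm(l + 1, m, s, 1e5, g) > base
        assert gamma_lm(l, m + 1, s, 1e5, g) > base


class TestReleaseTransform:
    def test_value_at_zero_is_t0(self):
        assert uhat_exponential(0.0, 1.0) == 1.0
        assert uhat_exponential(0.0, 3.0) == 3.0

    def test_half_value_at_reciprocal_t0(self):
        assert uhat_exponential(1.0, 1.0) == pytest.approx(0.5)

    def test_large_s_limit(self):
        assert uhat_exponential(1e8, 1.0) == pytest.approx(1e-8, rel=1e-6)


class TestQhat:
    def test_small_s_limit_reproduces_conservation(self, geometry, config):
        """pi a^2 Q(s) -> pi R^2 u^(s) as s -> 0 (accumulated-flux identity),
        for several (R, a, D) combinations including the standard set."""
        combos = [
            (20.0, 10.0, 1e5),
            (20.0, 2.5, 1e5),
            (20.0, 40.0, 4e5),
            (10.0, 10.0, 0.4e5),
            (40.0, 5.0, 1e5),
        ]
        s = config.small_s
        for R, a, D in combos:
            g = CleftGeometry(R=R, a=a)
            p = TransportParams(D=D, t0=1.0)
            q = cached_table(g.R, g, config.lmax, config.quad_order)
            ptab = cached_table(g.a, g, config.lmax, config.quad_order)
            jh = Jhat(s, g, p, q, ptab, config)
            exact = math.pi * R**2 * uhat_exponential(s, p.t0)
            assert jh == pytest.approx(exact, rel=1e-3)

    def test_accumulated_flux_independent_of_sink_radius(self, config):
        vals = []
        for a in (2.5, 10.0, 40.0):
            g = CleftGeometry(a=a)
            p = TransportParams()
            q = cached_table(g.R, g, config.lmax, config.quad_order)
            ptab = cached_table(g.a, g, config.lmax, config.quad_order)
            vals.append(Jhat(config.small_s, g, p, q, ptab, config))
        assert max(vals) / min(vals) - 1 < 1e-3

    def test_linearity_zero_release_gives_zero(self, geometry, transport, tables, config):
        q, p = tables
        assert Qhat(1.0, geometry, transport, q, p, config,
                    release=lambda s: np.zeros_like(np.asarray(s, float))) == 0.0

    def test_truncation_convergence_is_algebraic(self, geometry, transport, config):
        """Q converges ~ lmax^-2 (discontinuous sink indicator): consecutive
        truncation doublings shrink the difference by roughly 4x, and the
        40-vs-80 difference stays below 2% over the working s range."""
        for s in (1e-3, 1.0, 1e2):
            j = {}
            for lmax in (40, 80, 160):
                q = cached_table(geometry.R, geometry, lmax, config.quad_order)
                p = cached_table(geometry.a, geometry, lmax, config.quad_order)
                j[lmax] = Jhat(s, geometry, transport, q, p)
            rel_40_80 = abs(j[40] - j[80]) / abs(j[80])
            assert rel_40_80 < 0.02
            ratio = abs(j[40] - j[80]) / abs(j[80] - j[160])
            assert 2.0 < ratio < 8.0

    def test_invariant_under_quadrature_order(self, geometry, transport, config):
        vals = []
        for qo in (64, 96):
            q = cached_table(geometry.R, geometry, config.lmax, qo)
            p = cached_table(geometry.a, geometry, config.lmax, qo)
            vals.append(Jhat(1.0, geometry, transport, q, p))
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)

    def test_no_overflow_at_extreme_s(self, geometry, transport, tables, config):
        """gamma*Lz up to ~1e4 must evaluate without overflow."""
        q, p = tables
        s_huge = 4.0e9  # gamma_00*Lz = sqrt(s/D)*Lz = 1e4
        val = Jhat(s_huge, geometry, transport, q, p, config)
        assert np.isfinite(val) and val >= 0.0

    def test_requires_positive_s(self, geometry, transport, tables, config):
        q, p = tables
        with pytest.raises(ValueError):
            Qhat(0.0, geometry, transport, q, p, config)

    def test_mismatched_truncation_rejected(self, geometry, transport, config):
        q = cached_table(geometry.R, geometry, 40, 64)
        p = cached_table(geometry.a, geometry, 20, 64)
        with pytest.raises(ValueError):
            Qhat(1.0, geometry, transport, q, p, config)


class TestSeriesCoefficients:
    @pytest.mark.parametrize("s", [0.01, 1.0, 100.0])
    def test_boundary_identities_hold_to_roundoff(
        self, geometry, transport, tables, config, s
    ):
        q, p = tables
        Q = Qhat(s, geometry, transport, q, p, config)
        state = solve_series_coefficients(s, geometry, transport, q, p, Q)
        r_rel = release_bc_residual(state, transport, q, geometry)
        r_sink = sink_bc_residual(state, transport, p, geometry)
        scale_rel = abs(state.uhat) * np.abs(q.values).max()
        scale_sink = abs(state.Q) * np.abs(p.values).max()
        assert np.abs(r_rel).max() <= 1e-10 * scale_rel
        assert np.abs(r_sink).max() <= 1e-10 * scale_sink

    def test_zero_release_zero_flux_gives_zero_field(
        self, geometry, transport, tables
    ):
        q, p = tables
        state = solve_series_coefficients(
            1.0, geometry, transport, q, p, 0.0,
            release=lambda s: np.zeros_like(np.asarray(s, float)),
        )
        assert np.all(state.alpha == 0.0)
        assert np.all(state.beta == 0.0)
        assert concentration_hat(0.0, 0.0, 25.0, 1.0, state, geometry) == 0.0


class TestConcentration:
    @pytest.mark.parametrize("s", [0.1, 1.0, 10.0])
    def test_closure_zeroes_sink_average(self, geometry, transport, tables, config, s):
        """The disk-averaged transform over the sink at z = Lz vanishes (to
        round-off) relative to the same average at z = 0 — the defining
        condition of the constant-flux closure."""
        q, p = tables
        Q = Qhat(s, geometry, transport, q, p, config)
        state = solve_series_coefficients(s, geometry, transport, q, p, Q)
        top = disk_average_concentration_hat(geometry.Lz, state, geometry, p)
        bottom = disk_average_concentration_hat(0.0, state, geometry, p)
        assert abs(top) <= 1e-6 * abs(bottom)

    def test_source_flux_recovered_from_series_derivative(
        self, geometry, transport, config
    ):
        """D dC^/dz at z=0 averaged over the source disk approaches u^(s);
        convergence is slow (Parseval tail ~ 1/lmax of the discontinuous
        indicator), so the check is at a loose tolerance that tightens with
        lmax."""
        s = 1.0
        devs = {}
        for lmax in (40, 160):
            q = cached_table(geometry.R, geometry, lmax, config.quad_order)
            p = cached_table(geometry.a, geometry, lmax, config.quad_order)
            Q = Qhat(s, geometry, transport, q, p)
            state = solve_series_coefficients(s, geometry, transport, q, p, Q)
            g = state.gamma
            ex = np.exp(-g * geometry.Lz)
            dprof = transport.D * g * (state.alpha * ex - state.beta)
            w = q.values / epsilon_grid(lmax)
            avg = geometry.cell_area / (4 * math.pi * geometry.R**2) * np.sum(dprof * w)
            devs[lmax] = abs(avg - state.uhat) / state.uhat
        assert devs[40] < 0.10
        assert devs[160] < devs[40]

    def test_out_of_cleft_height_rejected(self, geometry, transport, tables, config):
        q, p = tables
        Q = Qhat(1.0, geometry, transport, q, p, config)
        state = solve_series_coefficients(1.0, geometry, transport, q, p, Q)
        with pytest.raises(ValueError):
            concentration_hat(0.0, 0.0, geometry.Lz + 1.0, 1.0, state, geometry)
        with pytest.raises(ValueError):
            disk_average_concentration_hat(-1.0, state, geometry, p)
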