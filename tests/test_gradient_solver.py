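"""Steady-state solver: closed-form oracles, interface continuity,
conservation, and analytic gradient/shift properties."""

import numpy as np
import pytest
import sympy as sp

from morphograd import (
    AnalyticGradient,
    SolverFailure,
    analytic_exponential,
    analytic_power_law,
    default_kinetics,
    deterministic_reference,
    power_law_length_scale,
    readout_shift,
    sample_domain,
    sample_kinetic_field,
    solve_steady_state,
)
from morphograd.gradient_solver import (
    cosh_reference_profile,
    dirichlet_bc_reference_profile,
    flattening_onset,
    flux_bc_reference_profile,
    mass_balance,
)
from morphograd.kinetics import KineticField, SourceBoundarySpec
from morphograd.tissue_domain import AreaDistributionSpec, uniform_domain


def _uniform_field(domain, spec):
    return KineticField(
        p=np.full(domain.n_cells, spec.mu_p),
        d=np.full(domain.n_cells, spec.mu_d),
        D=np.full(domain.n_cells, spec.mu_D),
        n=spec.n,
        C_ref=spec.C_ref,
    )


class TestAnalyticForms:
    def test_exponential_values(self):
        spec = default_kinetics()
        assert analytic_exponential(1.0, spec.mu_D, spec.mu_d, 0.0) == pytest.approx(1.0)
        assert analytic_exponential(1.0, spec.mu_D, spec.mu_d, 20.0) == pytest.approx(np.exp(-1))
        # linear in amplitude
        assert analytic_exponential(2.0, spec.mu_D, spec.mu_d, 13.0) == pytest.approx(
            2 * analytic_exponential(1.0, spec.mu_D, spec.mu_d, 13.0)
        )

    @pytest.mark.parametrize("n, m", [(2.0, 2.0), (3.0, 1.0), (5.0, 0.5)])
    def test_power_law_exponent(self, n, m):
        g = AnalyticGradient.power_law(1.0, 0.033, 8.25e-5, n)
        assert g.m == pytest.approx(m)

    def test_power_law_length_scale_value(self):
        # D/d = 400 µm², n = 2, C0 = C_ref: lambda_m = sqrt(1.5 * 400)
        lam = power_law_length_scale(0.033, 8.25e-5, 2.0, 1.0, 1.0)
        assert lam == pytest.approx(np.sqrt(600.0))

    def test_power_law_satisfies_steady_state_equation_symbolically(self):
        # substitute C0 (1 + x/(m lam))^(-m) into D C'' = d C^n / C_ref^(n-1)
        # with lam = sqrt((m+1)/m (D/d) (C_ref/C0)^(n-1)); residual must vanish
        x, D, d, C0, Cref, n = sp.symbols("x D d C0 Cref n", positive=True)
        m = 2 / (n - 1)
        lam = sp.sqrt((m + 1) / m * (D / d) * (Cref / C0) ** (n - 1))
        C = C0 * (1 + x / (m * lam)) ** (-m)
        residual = D * sp.diff(C, x, 2) - d * C**n / Cref ** (n - 1)
        for n_val in (2, 3, 4):
            assert sp.simplify(residual.subs(n, n_val)) == 0

    def test_power_law_residual_vanishes_numerically(self):
        # ODE-residual oracle via high-order finite differences
        D, d, n, C_ref, C0 = 0.033, 8.25e-5, 2.0, 1.0, 0.7
        rng = np.random.default_rng(1)
        x = rng.uniform(0.0, 500.0, 100)
        h = 1e-2
        stencil = np.array([-2, -1, 0, 1, 2]) * h
        w = np.array([-1.0, 16.0, -30.0, 16.0, -1.0]) / (12 * h**2)
        C = analytic_power_law(C0, D, d, n, C_ref, x[:, None] + stencil[None, :])
        d2C = C @ w
        resid = D * d2C - d * C[:, 2] ** n / C_ref ** (n - 1)
        assert np.max(np.abs(resid) / (d * C[:, 2] ** n)) < 1e-6

    def test_power_law_requires_superlinear_decay(self):
        with pytest.raises(ValueError):
            analytic_power_law(1.0, 0.033, 8.25e-5, 1.0, 1.0, 10.0)


class TestReadoutShift:
    def test_exponential_shift_is_amplitude_independent(self):
        spec = default_kinetics()
        for C0 in (1.0, 17.3):
            g = AnalyticGradient.exponential(C0, spec.mu_D, spec.mu_d)
            shift = readout_shift(g, C_theta=0.01 * C0, amplitude_factor=2.0)
            assert shift == pytest.approx(20.0 * np.log(2.0), rel=1e-12)

    def test_unit_factor_gives_zero_shift(self):
        g = AnalyticGradient.exponential(1.0, 0.033, 8.25e-5)
        assert readout_shift(g, 0.1, 1.0) == pytest.approx(0.0)

    def test_power_law_shift_shrinks_with_amplitude(self):
        spec = default_kinetics(n=2.0)
        lo = AnalyticGradient.power_law(1.0, spec.mu_D, spec.mu_d, 2.0)
        hi = lo.with_amplitude(10.0)
        c_theta = 1e-3
        assert readout_shift(hi, c_theta, 2.0) < readout_shift(lo, c_theta, 2.0)

    def test_threshold_above_amplitude_is_an_error(self):
        g = AnalyticGradient.exponential(1.0, 0.033, 8.25e-5)
        with pytest.raises(ValueError):
            readout_shift(g, C_theta=2.0, amplitude_factor=3.0)


class TestSolveSteadyState:
    def test_matches_cosh_closed_form_for_linear_decay(self):
        spec = default_kinetics()
        ref = deterministic_reference(spec, Lp=400.0, tol=1e-8)
        x = np.linspace(-25.0, 400.0, 1500)
        exact = cosh_reference_profile(x, spec.mu_p, spec.mu_d, spec.mu_D, 25.0, 400.0)
        assert np.max(np.abs(ref.concentration(x) / exact - 1.0)) < 1e-6

    @pytest.mark.parametrize("mode_profile", [
        ("flux", flux_bc_reference_profile),
        ("dirichlet", dirichlet_bc_reference_profile),
    ])
    def test_matches_closed_forms_for_boundary_source_modes(self, mode_profile):
        mode, profile = mode_profile
        spec = default_kinetics()
        src = SourceBoundarySpec(mode=mode)
        ref = deterministic_reference(spec, src, Lp=300.0, tol=1e-8)
        x = np.linspace(0.0, 300.0, 800)
        exact = profile(x, src.mean_boundary_value, spec.mu_d, spec.mu_D, 300.0)
        assert np.max(np.abs(ref.concentration(x) / exact - 1.0)) < 1e-6

    @pytest.mark.parametrize("n", [2.0, 4.0])
    def test_matches_power_law_away_from_distal_boundary(self, n):
        spec = default_kinetics(n=n)
        lam_m = power_law_length_scale(spec.mu_D, spec.mu_d, n, 1.0)
        Lp = 80.0 * lam_m
        ref = deterministic_reference(
            spec, SourceBoundarySpec(mode="dirichlet"), Lp=Lp, mu_delta=Lp / 120, tol=1e-8
        )
        x = np.linspace(0.0, Lp / 4, 600)
        exact = analytic_power_law(1.0, spec.mu_D, spec.mu_d, n, 1.0, x)
        assert np.max(np.abs(ref.concentration(x) / exact - 1.0)) < 0.01

    def test_zero_influx_gives_zero_gradient(self):
        dom = uniform_domain(5.0, 0.0, 200.0)
        fld = _uniform_field(dom, default_kinetics())
        sol = solve_steady_state(dom, fld, SourceBoundarySpec(mode="flux"), boundary_value=0.0)
        assert np.max(np.abs(sol.concentration(np.linspace(0, 200, 100)))) < 1e-12

    def test_concentration_and_flux_continuous_at_cell_borders(self):
        rng = np.random.default_rng(8)
        dom = sample_domain(AreaDistributionSpec(), 25.0, 500.0, rng)
        fld = sample_kinetic_field(default_kinetics(), dom, rng)
        sol = solve_steady_state(dom, fld)
        borders = dom.boundaries[1:-1]
        eps = 1e-6
        c_jump = np.abs(sol.concentration(borders + eps) - sol.concentration(borders - eps))
        f_jump = np.abs(sol.flux(borders + eps) - sol.flux(borders - eps))
        assert np.max(c_jump / sol.amplitude) < 1e-6
        assert np.max(f_jump / np.max(np.abs(sol.flux(borders)))) < 1e-5

    def test_positive_and_monotone_decreasing_reference(self, reference_n1):
        x = np.linspace(0.0, 1000.0, 2000)
        C = reference_n1.concentration(x)
        assert np.all(C > 0)
        assert np.all(np.diff(C) < 0)

    def test_distal_no_flux_condition(self, reference_n1):
        scale = reference_n1.amplitude * np.sqrt(0.033 * 8.25e-5)
        assert abs(reference_n1.flux(1000.0)) < 1e-6 * scale

    def test_mismatched_field_rejected(self):
        dom = uniform_domain(5.0, 25.0, 100.0)
        short = uniform_domain(5.0, 25.0, 50.0)
        fld = _uniform_field(short, default_kinetics())
        with pytest.raises(ValueError):
            solve_steady_state(dom, fld)

    @pytest.mark.parametrize("n", [1.0, 2.0])
    def test_production_degradation_balance_noisy(self, n):
        rng = np.random.default_rng(15)
        dom = sample_domain(AreaDistributionSpec(), 25.0, 1000.0, rng)
        fld = sample_kinetic_field(default_kinetics(n=n), dom, rng)
        sol = solve_steady_state(dom, fld)
        assert mass_balance(sol)["relative_mismatch"] < 1e-3


class TestDeterministicReference:
    def test_log_slope_recovers_decay_length(self, reference_n1):
        x = np.linspace(40.0, 800.0, 500)
        slope = np.polyfit(x, np.log(reference_n1.concentration(x)), 1)[0]
        assert -1.0 / slope == pytest.approx(20.0, rel=0.005)

    def test_nonlinear_decay_has_shallower_tail(self):
        # at matched amplitude the n = 2 profile lies above n = 1 far out
        spec1, spec2 = default_kinetics(), default_kinetics(n=2.0)
        src = SourceBoundarySpec(mode="dirichlet")
        r1 = deterministic_reference(spec1, src, Lp=1000.0)
        r2 = deterministic_reference(spec2, src, Lp=1000.0)
        x = np.linspace(100.0, 900.0, 50)
        assert np.all(r2.concentration(x) > r1.concentration(x))

    def test_flattening_range_grows_with_decay_order(self):
        onsets = {}
        for n in (1.0, 2.0, 4.0):
            ref = deterministic_reference(default_kinetics(n=n))
            onsets[n] = flattening_onset(ref)
        # onset moves toward the source as n increases
        assert onsets[4.0] < onsets[2.0] < onsets[1.0]
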