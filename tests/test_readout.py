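"""Threshold readout, positional error, bootstrap and the first-order
noise-to-position relation."""

import math

import numpy as np
import pytest

from morphograd import (
    AreaDistributionSpec,
    EnsembleConfig,
    default_kinetics,
    eq_noise_to_position_error,
    positional_error,
    read_position,
    run_ensemble,
    threshold_from_reference,
)
from morphograd.gradient_solver import GradientRealization, SolverDiagnostics
from morphograd.kinetics import KineticField
from morphograd.readout import ReadoutEnsemble, simulate_realizations
from morphograd.tissue_domain import uniform_domain

MU_DELTA = 5.0


def _fake_realization(cell_averages, Lp):
    dom = uniform_domain(MU_DELTA, 0.0, Lp)
    fld = KineticField(
        p=np.ones(dom.n_cells), d=np.ones(dom.n_cells), D=np.ones(dom.n_cells), n=1.0, C_ref=1.0
    )
    diag = SolverDiagnostics(0.0, 0, 0, True, 0)
    return dom, GradientRealization(
        domain=dom, field=fld, cell_averages=np.asarray(cell_averages, dtype=float),
        diagnostics=diag, mode="flux", boundary_value=1.0,
    )


class TestThresholdFromReference:
    def test_monotone_decreasing_in_target_position(self, reference_n1):
        targets = [0.0, 10.0, 100.0, 500.0, 999.0]
        thresholds = [threshold_from_reference(reference_n1, x) for x in targets]
        assert all(a > b for a, b in zip(thresholds, thresholds[1:]))

    def test_one_decay_length_drops_concentration_by_e(self, reference_n1):
        # per-cell averaging applies the same correction factor to every
        # cell, so threshold ratios follow the pure exponential
        c0 = threshold_from_reference(reference_n1, 0.0)
        c20 = threshold_from_reference(reference_n1, 20.0)
        assert c20 / c0 == pytest.approx(np.exp(-1.0), rel=0.01)

    @pytest.mark.parametrize("x", [-1.0, 1000.1])
    def test_out_of_domain_rejected(self, reference_n1, x):
        with pytest.raises(ValueError):
            threshold_from_reference(reference_n1, x)


class TestReadPosition:
    def test_first_subceeding_cell_border(self):
        dom, real = _fake_realization([1.0, 0.5, 0.2], Lp=15.0)
        assert read_position(real, dom, 0.4) == 10.0

    def test_threshold_above_all_averages_reads_zero(self):
        dom, real = _fake_realization([1.0, 0.5, 0.2], Lp=15.0)
        assert read_position(real, dom, 2.0) == 0.0

    def test_zero_threshold_is_censored(self):
        dom, real = _fake_realization([1.0, 0.5, 0.2], Lp=15.0)
        assert math.isnan(read_position(real, dom, 0.0))

    def test_first_crossing_wins_even_if_profile_recovers(self):
        dom, real = _fake_realization([1.0, 0.3, 0.8, 0.2], Lp=20.0)
        assert read_position(real, dom, 0.4) == 5.0


def _ensemble_from(positions, **kwargs):
    positions = np.asarray(positions, dtype=float)
    defaults = dict(
        threshold=0.1, target_position=10.0, n_replicates=positions.size,
        n_censored=int(np.isnan(positions).sum()), mu_delta=MU_DELTA,
    )
    defaults.update(kwargs)
    return ReadoutEnsemble(positions=positions, **defaults)


class TestPositionalError:
    def test_degenerate_ensembles(self, rng):
        s = positional_error(_ensemble_from([10.0] * 4), rng=rng)
        assert s.sigma_x == 0.0 and s.sigma_x_se == 0.0

    def test_two_point_standard_deviation(self, rng):
        s = positional_error(_ensemble_from([0.0, 10.0]), rng=rng)
        assert s.sigma_x == pytest.approx(math.sqrt(50.0))

    def test_requires_two_uncensored(self, rng):
        with pytest.raises(ValueError):
            positional_error(_ensemble_from([10.0, math.nan]), rng=rng)

    def test_invariant_under_reordering_and_censored_entries(self, rng):
        base = [3.0, 7.0, 11.0, 2.0, 9.0]
        s1 = positional_error(_ensemble_from(base), rng=np.random.default_rng(0))
        s2 = positional_error(
            _ensemble_from(base[::-1] + [math.nan]), rng=np.random.default_rng(0)
        )
        assert s1.sigma_x == pytest.approx(s2.sigma_x)
        assert s2.n_censored == 1

    def test_bootstrap_se_matches_normal_theory(self, rng):
        # for near-normal positions, SE[sigma] ~ sigma / sqrt(2 (n-1))
        n = 1000
        positions = np.random.default_rng(42).normal(50.0, 8.0, n)
        s = positional_error(_ensemble_from(positions), n_bootstrap=2000, rng=rng)
        assert s.sigma_x_se == pytest.approx(s.sigma_x / math.sqrt(2 * (n - 1)), rel=0.2)


class TestRunEnsemble:
    def test_noise_free_ensemble_has_zero_positional_error(self):
        cfg = EnsembleConfig(
            kinetics=default_kinetics(cv_p=0.0, cv_d=0.0, cv_D=0.0),
            area=AreaDistributionSpec(cv_A=0.0),
            Lp_over_delta=50.0,
        )
        ens = run_ensemble(cfg, [50.0], n_replicates=5, seed=0)[50.0]
        assert np.all(ens.positions == ens.positions[0])
        s = positional_error(ens, rng=np.random.default_rng(0))
        assert s.sigma_x == 0.0

    def test_same_seed_bit_identical(self):
        cfg = EnsembleConfig(kinetics=default_kinetics(), Lp_over_delta=50.0)
        e1 = run_ensemble(cfg, [50.0], n_replicates=8, seed=77)[50.0]
        e2 = run_ensemble(cfg, [50.0], n_replicates=8, seed=77)[50.0]
        assert np.array_equal(e1.positions, e2.positions)
        e3 = run_ensemble(cfg, [50.0], n_replicates=8, seed=78)[50.0]
        assert not np.array_equal(e1.positions, e3.positions)

    def test_minimum_replicates_enforced(self):
        cfg = EnsembleConfig(kinetics=default_kinetics())
        with pytest.raises(ValueError):
            run_ensemble(cfg, [25.0], n_replicates=1, seed=0)

    def test_unreliable_flag_trips_above_20_percent(self):
        ens = _ensemble_from([1.0, 2.0, math.nan, math.nan], n_replicates=4)
        assert ens.unreliable
        ens2 = _ensemble_from([1.0, 2.0, 3.0, 4.0, math.nan], n_replicates=5)
        assert not ens2.unreliable


class TestFirstOrderNoisePropagation:
    def test_zero_noise_and_zero_slope_limits(self):
        assert eq_noise_to_position_error(0.0, -0.5) == 0.0
        assert math.isinf(eq_noise_to_position_error(0.1, 0.0))

    def test_prediction_matches_simulation_at_small_noise(self, reference_n1):
        # production noise only, CVp = 0.05, linear decay, x = 10 cells
        cfg = EnsembleConfig(kinetics=default_kinetics(cv_p=0.05, cv_d=0.0, cv_D=0.0))
        x_t = 10 * MU_DELTA
        pairs = simulate_realizations(cfg, 200, seed=6)
        c_theta = threshold_from_reference(reference_n1, x_t)
        positions = np.array([read_position(r, d, c_theta) for d, r in pairs])
        measured = float(np.std(positions[~np.isnan(positions)], ddof=1))
        # local concentration SD at the mean readout position
        mu_x = float(np.nanmean(positions))
        sigma_C = float(np.std([r.concentration(mu_x) for _, r in pairs], ddof=1))
        h = 0.5
        slope = (reference_n1.concentration(mu_x + h) - reference_n1.concentration(mu_x - h)) / (2 * h)
        predicted = eq_noise_to_position_error(sigma_C, slope)
        assert predicted == pytest.approx(measured, rel=1.0)  # within a factor of 2
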