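"""Closed-form scaling relations, the Flory minimizer and exponent fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bioscaling.scaling import (
    ChainScalingModel,
    alpha_from_rg,
    dimensionality,
    fit_scaling_exponent,
    flory_exponent,
    flory_free_energy,
    flory_minimize,
    folding_time_fit,
    globule_radius,
    ideal_chain_rg,
    ideal_end_to_end,
    prefactor_k,
    rg_from_alpha,
    sphere_rg,
    stretched_rg,
)

from conftest import TRP_A, TRP_L, TRP_N


class TestClosedForms:
    @pytest.mark.parametrize("length, expected", [
        (TRP_L, 21.25),       # extended Trp-cage
        (0.0, 0.0),
        (math.sqrt(12), 1.0),
    ])
    def test_stretched_rg(self, length, expected):
        assert stretched_rg(length) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize("n, a, expected, tol", [
        (TRP_N, TRP_A, 6.72, 0.02),   # printed as 6.73
        (6, 1.0, 1.0, 1e-12),
        (100, 2.0, 2 * math.sqrt(100 / 6), 1e-9),
    ])
    def test_ideal_chain_rg(self, n, a, expected, tol):
        assert ideal_chain_rg(n, a) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("n, a, expected", [
        (100, 1.0, 10.0),
        (TRP_N, TRP_A, TRP_A * math.sqrt(20)),
        (1, 2.5, 2.5),
    ])
    def test_ideal_end_to_end(self, n, a, expected):
        assert ideal_end_to_end(n, a) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("radius, expected", [
        (6.19, 4.80),         # compact Trp-cage sphere (inputs printed at 2 dp)
        (0.0, 0.0),
        (1.0, math.sqrt(3 / 5)),
    ])
    def test_sphere_rg_uses_about_centre_prefactor(self, radius, expected):
        assert sphere_rg(radius) == pytest.approx(expected, abs=1e-2)

    @pytest.mark.parametrize("n, v, expected", [
        (20, 49.84, 6.19),    # V = a^3 N ~ 997 A^3
        (1, 4 * math.pi / 3, 1.0),
        (160, 4 * math.pi / 3, 160 ** (1 / 3)),
    ])
    def test_globule_radius(self, n, v, expected):
        assert globule_radius(n, v) == pytest.approx(expected, abs=1e-2)

    @pytest.mark.parametrize("alpha, expected", [
        (1.0, 1 / math.sqrt(12)),
        (0.5, 1 / math.sqrt(6)),
        (0.25, 1 / math.sqrt(3)),
    ])
    def test_prefactor_anchors(self, alpha, expected):
        assert prefactor_k(alpha) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("alpha, expected, tol", [
        (0.6, 8.28, 5e-3),        # excluded-volume coil
        (1.0, 21.25, 5e-3),       # stretched anchor
        (1 / 3, 4.9952, 5e-3),    # compact globule (printed as 4.99)
    ])
    def test_rg_from_alpha_worked_examples(self, alpha, expected, tol):
        assert rg_from_alpha(alpha, TRP_N, TRP_A) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("func, args", [
        (stretched_rg, (-1.0,)),
        (ideal_chain_rg, (0, 1.0)),
        (ideal_chain_rg, (5, -1.0)),
        (ideal_end_to_end, (0, 1.0)),
        (sphere_rg, (-0.1,)),
        (globule_radius, (0, 1.0)),
        (globule_radius, (5, 0.0)),
        (prefactor_k, (0.0,)),
        (rg_from_alpha, (0.0, 20, 1.0)),
        (rg_from_alpha, (0.5, 1, 1.0)),
        (dimensionality, (0.0,)),
    ])
    def test_domain_errors(self, func, args):
        with pytest.raises(ValueError):
            func(*args)


class TestAnchorsAndModel:
    @pytest.mark.parametrize("n", [2, 5, 20, 100, 1000, 10_000])
    def test_scaling_law_meets_its_anchors(self, n):
        a = 3.8
        assert rg_from_alpha(1.0, n, a) == pytest.approx(
            stretched_rg(a * n), rel=1e-12)
        assert rg_from_alpha(0.5, n, a) == pytest.approx(
            ideal_chain_rg(n, a), rel=1e-12)

    def test_chain_model_invariants(self):
        model = ChainScalingModel.from_contour_length(TRP_N, TRP_L)
        assert model.segment_length == pytest.approx(3.6805, rel=1e-9)
        assert model.contour_length == pytest.approx(TRP_L, rel=1e-9)
        assert model.rg_stretched == pytest.approx(TRP_L / math.sqrt(12), rel=1e-12)
        assert model.excluded_volume == pytest.approx(3.6805 ** 3, rel=1e-9)
        est = model.alpha(model.rg(0.52))
        assert est.alpha == pytest.approx(0.52, abs=1e-8)

    def test_chain_model_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            ChainScalingModel(1, 1.0)
        with pytest.raises(ValueError):
            ChainScalingModel(10, -1.0)


class TestAlphaInversion:
    def test_simulated_folded_state(self):
        est = alpha_from_rg(6.97, TRP_L, TRP_N)
        assert round(est.alpha, 2) == 0.52
        assert est.flag == "ok"
        assert est.residual < 1e-9
        assert est.dimensionality * est.alpha == pytest.approx(1.0, abs=1e-12)

    def test_stretched_rg_gives_alpha_one(self):
        rg0 = TRP_L / math.sqrt(12)
        est = alpha_from_rg(rg0, TRP_L, TRP_N)
        assert est.alpha == pytest.approx(1.0, abs=1e-10)

    @settings(max_examples=60, derandomize=True)
    @given(alpha=st.floats(0.35, 1.0), n=st.sampled_from([10, 20, 50, 100]))
    def test_round_trip_recovers_alpha(self, alpha, n):
        a = 3.6805
        est = alpha_from_rg(rg_from_alpha(alpha, n, a), a * n, n)
        assert est.alpha == pytest.approx(alpha, abs=1e-8)
        assert est.residual < 1e-9

    def test_clamping_flags(self):
        # far above the stretched Rg -> high clamp; tiny Rg -> low clamp
        high = alpha_from_rg(100.0, TRP_L, TRP_N)
        assert high.flag == "clamped_high"
        assert high.alpha == 1.25
        assert high.dimensionality == 1.0
        low = alpha_from_rg(1e-3, TRP_L, TRP_N)
        assert low.flag == "clamped_low"
        assert low.alpha == pytest.approx(
            max(1 / (2 * math.log(TRP_N)) + 0.01, 0.20))

    def test_monotone_in_alpha(self):
        for n in (5, 20, 200):
            lo = 1 / (2 * math.log(n)) + 1e-6
            alphas = np.linspace(lo, 1.0, 200)
            rgs = [rg_from_alpha(al, n, 1.0) for al in alphas]
            assert np.all(np.diff(rgs) > 0)

    def test_rejects_degenerate_n(self):
        with pytest.raises(ValueError):
            alpha_from_rg(5.0, 10.0, 1)
        with pytest.raises(ValueError):
            alpha_from_rg(-1.0, 10.0, 20)

    @pytest.mark.parametrize("alpha, expected", [
        (0.52, 1.92), (1.0, 1.0), (1 / 3, 3.0),
    ])
    def test_dimensionality(self, alpha, expected):
        assert dimensionality(alpha) == pytest.approx(expected, abs=5e-3)

    def test_dimensionality_maps_globule_to_three_dimensions(self):
        alphas = np.linspace(1 / 3, 1.0, 50)
        dims = np.array([dimensionality(a) for a in alphas])
        assert dims.min() == pytest.approx(1.0)
        assert dims.max() == pytest.approx(3.0)
        assert np.all((dims >= 1.0 - 1e-12) & (dims <= 3.0 + 1e-12))


class TestFlory:
    def test_free_energy_values(self):
        assert flory_free_energy(1.0, 1, 1.0, 1.0) == pytest.approx(2.0)
        assert flory_free_energy(2.0, 1, 1.0, 1.0) == pytest.approx(4.125)

    def test_free_energy_diverges_with_extension(self):
        ls = np.geomspace(10, 1e6, 20)
        f = flory_free_energy(ls, 10, 1.0, 1.0)
        assert np.all(np.diff(f) > 0)

    def test_minimizer_matches_closed_form(self):
        res = flory_minimize(20, 49.836, 3.6805)
        assert res.analytic_l_star == pytest.approx(
            (1.5 * 20**3 * 49.836 * 3.6805**2) ** 0.2, rel=1e-12)
        assert res.l_star == pytest.approx(res.analytic_l_star, rel=1e-6)
        assert res.l_star == pytest.approx(24.08, abs=5e-3)
        assert flory_minimize(1, 1.0, 1.0).l_star == pytest.approx(
            1.5 ** 0.2, rel=1e-6)

    def test_minimizer_against_random_draws(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 5000))
            v = float(rng.uniform(0.1, 100.0))
            a = float(rng.uniform(0.5, 10.0))
            res = flory_minimize(n, v, a)
            assert abs(res.l_star - res.analytic_l_star) / res.analytic_l_star < 1e-6

    def test_minimizer_against_grid_oracle(self):
        # independent oracle: dense grid minimization of the free energy
        n, v, a = 30, 10.0, 2.0
        res = flory_minimize(n, v, a)
        grid = np.arange(0.5 * res.l_star, 1.5 * res.l_star, 1e-4)
        f = flory_free_energy(grid, n, v, a)
        assert res.l_star == pytest.approx(grid[np.argmin(f)], abs=2e-4)

    def test_flory_exponent_is_three_fifths(self):
        fit = flory_exponent([50, 100, 200, 400, 800, 1600, 3200], 3.8**3, 3.8)
        assert fit.slope == pytest.approx(0.6, abs=1e-6)
        assert fit.n_points == 7

    def test_flory_exponent_invariant_to_prefactor_rescaling(self):
        ns = [50, 100, 200, 400, 800]
        s1 = flory_exponent(ns, 1.0, 1.0).slope
        s2 = flory_exponent(ns, 55.0, 7.0).slope
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            flory_free_energy(-1.0, 1, 1.0, 1.0)
        with pytest.raises(ValueError):
            flory_minimize(0, 1.0, 1.0)
        with pytest.raises(ValueError):
            flory_exponent([10, 20], 1.0, 1.0)


class TestExponentFits:
    def test_exact_power_law_recovery(self):
        ns = np.unique(np.geomspace(10, 1000, 12).astype(int))
        pairs = [(n, 0.7 * n**0.7) for n in ns]
        fit = fit_scaling_exponent(pairs)
        assert fit.slope == pytest.approx(0.7, abs=1e-6)
        assert fit.stderr_slope == pytest.approx(0.0, abs=1e-6)
        assert math.exp(fit.intercept) == pytest.approx(0.7, rel=1e-6)

    def test_discrete_stretched_chain_slope_tends_to_one(self):
        # discrete rod: Rg = a sqrt(N(N+2)/12); slope -> 1 with growing N
        ns = np.arange(100, 1001, 100)
        pairs = [(n, math.sqrt(n * (n + 2) / 12)) for n in ns]
        fit = fit_scaling_exponent(pairs)
        assert 0.99 < fit.slope < 1.0

    def test_rejects_degenerate_tables(self):
        with pytest.raises(ValueError):
            fit_scaling_exponent([(10, 1.0), (20, 2.0)])
        with pytest.raises(ValueError):
            fit_scaling_exponent([(10, 1.0), (10, 2.0), (30, 3.0)])
        with pytest.raises(ValueError):
            fit_scaling_exponent([(10, -1.0), (20, 2.0), (30, 3.0)])

    def test_folding_time_fit(self, rng):
        ns = [20, 40, 80, 160, 320]
        exact = folding_time_fit(ns, [2.0 * math.sqrt(n) for n in ns])
        assert exact.slope == pytest.approx(2.0, abs=1e-12)
        assert exact.intercept == pytest.approx(0.0, abs=1e-10)

        noisy = [1.5 * math.sqrt(n) + 3 + rng.normal(0, 0.01) for n in ns]
        fit = folding_time_fit(ns, noisy)
        assert fit.slope == pytest.approx(1.5, abs=0.05)

    def test_folding_time_fit_errors(self):
        with pytest.raises(ValueError):
            folding_time_fit([10], [1.0])
        with pytest.raises(ValueError):
            folding_time_fit([10, 20], [1.0])
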