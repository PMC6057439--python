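"""Simulated-annealing mixture fitting: components, amplitudes, annealer."""

import numpy as np
import pytest

from tendonmech import mixture as mx
from tendonmech.errors import (
    ConfigurationError,
    DegenerateFitError,
    DomainError,
)
from tendonmech.fibrils import build_histogram
from tendonmech.io import FibrilHistogram
from tendonmech.simulate import MixtureParams, simulate_diameters


def two_component_histogram(seed=1):
    d, _ = simulate_diameters(MixtureParams(seed=seed))
    return build_histogram(d, bin_width=20.0)


class TestGaussianComponent:
    def test_unit_amplitude_at_the_mean(self):
        assert mx.gaussian_component(100.0, 100.0, 30.0) == 1.0

    def test_one_sigma_value(self):
        assert mx.gaussian_component(130.0, 100.0, 30.0) == (
            pytest.approx(np.exp(-0.5)))

    def test_integral_matches_quadrature_oracle(self):
        x = np.linspace(-400, 600, 20001)
        got = np.trapezoid(mx.gaussian_component(x, 100.0, 30.0), x)
        assert got == pytest.approx(30.0 * np.sqrt(2 * np.pi), rel=1e-3)

    def test_non_positive_sigma(self):
        with pytest.raises(DomainError):
            mx.gaussian_component(0.0, 0.0, 0.0)


class TestSolveAmplitudes:
    def test_exact_representation_recovered(self):
        x = np.arange(10.0, 400.0, 20.0)
        G = np.column_stack([mx.gaussian_component(x, 100, 30),
                             mx.gaussian_component(x, 250, 50)])
        y = G @ np.array([0.7, 0.3])
        amp = mx.solve_amplitudes(y, G)
        np.testing.assert_allclose(amp, [0.7, 0.3], atol=1e-8)

    def test_all_zero_histogram(self):
        x = np.arange(10.0, 400.0, 20.0)
        G = np.column_stack([mx.gaussian_component(x, 100, 30),
                             mx.gaussian_component(x, 250, 50)])
        np.testing.assert_array_equal(
            mx.solve_amplitudes(np.zeros(len(x)), G), [0.0, 0.0])

    def test_identical_components_degenerate(self):
        x = np.arange(10.0, 400.0, 20.0)
        g = mx.gaussian_component(x, 100, 30)
        with pytest.raises(DegenerateFitError):
            mx.solve_amplitudes(g, np.column_stack([g, g]))

    def test_nnls_beats_sign_constrained_grid_oracle(self, rng):
        x = np.arange(10.0, 400.0, 20.0)
        G = np.column_stack([mx.gaussian_component(x, 120, 40),
                             mx.gaussian_component(x, 260, 60)])
        for _ in range(5):
            y = np.abs(rng.normal(0.05, 0.05, len(x)))
            amp = mx.solve_amplitudes(y, G)
            best = min(float(np.sum((y - G @ np.array([a, b])) ** 2))
                       for a in np.linspace(0, 1, 21)
                       for b in np.linspace(0, 1, 21))
            assert float(np.sum((y - G @ amp) ** 2)) <= best + 1e-12


class TestMetropolis:
    def test_improvements_always_accepted(self, rng):
        assert all(mx.metropolis_accept(-1.0, T, rng)
                   for T in (1e-9, 0.5, 100.0))

    def test_acceptance_frequency_matches_boltzmann(self):
        """At delta = 0.5, T = 0.5 the empirical acceptance over 1e4 draws
        equals exp(-1) within 3 sigma binomial."""
        rng = np.random.default_rng(0)
        n = 10_000
        hits = sum(mx.metropolis_accept(0.5, 0.5, rng) for _ in range(n))
        p = np.exp(-1.0)
        assert abs(hits / n - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_freezing_limit_rejects(self, rng):
        assert not any(mx.metropolis_accept(10.0, 1e-9, rng)
                       for _ in range(100))


class TestSAFit:
    def test_recovers_bimodal_means(self):
        hist = two_component_histogram(seed=1)
        cfg = mx.SAConfig.from_histogram(hist, seed=1)
        fit = mx.sa_fit(hist, cfg)
        assert abs(fit.mu[0] - 100.0) <= 10.0
        assert abs(fit.mu[1] - 250.0) <= 15.0

    def test_components_sorted_and_amplitudes_nonneg(self):
        hist = two_component_histogram(seed=2)
        fit = mx.sa_fit(hist, mx.SAConfig.from_histogram(hist, seed=2))
        assert fit.mu[0] < fit.mu[1]
        assert all(a >= 0 for a in fit.amplitude)

    def test_best_objective_trace_non_increasing(self):
        hist = two_component_histogram(seed=3)
        fit = mx.sa_fit(hist, mx.SAConfig.from_histogram(hist, seed=3))
        assert all(b <= a + 1e-15 for a, b in zip(fit.trace, fit.trace[1:]))

    def test_pure_function_of_inputs(self):
        hist = two_component_histogram(seed=4)
        cfg = mx.SAConfig.from_histogram(hist, seed=4)
        a, b = mx.sa_fit(hist, cfg), mx.sa_fit(hist, cfg)
        assert a.mu == b.mu and a.objective == b.objective

    def test_two_components_nest_a_single_gaussian(self, rng):
        """On a pure single-Gaussian histogram the two-component composite
        fits at least as well as the best single component."""
        d = rng.normal(150, 35, 3000)
        hist = build_histogram(d[d > 0], bin_width=20.0)
        two = mx.fit_subpopulations(hist, seed=0)
        one = mx.fit_subpopulations(hist, seed=0, ngauss=1)
        assert two.objective <= one.objective + 1e-10

    def test_greedy_descent_in_the_cold_limit(self):
        """With a vanishing initial temperature the accepted-state sequence
        can only improve, so the fit equals best-ever bookkeeping."""
        hist = two_component_histogram(seed=5)
        cfg = mx.SAConfig.from_histogram(hist, seed=5, temperature=1e-12,
                                         ntrials=20)
        fit = mx.sa_fit(hist, cfg)
        assert all(b <= a + 1e-15 for a, b in zip(fit.trace, fit.trace[1:]))

    def test_infeasible_proposal_ranges_rejected(self):
        hist = two_component_histogram(seed=1)
        with pytest.raises(ConfigurationError):
            mx.SAConfig.from_histogram(hist, mua=(5000.0, 6000.0),
                                       mub=(10.0, 10.0))


class TestRefineFit:
    def test_refinement_never_worsens_objective(self):
        hist = two_component_histogram(seed=6)
        cfg = mx.SAConfig.from_histogram(hist, seed=6)
        first = mx.sa_fit(hist, cfg)
        refined = mx.refine_fit(first, hist, cfg)
        assert refined.objective <= first.objective

    def test_refined_means_tighter_on_recovery_fixture(self):
        hist = two_component_histogram(seed=1)
        cfg = mx.SAConfig.from_histogram(hist, seed=1)
        refined = mx.refine_fit(mx.sa_fit(hist, cfg), hist, cfg)
        assert abs(refined.mu[0] - 100.0) <= 5.0
        assert abs(refined.mu[1] - 250.0) <= 7.5

    def test_shrink_one_is_an_independent_second_run(self):
        hist = two_component_histogram(seed=7)
        cfg = mx.SAConfig.from_histogram(hist, seed=7)
        first = mx.sa_fit(hist, cfg)
        again = mx.refine_fit(first, hist, cfg, shrink=1.0)
        # same search ranges, fresh seed: objective comparable, not worse
        assert again.objective <= first.objective
        assert abs(again.mu[0] - first.mu[0]) < 25.0


class TestConfigFile:
    def test_round_trip(self, tmp_path):
        hist = two_component_histogram(seed=1)
        cfg = mx.SAConfig.from_histogram(hist, seed=9)
        path = tmp_path / "fibrilprogram_1M_v5.txt"
        mx.write_sa_config(cfg, path)
        back = mx.read_sa_config(path)
        assert back == cfg
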