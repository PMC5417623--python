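"""Tests for the two-barrier hazard/renewal theory."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize_scalar

from phasic.barrier_theory import (BarrierModelSpec, GridSpec, ISIDensity,
                                   auto_grid, exit_kernels,
                                   firing_rate_from_density, hazard,
                                   isi_density_endogenous,
                                   isi_density_exogenous, isi_family,
                                   moving_barrier,
                                   phase_density_fixed_point, phase_kernel,
                                   theory_metrics)


@pytest.fixture(scope="module")
def phasic_spec():
    return BarrierModelSpec(D=1.0, variant="phasic")


def series_solution(J_L, J_R, dt, n_terms):
    """Independent oracle: direct summation of the convolution series.

    Convolutions use trapezoidal quadrature; partial sums are (up to the
    quadrature error) lower bounds of f because every term is nonnegative.
    """
    f = J_R.copy()
    term = J_R.copy()
    n = J_R.size
    for _ in range(n_terms):
        term = np.convolve(J_L, term)[:n] * dt \
            - 0.5 * dt * (J_L[0] * term + J_L[:n] * term[0])
        f += term
    return f, term


class TestHazard:
    def test_zero_barrier_gives_prefactor(self, phasic_spec):
        assert hazard(0.0, 1.0, phasic_spec) == pytest.approx(5.0)

    def test_printed_form_at_unit_noise(self, phasic_spec):
        # 5 exp(-3 * 1.5^1.5) evaluated independently
        expected = 5.0 * np.exp(-3.0 * 1.5 ** 1.5)
        assert hazard(1.5, 1.0, phasic_spec) == pytest.approx(expected,
                                                              rel=1e-12)
        assert expected == pytest.approx(0.0202, abs=1e-4)

    def test_vanishes_monotonically_for_large_barriers(self, phasic_spec):
        dU = np.linspace(0.0, 50.0, 500)
        h = hazard(dU, 1.0, phasic_spec)
        assert np.all(np.diff(h) <= 0) and h[-1] < 1e-30

    def test_negative_barrier_signals_collapse(self, phasic_spec):
        with pytest.raises(ValueError, match="collapsed"):
            hazard(-0.01, 1.0, phasic_spec)

    @given(st.floats(0.01, 5.0), st.floats(0.01, 5.0),
           st.floats(0.0, 3.0))
    def test_monotone_in_noise_and_bounded(self, D1, D2, dU):
        spec = BarrierModelSpec(D=1.0)
        lo, hi = sorted([D1, D2])
        assert hazard(dU, lo, spec) <= hazard(dU, hi, spec) <= spec.gamma


class TestMovingBarrier:
    def test_initial_height(self, phasic_spec):
        # direct evaluation of the printed formula at t = 0
        expected = 1.5 - 1.4 * np.sin(0.8 * np.pi * 0.15) / np.exp(0.8 * 0.25)
        assert moving_barrier(0.0, phasic_spec) == pytest.approx(expected)
        assert expected == pytest.approx(1.0780471508555698)

    def test_relaxes_to_asymptote(self, phasic_spec):
        assert moving_barrier(30.0, phasic_spec) == pytest.approx(1.5,
                                                                  abs=1e-6)

    def test_global_minimum_against_minimizer_oracle(self, phasic_spec):
        t_grid = np.linspace(0.0, 20.0, 200_001)
        coarse = moving_barrier(t_grid, phasic_spec)
        t0 = t_grid[np.argmin(coarse)]
        res = minimize_scalar(lambda t: moving_barrier(t, phasic_spec),
                              bounds=(t0 - 1e-3, t0 + 1e-3),
                              method="bounded", options={"xatol": 1e-10})
        assert res.fun <= coarse.min() + 1e-12
        assert moving_barrier(res.x, phasic_spec) == pytest.approx(res.fun)
        # the dip transiently lowers the spike barrier well below v_R
        assert res.fun == pytest.approx(0.67609, abs=1e-4)
        assert res.x == pytest.approx(0.35238, abs=1e-4)

    def test_classic_variant_is_constant(self):
        spec = BarrierModelSpec(D=1.0, variant="classic")
        t = np.linspace(0.0, 10.0, 101)
        assert np.all(moving_barrier(t, spec) == spec.v_R)


class TestExitKernels:
    def test_classic_constant_hazard_closed_form(self):
        spec = BarrierModelSpec(D=1.0, variant="classic")
        grid = GridSpec(t_max=300.0, n_t=2 ** 14)
        J_L, J_R = exit_kernels(spec, grid)
        H = hazard(spec.v_R, spec.D, spec)
        assert np.all(J_L == 0.0)
        assert np.allclose(J_R, H * np.exp(-H * grid.t), rtol=1e-10)

    def test_total_exit_probability_one(self, phasic_spec):
        grid = auto_grid(phasic_spec)
        J_L, J_R = exit_kernels(phasic_spec, grid)
        total = np.trapezoid(J_L + J_R, dx=grid.dt)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_pointwise_ratio_equals_hazard_ratio(self, phasic_spec):
        grid = GridSpec(t_max=50.0, n_t=2 ** 12)
        J_L, J_R = exit_kernels(phasic_spec, grid)
        H_R = hazard(moving_barrier(grid.t, phasic_spec), phasic_spec.D,
                     phasic_spec)
        H_L = hazard(phasic_spec.dU_L, phasic_spec.D, phasic_spec)
        np.testing.assert_allclose(J_L / J_R, H_L / H_R, rtol=1e-12)

    def test_collapsed_barrier_signals(self):
        spec = BarrierModelSpec(D=1.0, variant="classic", A=2.0, phi=0.1)
        with pytest.raises(ValueError, match="collapsed"):
            exit_kernels(spec, GridSpec(t_max=50.0, n_t=2 ** 12))


class TestRenewalSolver:
    def test_constant_right_barrier_reduction(self, rng):
        # with a constant right barrier, left crossings are invisible:
        # f(t) = H_R exp(-H_R t) exactly, for any left hazard
        for _ in range(5):
            v_R = rng.uniform(0.3, 1.5)
            dU_L = rng.uniform(0.3, 1.5)
            spec = BarrierModelSpec(D=1.0, variant="phasic", mb_amp=0.0,
                                    v_R=v_R, dU_L=dU_L)
            H_R = hazard(v_R, 1.0, spec)
            grid = GridSpec(t_max=30.0 / H_R, n_t=2 ** 17)
            f = isi_density_endogenous(spec, grid)
            exact = H_R * np.exp(-H_R * grid.t)
            mask = exact >= 1e-8 * H_R
            rel = np.abs(f.f[mask] - exact[mask]) / exact[mask]
            assert rel.max() < 1e-6

    def test_series_oracle_matches_fft_solution(self, phasic_spec):
        grid = auto_grid(phasic_spec)
        J_L, J_R = exit_kernels(phasic_spec, grid)
        f = isi_density_endogenous(phasic_spec, grid).f
        f8, term8 = series_solution(J_L, J_R, grid.dt, 8)
        tail_mass = np.trapezoid(term8, dx=grid.dt)
        # the partial sum is a lower bound, accurate to the truncated mass
        assert np.all(f >= f8 - 1e-5 * f.max())
        assert np.max(np.abs(f - f8)) / f.max() < tail_mass

    def test_normalized_for_phasic_at_unit_noise(self, phasic_spec):
        f = isi_density_endogenous(phasic_spec, auto_grid(phasic_spec))
        assert f.norm_defect < 1e-3

    def test_truncated_domain_detected(self, phasic_spec):
        # a domain much shorter than the mean ISI wraps circularly, which
        # must be caught by the tail check
        with pytest.raises(RuntimeError):
            isi_density_endogenous(
                phasic_spec.with_(D=0.5), GridSpec(t_max=300.0, n_t=2 ** 14))


class TestFiringRateFromDensity:
    def _density(self, t, f):
        return ISIDensity(t=t, f=f,
                          norm_defect=abs(1 - np.trapezoid(f, t)))

    def test_exponential(self):
        t = np.linspace(0.0, 200.0, 2 ** 16)
        lam = 0.25
        nu = firing_rate_from_density(
            self._density(t, lam * np.exp(-lam * t)))
        assert nu == pytest.approx(lam, rel=1e-4)

    def test_narrow_peak(self):
        t = np.linspace(0.0, 20.0, 2 ** 16)
        f = np.exp(-0.5 * ((t - 5.0) / 0.01) ** 2)
        f /= np.trapezoid(f, t)
        assert firing_rate_from_density(self._density(t, f)) == \
            pytest.approx(0.2, rel=1e-6)

    def test_mixture_of_exponentials_closed_form(self):
        t = np.linspace(0.0, 400.0, 2 ** 18)
        l1, l2 = 0.2, 1.3
        f = 0.5 * l1 * np.exp(-l1 * t) + 0.5 * l2 * np.exp(-l2 * t)
        expected = 1.0 / (0.5 * (1 / l1 + 1 / l2))
        assert firing_rate_from_density(self._density(t, f)) == \
            pytest.approx(expected, rel=1e-4)

    def test_unnormalized_density_rejected(self):
        t = np.linspace(0.0, 10.0, 1000)
        with pytest.raises(ValueError):
            firing_rate_from_density(self._density(t, np.exp(-t) * 0.5))


@pytest.fixture(scope="module")
def driven_spec():
    return BarrierModelSpec(D=1.0, variant="phasic", A=0.1, phi=0.1)


@pytest.fixture(scope="module")
def driven_grid(driven_spec):
    return auto_grid(driven_spec)


class TestPhaseMachinery:
    def test_columns_integrate_to_one(self, driven_spec, driven_grid):
        g = phase_kernel(driven_spec, driven_grid)
        dpsi = driven_spec.period / driven_grid.n_psi
        np.testing.assert_allclose(g.sum(axis=0) * dpsi, 1.0, rtol=1e-12)

    def test_shift_invariance_without_signal(self, driven_grid):
        spec = BarrierModelSpec(D=1.0, variant="phasic", A=0.0, phi=0.1)
        grid = auto_grid(spec)
        g = phase_kernel(spec, grid)
        for j in (1, grid.n_psi // 2):
            np.testing.assert_allclose(g[:, j], np.roll(g[:, 0], j),
                                       atol=1e-10 * g.max())

    def test_doubling_k_max_converged(self, driven_spec, driven_grid):
        fam = isi_family(driven_spec, driven_grid)
        k0 = int(np.ceil(driven_grid.t_max / driven_spec.period)) + 1
        g1 = phase_kernel(driven_spec, driven_grid, fam=fam, k_max=k0)
        g2 = phase_kernel(driven_spec, driven_grid, fam=fam, k_max=2 * k0)
        assert np.max(np.abs(g1 - g2)) < 1e-12

    def test_insufficient_k_max_signals(self, driven_spec, driven_grid):
        with pytest.raises(RuntimeError, match="k_max"):
            phase_kernel(driven_spec, driven_grid, k_max=1)

    def test_fixed_point_uniform_without_signal(self):
        # a shift-invariant kernel fixes the uniform density
        spec = BarrierModelSpec(D=1.0, variant="phasic", A=0.0, phi=0.1)
        grid = auto_grid(spec)
        g = phase_kernel(spec, grid)
        p = phase_density_fixed_point(g, spec, grid)
        assert np.allclose(p.p, spec.phi, rtol=1e-8)

    def test_fixed_point_residual_and_normalization(self, driven_spec,
                                                    driven_grid):
        g = phase_kernel(driven_spec, driven_grid)
        p = phase_density_fixed_point(g, driven_spec, driven_grid)
        dpsi = p.dpsi
        assert np.sum(p.p) * dpsi == pytest.approx(1.0, abs=1e-10)
        again = g @ p.p * dpsi
        assert np.sum(np.abs(again - p.p)) * dpsi < 1e-10
        assert np.all(p.p >= 0)

    def test_exogenous_equals_endogenous_without_signal(self):
        spec = BarrierModelSpec(D=1.0, variant="phasic", A=0.0, phi=0.1)
        grid = auto_grid(spec)
        fam = isi_family(spec, grid)
        g = phase_kernel(spec, grid, fam=fam)
        p = phase_density_fixed_point(g, spec, grid)
        f_exo = isi_density_exogenous(fam, p, grid)
        f_endo = isi_density_endogenous(spec, grid)
        assert np.max(np.abs(f_exo.f - f_endo.f)) < 1e-10 * f_endo.f.max()
        assert f_exo.norm_defect < 1e-3


class TestTheoryMetrics:
    def test_classic_rate_approaches_closed_form_as_signal_vanishes(self):
        for D in (1.0, 2.0):
            spec = BarrierModelSpec(D=D, variant="classic", A=1e-4,
                                    phi=0.1)
            nu, r, q = theory_metrics(spec)
            expected = 5.0 * np.exp(-3.0 * 1.5 ** 1.5 / D)
            assert nu == pytest.approx(expected, rel=1e-3)
            assert r < 0.02

    def test_rate_monotone_in_noise_all_variants(self):
        for variant in ("phasic", "right_moving", "classic"):
            nus = []
            for D in (1.0, 1.5, 2.0, 3.0):
                spec = BarrierModelSpec(D=D, variant=variant, A=0.1,
                                        phi=0.1)
                nus.append(theory_metrics(spec)[0])
            assert all(a < b for a, b in zip(nus, nus[1:])), (variant, nus)
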