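"""Exchange-matrix structure, conservation laws and propagation."""

import numpy as np
import pytest
from scipy import linalg

from bicellesim.exchange import (ExchangeSystem, discrete_rim_grid,
                                 jump_rates, propagate)
from bicellesim.surfaces import OrientationGrid, RimGeometry, build_grid


def uniform_chain(n, spacing=1.0, n_phi=1):
    return OrientationGrid(
        positions=np.arange(n, dtype=float) * spacing,
        normal_angles=np.zeros(n), h_par=np.ones(n), h_azi=np.ones(n),
        spacing=spacing, n_theta=n, n_phi=n_phi,
        phi_deg=np.arange(n_phi) * 360.0 / n_phi, geometry_tag="chain")


def random_system(rng, n=20, rate_scale=1e3, spread=1e4):
    grid = uniform_chain(n)
    grid.h_azi = rng.uniform(0.5, 2.0, n)
    freqs = rng.uniform(-spread, spread, n)
    return ExchangeSystem(grid=grid, frequencies=freqs,
                          d_ld=rate_scale * rng.uniform(0.1, 1.0))


class TestJumpRates:
    def test_zero_diffusion(self):
        ku, kd, kp = jump_rates(uniform_chain(5), 0.0)
        assert not ku.any() and not kd.any() and not kp.any()

    def test_uniform_chain_finite_difference(self):
        ds = 0.25
        ku, kd, _ = jump_rates(uniform_chain(6, spacing=ds), 2.0)
        np.testing.assert_allclose(ku[:-1], 2.0 / ds**2)
        np.testing.assert_allclose(kd[1:], 2.0 / ds**2)
        assert ku[-1] == 0.0 and kd[0] == 0.0

    def test_circular_rim_profile_symmetric_about_equator(self):
        grid = build_grid(RimGeometry(2.0, 2.0, 10.0), 40)
        ku, kd, _ = jump_rates(grid, 1.0)
        # jumping up from site j mirrors jumping down from site n-1-j
        np.testing.assert_allclose(ku[:-1], kd[1:][::-1], rtol=1e-12)

    def test_proportional_to_diffusion_coefficient(self):
        grid = build_grid(RimGeometry(2.0, 1.6, 10.0), 10)
        k1 = jump_rates(grid, 1.0)
        k7 = jump_rates(grid, 7.0)
        for a, b in zip(k1, k7):
            np.testing.assert_allclose(7.0 * a, b, rtol=1e-12)

    def test_zero_metric_factor_reported(self):
        grid = uniform_chain(4)
        grid.h_azi = np.array([1.0, 0.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="site 1"):
            jump_rates(grid, 1.0)


class TestAssemble1d:
    def test_two_site_structure(self):
        grid = uniform_chain(2)
        sys_ = ExchangeSystem(grid=grid, frequencies=[100.0, -100.0],
                              d_ld=1.0)
        k = 1.0  # D/ds^2
        expect = np.array([[2j * np.pi * 100 - k, k],
                           [k, -2j * np.pi * 100 - k]])
        np.testing.assert_allclose(sys_.L, expect, atol=1e-12)

    def test_rate_part_columns_sum_to_zero(self, rng):
        sys_ = random_system(rng)
        col = sys_.L.real.sum(axis=0)
        assert np.abs(col).max() < 1e-9 * np.abs(sys_.L.real).max()

    def test_equilibrium_is_stationary(self, rng):
        sys_ = random_system(rng)
        w = sys_.grid.weights
        resid = sys_.L.real @ (w / w.sum())
        assert np.abs(resid).max() < 1e-9 * np.abs(sys_.L.real).max()

    def test_eigenvalue_real_parts_nonpositive(self, rng):
        for _ in range(5):
            sys_ = random_system(rng)
            lam = np.linalg.eigvals(sys_.L)
            assert lam.real.max() < 1e-6

    def test_zero_diffusion_diagonal(self):
        grid = build_grid(RimGeometry(2.0, 1.8, 10.0), 8)
        sys_ = ExchangeSystem(grid=grid, frequencies=np.arange(8.0),
                              d_ld=0.0)
        off = sys_.L - np.diag(np.diag(sys_.L))
        assert np.abs(off).max() == 0.0

    def test_t2_on_diagonal(self):
        grid = uniform_chain(3)
        sys_ = ExchangeSystem(grid=grid, frequencies=np.zeros(3), d_ld=0.0,
                              t2_inv=50.0)
        np.testing.assert_allclose(np.diag(sys_.L), -50.0)


class TestAssemble2d:
    def test_single_phi_block_reduces_to_1d(self):
        grid = build_grid(RimGeometry(2.0, 1.8, 10.0), 6, 1,
                          mode="n_perpendicular_B")
        freqs = np.arange(6.0)
        a = ExchangeSystem(grid=grid, frequencies=freqs, d_ld=2.0)
        grid1 = build_grid(RimGeometry(2.0, 1.8, 10.0), 6, 1)
        b = ExchangeSystem(grid=grid1, frequencies=freqs, d_ld=2.0)
        np.testing.assert_allclose(a.L, b.L, atol=1e-12)

    def test_2x2_hand_constructed_layout(self):
        grid = uniform_chain(2, n_phi=2)
        freqs = np.array([10.0, 20.0, 30.0, 40.0])
        sys_ = ExchangeSystem(grid=grid, frequencies=freqs, d_ld=1.0)
        kth = 1.0
        kph = 1.0 / (2 * np.pi / 2) ** 2  # D/(h_azi*dphi)^2
        # wrap means two paths between the two phi blocks
        rate = np.array([
            [-kth - 2 * kph, kth, 2 * kph, 0],
            [kth, -kth - 2 * kph, 0, 2 * kph],
            [2 * kph, 0, -kth - 2 * kph, kth],
            [0, 2 * kph, kth, -kth - 2 * kph],
        ])
        np.testing.assert_allclose(sys_.L.real, rate, atol=1e-12)
        np.testing.assert_allclose(np.imag(np.diag(sys_.L)),
                                   2 * np.pi * freqs)

    def test_columns_sum_to_zero_with_wrap(self):
        grid = build_grid(RimGeometry(2.0, 1.7, 12.0), 5, 4,
                          mode="n_perpendicular_B")
        sys_ = ExchangeSystem(grid=grid, frequencies=np.zeros(20), d_ld=3.0)
        col = sys_.L.real.sum(axis=0)
        assert np.abs(col).max() < 1e-9 * np.abs(sys_.L.real).max()

    def test_site_cap(self):
        grid = build_grid(RimGeometry(2.0, 1.8, 10.0), 10, 4,
                          mode="n_perpendicular_B")
        with pytest.raises(MemoryError, match="cap"):
            ExchangeSystem(grid=grid, frequencies=np.zeros(40), d_ld=1.0,
                           max_sites=30)


class TestPropagate:
    def test_single_site_closed_form(self):
        grid = build_grid(__import__("bicellesim").FlatDisc(), 1, 1)
        sys_ = ExchangeSystem(grid=grid, frequencies=[500.0], d_ld=0.0,
                              t2_inv=80.0)
        dwell, n = 1e-4, 64
        fid = sys_.propagate(dwell, n)
        t = np.arange(n) * dwell
        np.testing.assert_allclose(
            fid, np.exp((2j * np.pi * 500.0 - 80.0) * t), rtol=1e-10)

    def test_fid_starts_at_total_population(self, rng):
        sys_ = random_system(rng)
        fid = sys_.propagate(1e-5, 8)
        assert fid[0] == pytest.approx(1.0)

    def test_envelope_decays_with_t2(self):
        grid = uniform_chain(4)
        sys_ = ExchangeSystem(grid=grid,
                              frequencies=[0.0, 1e3, -2e3, 3e3],
                              d_ld=10.0, t2_inv=200.0)
        fid = sys_.propagate(5e-5, 200)
        assert np.all(np.abs(fid[1:]) <= np.abs(fid[0]) + 1e-12)

    def test_eigen_vs_expm_stepping(self, rng):
        sys_ = random_system(rng, n=20)
        dwell, n = 2e-5, 40
        fid_eig = sys_.propagate(dwell, n)
        prop = linalg.expm(sys_.L * dwell)
        m = sys_.meq.astype(complex)
        fid_expm = np.empty(n, dtype=complex)
        for i in range(n):
            fid_expm[i] = m.sum()
            m = prop @ m
        np.testing.assert_allclose(fid_eig, fid_expm, rtol=1e-8, atol=1e-10)

    def test_two_site_bloch_mcconnell_closed_form(self):
        # symmetric two-site exchange: s(t) = exp((i w_avg - k) t)
        # [cosh(Omega t) + (k/Omega) sinh(Omega t)], Omega^2 = k^2 - (dw/2)^2
        nu = 1000.0
        for k in (100.0, np.pi * 2 * nu / np.sqrt(2), 5e4):
            grid = uniform_chain(2)
            sys_ = ExchangeSystem(grid=grid, frequencies=[nu, -nu],
                                  d_ld=k)  # ds=1 so rate = k
            dwell, n = 2e-5, 256
            fid = sys_.propagate(dwell, n)
            t = np.arange(n) * dwell
            dw = 2 * np.pi * (2 * nu)
            om = np.sqrt(complex(k**2 - (dw / 2) ** 2))
            ref = np.exp(-k * t) * (np.cosh(om * t)
                                    + (k / om) * np.sinh(om * t))
            np.testing.assert_allclose(fid, ref, rtol=1e-6, atol=1e-9)

    def test_bad_dwell(self):
        grid = uniform_chain(2)
        sys_ = ExchangeSystem(grid=grid, frequencies=[0.0, 0.0], d_ld=0.0)
        with pytest.raises(ValueError):
            sys_.propagate(0.0, 16)


class TestDiscreteRimGrid:
    def test_ring_tilts_and_spacing(self):
        alphas = [0.0, 30.0, 90.0, 150.0, 180.0]
        x = [20.0, 21.0, 22.0, 21.0, 20.0]
        grid = discrete_rim_grid(alphas, x, 2.0, 1.8)
        assert grid.normal_angles[0] == pytest.approx(0.0)
        assert grid.normal_angles[2] == pytest.approx(90.0)
        assert grid.normal_angles[-1] == pytest.approx(180.0)
        assert grid.scale_m == 1e-9

    def test_absolute_rates_scale(self):
        alphas = [0.0, 90.0, 180.0]
        x = [20.0, 22.0, 20.0]
        grid = discrete_rim_grid(alphas, x, 2.0, 2.0)
        ku, _, _ = jump_rates(grid, 1e-12)
        # ds ~ pi nm for the half circle; expect D/ds^2 within a factor of
        # the ring-radius correction
        ds = grid.spacing * 1e-9
        assert ku[0] == pytest.approx(1e-12 / ds**2, rel=0.15)
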