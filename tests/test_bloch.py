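"""Two-pool Bloch-McConnell simulator against independent oracles."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from darkphos import bloch, thermo
from darkphos.bloch import SaturationScheme, SpinSystemParams, ZSpectrum


def rhs_oracle(sys, sat_offset, nutation):
    """Bloch-McConnell equations written out term by term (no matrix reuse)."""
    dA = 2 * np.pi * (sys.offsetA - sat_offset)
    dB = 2 * np.pi * (sys.offsetB - sat_offset)
    w1 = 2 * np.pi * nutation
    meqA, meqB = 1.0 - sys.pB, sys.pB

    def f(t, m):
        mxA, myA, mzA, mxB, myB, mzB = m
        return [
            -sys.R2A * mxA + dA * myA - sys.kf * mxA + sys.kb * mxB,
            -dA * mxA - sys.R2A * myA + w1 * mzA - sys.kf * myA + sys.kb * myB,
            -w1 * myA - sys.R1A * (mzA - meqA) - sys.kf * mzA + sys.kb * mzB,
            -sys.R2B * mxB + dB * myB + sys.kf * mxA - sys.kb * mxB,
            -dB * mxB - sys.R2B * myB + w1 * mzB + sys.kf * myA - sys.kb * myB,
            -w1 * myB - sys.R1B * (mzB - meqB) + sys.kf * mzA - sys.kb * mzB,
        ]

    return f


def random_system(rng):
    pB = rng.uniform(1e-4, 0.3)
    kf = rng.uniform(0.0, 500.0)
    return SpinSystemParams(
        R1A=rng.uniform(0.05, 2.0), R2A=rng.uniform(0.05, 5.0),
        R1B=rng.uniform(0.05, 2.0), R2B=rng.uniform(1.0, 100.0),
        pB=pB, kf=kf, kb=kf * (1 - pB) / pB,
        offsetA=rng.uniform(-1000.0, 1000.0), offsetB=rng.uniform(-1000.0, 1000.0),
    )


class TestGenerator:
    def test_no_rf_no_exchange_blocks_decouple(self):
        sys = SpinSystemParams(R1A=1.0, R2A=2.0, R1B=1.0, R2B=50.0,
                               pB=0.0, kf=0.0, kb=0.0)
        L = bloch.build_generator(sys, sat_offset=100.0, nutation=0.0)
        # Mz rows couple only to Mz and the augmentation column
        for zi in (2, 5):
            row = L[zi].copy()
            row[[2, 5, 6]] = 0.0
            assert np.all(row == 0.0)

    def test_no_exchange_zero_coupling_entries(self):
        sys = SpinSystemParams(R1A=1.0, R2A=2.0, R1B=1.0, R2B=50.0,
                               pB=0.0, kf=0.0, kb=0.0)
        L = bloch.build_generator(sys, 0.0, 150.0)
        assert np.all(L[:3, 3:6] == 0.0)
        assert np.all(L[3:6, :3] == 0.0)

    def test_exchange_flux_conserved_pairwise(self):
        rng = np.random.default_rng(0)
        sys = random_system(rng)
        L = bloch.build_generator(sys, 123.0, 45.0)
        L0 = bloch.build_generator(dataclasses.replace(sys, kf=0.0, kb=0.0,
                                                       pB=sys.pB), 123.0, 45.0)
        X = L - L0  # pure exchange part
        for i in range(3):
            assert X[i, i] == pytest.approx(-sys.kf)
            assert X[i + 3, i] == pytest.approx(sys.kf)
            assert X[i, i + 3] == pytest.approx(sys.kb)
            assert X[i + 3, i + 3] == pytest.approx(-sys.kb)
            # columns of the exchange part sum to zero: flux conservation
            assert np.sum(X[:, i]) == pytest.approx(0.0, abs=1e-12)
            assert np.sum(X[:, i + 3]) == pytest.approx(0.0, abs=1e-12)


class TestPropagate:
    def test_t0_is_identity(self):
        sys = random_system(np.random.default_rng(1))
        m0 = bloch.equilibrium_state(sys)
        np.testing.assert_array_equal(bloch.propagate(sys, 0.0, 150.0, 0.0, m0), m0)

    def test_closed_form_monoexponential_recovery(self):
        sys = SpinSystemParams(R1A=0.7, R2A=1.0, R1B=0.7, R2B=10.0,
                               pB=0.0, kf=0.0, kb=0.0)
        m0 = np.array([0.0, 0.0, -1.0, 0.0, 0.0, 0.0, 1.0])
        for t in (0.1, 0.5, 2.0):
            mz = bloch.propagate(sys, 0.0, 0.0, t, m0)[2]
            expected = 1.0 + (-1.0 - 1.0) * np.exp(-0.7 * t)
            assert mz == pytest.approx(expected, rel=1e-10)

    def test_matches_explicit_integrator_on_random_systems(self):
        # oracle: high-accuracy adaptive integration of the hand-written RHS
        rng = np.random.default_rng(42)
        for _ in range(20):
            sys = random_system(rng)
            sat_offset = rng.uniform(-2000.0, 2000.0)
            nutation = rng.uniform(0.0, 150.0)
            t = 0.2
            m0 = bloch.equilibrium_state(sys)
            got = bloch.propagate(sys, sat_offset, nutation, t, m0)
            sol = solve_ivp(rhs_oracle(sys, sat_offset, nutation), (0.0, t), m0[:6],
                            rtol=1e-11, atol=1e-13, method="DOP853")
            want = sol.y[:, -1]
            scale = np.max(np.abs(want)) + 1e-12
            assert np.max(np.abs(got[:6] - want)) / scale < 1e-6

    def test_exchange_conserves_total_mz_without_relaxation(self):
        pB = 0.2
        kf = 80.0
        sys = SpinSystemParams(R1A=0.0, R2A=0.0, R1B=0.0, R2B=0.0,
                               pB=pB, kf=kf, kb=kf * (1 - pB) / pB)
        m0 = np.array([0.0, 0.0, 0.9, 0.0, 0.0, 0.02, 1.0])
        for t in (0.01, 0.1, 1.0):
            m = bloch.propagate(sys, 0.0, 0.0, t, m0)
            assert m[2] + m[5] == pytest.approx(0.92, rel=1e-10)


class TestSteadyStateSinglePool:
    def test_no_saturation(self):
        assert bloch.steady_state_z_single_pool(1.0, 1.0, 0.0, 500.0) == 1.0

    def test_full_on_resonance_saturation(self):
        z = bloch.steady_state_z_single_pool(0.5, 0.5, 150.0, 0.0)
        assert z == pytest.approx(2.8e-7, rel=0.01)

    def test_half_depth_at_nutation_offset_when_R1_eq_R2(self):
        # for R1 = R2 << w1 the half-depth offset sits at delta ~ nu1
        z = bloch.steady_state_z_single_pool(0.5, 0.5, 150.0, 150.0)
        assert z == pytest.approx(0.5, abs=0.01)


class TestSimulateZSpectrum:
    def test_matches_closed_form_when_exchange_off(self):
        sys = SpinSystemParams(R1A=1.0, R2A=1.0, R1B=1.0, R2B=10.0,
                               pB=0.0, kf=0.0, kb=0.0)
        offsets = np.linspace(-2000.0, 2000.0, 41)
        scheme = SaturationScheme(nutation=50.0, duration=20.0, offsets=offsets)
        zs = bloch.simulate_z_spectrum(sys, scheme)
        want = [bloch.steady_state_z_single_pool(1.0, 1.0, 50.0, d) for d in offsets]
        np.testing.assert_allclose(zs.z, want, atol=1e-4)

    def test_symmetry_for_shared_zero_shift(self):
        rng = np.random.default_rng(3)
        sys = dataclasses.replace(random_system(rng), offsetA=0.0, offsetB=0.0)
        offsets = np.linspace(-3000.0, 3000.0, 31)
        zs = bloch.simulate_z_spectrum(sys, SaturationScheme(100.0, 2.0, offsets))
        np.testing.assert_allclose(zs.z, zs.z[::-1], atol=1e-10)

    def test_values_within_physical_band(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            sys = random_system(rng)
            zs = bloch.simulate_z_spectrum(sys, SaturationScheme(150.0, 5.0))
            assert np.all(zs.z >= -0.01) and np.all(zs.z <= 1.02)

    def test_exchange_broadens_dip(self):
        # fitted exchange parameters vs the same pool-A rates without exchange
        params = thermo.ThermoKineticParams(dH=25e3, dS=30.0, k0=20e3, Ea=10e3)
        state = thermo.exchange_state(params, 298.0)
        offsets = np.arange(-4000.0, 4001.0, 100.0)
        scheme = SaturationScheme(nutation=150.0, duration=5.0, offsets=offsets)
        r1a = 0.06
        sys_ex = SpinSystemParams(R1A=r1a, R2A=r1a, R1B=r1a, R2B=450.0,
                                  pB=state.pB, kf=state.kf, kb=state.kb)
        sys_off = SpinSystemParams(R1A=r1a, R2A=r1a, R1B=r1a, R2B=450.0,
                                   pB=0.0, kf=0.0, kb=0.0)
        w_ex = bloch.dip_width(bloch.simulate_z_spectrum(sys_ex, scheme))
        w_off = bloch.dip_width(bloch.simulate_z_spectrum(sys_off, scheme))
        assert w_ex > w_off


class TestDipWidth:
    def test_triangle_dip_exact(self):
        offsets = np.linspace(-100.0, 100.0, 201)
        z = np.maximum(1.0 - np.maximum(1.0 - np.abs(offsets) / 40.0, 0.0), 0.0)
        zs = ZSpectrum(offsets=offsets, z=z)
        # triangular dip of depth 1: half height crossing at |offset| = 20
        assert bloch.dip_width(zs) == pytest.approx(40.0, rel=1e-12)

    @pytest.mark.parametrize("nu1, expected", [(150.0, 300.0), (20.0, 40.0)])
    def test_no_exchange_width_twice_nutation(self, nu1, expected):
        offsets = np.linspace(-25 * nu1, 25 * nu1, 2001)
        z = np.array([bloch.steady_state_z_single_pool(0.5, 0.5, nu1, d)
                      for d in offsets])
        width = bloch.dip_width(ZSpectrum(offsets=offsets, z=z))
        assert width == pytest.approx(expected, rel=0.05)

    def test_grid_refinement_stable(self):
        widths = []
        for n in (501, 1001):
            offsets = np.linspace(-3000.0, 3000.0, n)
            z = np.array([bloch.steady_state_z_single_pool(0.5, 0.5, 150.0, d)
                          for d in offsets])
            widths.append(bloch.dip_width(ZSpectrum(offsets=offsets, z=z)))
        assert abs(widths[1] / widths[0] - 1.0) < 0.01

    def test_monotone_in_pB_and_R2B(self):
        params = thermo.ThermoKineticParams(dH=25e3, dS=30.0, k0=20e3, Ea=10e3)
        kf = float(thermo.forward_rate(params, 298.0))
        offsets = np.arange(-4000.0, 4001.0, 100.0)
        scheme = SaturationScheme(150.0, 5.0, offsets)

        def width(pB, r2b):
            sys = SpinSystemParams(R1A=0.06, R2A=0.06, R1B=0.06, R2B=r2b,
                                   pB=pB, kf=kf, kb=kf * (1 - pB) / pB)
            return bloch.dip_width(bloch.simulate_z_spectrum(sys, scheme))

        for r2b in (450.0, 800.0):
            w = [width(pB, r2b) for pB in (0.001, 0.003, 0.007)]
            assert np.all(np.diff(w) > 0)
        for pB in (0.002, 0.005):
            w = [width(pB, r2b) for r2b in (300.0, 600.0, 1000.0)]
            assert np.all(np.diff(w) > 0)

    def test_boundary_minimum_raises(self):
        offsets = np.linspace(-100.0, 100.0, 11)
        z = np.linspace(0.1, 1.0, 11)  # minimum on the left boundary
        with pytest.raises(ValueError, match="not resolved"):
            bloch.dip_width(ZSpectrum(offsets=offsets, z=z))


class TestObservedRates:
    def test_no_exchange_returns_pool_A_rates(self):
        sys = SpinSystemParams(R1A=0.3, R2A=0.5, R1B=1.0, R2B=450.0,
                               pB=0.0, kf=0.0, kb=0.0)
        assert bloch.observed_rates(sys) == pytest.approx((0.3, 0.5))

    def test_fast_exchange_limit_population_weighted(self):
        pB = 0.0013
        kf = 1e6
        sys = SpinSystemParams(R1A=0.3, R2A=0.3, R1B=0.3, R2B=450.0,
                               pB=pB, kf=kf, kb=kf * (1 - pB) / pB)
        _, r2 = bloch.observed_rates(sys)
        assert r2 == pytest.approx(0.3 + pB * (450.0 - 0.3), rel=1e-3)

    def test_within_5pc_of_fast_exchange_across_fitted_range(self):
        params = thermo.ThermoKineticParams(dH=25e3, dS=30.0, k0=20e3, Ea=10e3)
        for T in np.linspace(293.0, 353.0, 7):
            st = thermo.exchange_state(params, T)
            r2b = 450.0 + (1000.0 - 450.0) * (T - 293.0) / 60.0
            sys = SpinSystemParams(R1A=0.05, R2A=0.05, R1B=0.05, R2B=r2b,
                                   pB=st.pB, kf=st.kf, kb=st.kb)
            ratio = thermo.exchange_regime_ratio(st.kf, st.pB, r2b - 0.05)
            assert ratio > 10.0
            _, r2 = bloch.observed_rates(sys)
            assert r2 == pytest.approx(
                thermo.fast_exchange_R2(0.05, r2b, st.pB), rel=0.05)

    def test_requires_shared_shift(self):
        sys = SpinSystemParams(R1A=0.3, R2A=0.3, R1B=0.3, R2B=450.0,
                               pB=0.0, kf=0.0, kb=0.0, offsetA=0.0, offsetB=100.0)
        with pytest.raises(ValueError):
            bloch.observed_rates(sys)
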