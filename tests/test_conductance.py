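"""MFPT conductance pipeline against closed forms and invariances."""

import math

import numpy as np
import pytest
from scipy.integrate import dblquad

import permion.constants as C
from permion import (
    ChannelParams,
    PMFProfile,
    compute_conductance,
    corrected_conductance,
    debye_length,
    flat_profile_conductance_closed_form,
    ion_count,
    mfpt,
    multi_ion_correction,
    tilt_potential,
)

SMALL_SWEEP = (-10, -8, -6, -4, -2, 2, 4, 6, 8, 10)


class TestDebyeLength:
    def test_physiological_value(self, params):
        assert round(debye_length(params), 2) == 0.79

    def test_inverse_sqrt_concentration(self, params):
        lam = debye_length(params)
        lam4 = debye_length(ChannelParams(c=4 * params.c))
        assert lam4 == pytest.approx(lam / 2, rel=1e-12)
        assert round(lam4, 2) == 0.39

    def test_temperature_concentration_invariance(self, params):
        scaled = ChannelParams(T=4 * params.T, c=4 * params.c)
        assert debye_length(scaled) == pytest.approx(debye_length(params), rel=1e-12)


class TestIonCount:
    def test_printed_rounding_convention(self, params):
        assert round(ion_count(params, rounding="printed"), 2) == 10.89

    def test_exact_division(self, params):
        assert round(ion_count(params, rounding="none"), 2) == 10.92

    def test_single_ion_when_length_equals_debye_diameter(self, params):
        lam = debye_length(params)
        p = ChannelParams(L=2 * lam)
        assert ion_count(p, lam) == pytest.approx(1.0, rel=1e-12)


class TestTiltPotential:
    def test_zero_voltage_is_identity(self, params, flat_profile):
        w = flat_profile()
        u = tilt_potential(w, 0.0, params)
        np.testing.assert_array_equal(u.w, w.w)

    def test_linear_energy_ramp(self, params, flat_profile):
        u = tilt_potential(flat_profile(), 100.0, params)
        assert u.w[0] == pytest.approx(9.6485, abs=1e-3)
        assert u.w[-1] == pytest.approx(0.0, abs=1e-12)
        # linear in between
        resid = u.w - (u.w[0] * (params.L - u.z) / params.L)
        assert np.abs(resid).max() < 1e-12

    def test_tilt_is_invertible(self, params, barrier_profile):
        w = barrier_profile(12.0)
        u = tilt_potential(w, 37.0, params)
        back = u.w - params.q * 37.0 * C.EMV_TO_KJMOL * (params.L - u.z) / params.L
        np.testing.assert_allclose(back, w.w, atol=1e-12)

    def test_wrong_span_rejected(self, params):
        z = np.linspace(0, 5.0, 64)
        with pytest.raises(ValueError, match="span"):
            tilt_potential(PMFProfile(z=z, w=np.zeros(64)), 10.0, params)


class TestMFPT:
    def test_flat_profile_closed_form(self, params, flat_profile):
        tau = mfpt(flat_profile(), params)
        assert tau == pytest.approx(params.L**2 / (2 * params.D_sim), rel=1e-6)

    def test_linear_downhill_closed_form(self, params, flat_profile):
        # beta*U drops by a=1 from left to right: tau = (L^2/D)(e^-a + a - 1)/a^2
        w = flat_profile()
        u = PMFProfile(z=w.z, w=C.kBT(params.T) * (params.L - w.z) / params.L, tag="tilted")
        expected = (params.L**2 / params.D_sim) * (math.exp(-1) + 1 - 1) / 1.0
        assert mfpt(u, params) == pytest.approx(expected, rel=1e-5)

    def test_matches_independent_quadrature(self, params):
        # brute-force scipy double integral on a rough barrier profile
        b = params.beta

        def w_fn(z):
            return 8.0 * np.exp(-((z - 10.0) ** 2) / 2.0) + 0.3 * z

        tau_quad, _ = dblquad(
            lambda zz, y: np.exp(b * w_fn(y)) * np.exp(-b * w_fn(zz)),
            0.0, params.L, 0.0, lambda y: y, epsabs=1e-10, epsrel=1e-10,
        )
        z = np.linspace(0.0, params.L, 4097)
        tau = mfpt(PMFProfile(z=z, w=w_fn(z), tag="full_channel"), params)
        assert tau == pytest.approx(tau_quad / params.D_sim, rel=1e-4)

    def test_gauge_invariance(self, params, barrier_profile):
        w = barrier_profile(15.0)
        assert mfpt(w.shifted(40.0), params) == pytest.approx(mfpt(w, params), rel=1e-12)

    def test_high_barrier_does_not_overflow(self, params, barrier_profile):
        tau = mfpt(barrier_profile(150.0), params)
        assert np.isfinite(tau) and tau > 0

    def test_tiny_grid_rejected(self, params):
        z = np.linspace(0, 17.2, 8)
        with pytest.raises(ValueError, match="16"):
            mfpt(PMFProfile(z=z, w=np.zeros(8)), params)


class TestConductance:
    def test_flat_profile_matches_closed_form_small_signal(self, params, flat_profile):
        res = compute_conductance(flat_profile(), params, SMALL_SWEEP)
        cf = flat_profile_conductance_closed_form(params)
        assert res.gamma0_pS == pytest.approx(cf, rel=0.01)

    def test_default_sweep_within_two_percent_of_closed_form(self, params, flat_profile):
        # at +-50 mV the I-V cubic term shaves ~1.4% off the slope
        res = compute_conductance(flat_profile(), params)
        cf = flat_profile_conductance_closed_form(params)
        assert res.gamma0_pS == pytest.approx(cf, rel=0.02)
        assert res.gamma0_pS < cf

    def test_zero_voltage_zero_current(self, params, barrier_profile):
        w = barrier_profile(10.0)
        u = tilt_potential(w, 0.0, params)
        kf = 1.0 / mfpt(u, params, "l_to_r")
        kr = 1.0 / mfpt(u, params, "r_to_l")
        assert kf - kr == pytest.approx(0.0, abs=1e-12 * kf)

    def test_gauge_invariance(self, params, barrier_profile):
        w = barrier_profile(10.0)
        g1 = compute_conductance(w, params, SMALL_SWEEP).gamma0_pS
        g2 = compute_conductance(w.shifted(25.0), params, SMALL_SWEEP).gamma0_pS
        assert abs(g2 - g1) / g1 < 1e-9

    def test_current_odd_and_rates_mirror_for_symmetric_profile(self, params, barrier_profile):
        res = compute_conductance(barrier_profile(8.0), params)
        dv = res.dV_mV
        for v in (10.0, 30.0, 50.0):
            i_p = res.I_pA[np.where(dv == v)[0][0]]
            i_m = res.I_pA[np.where(dv == -v)[0][0]]
            assert i_m == pytest.approx(-i_p, rel=1e-9)
            kf_p = res.kappa_forward[np.where(dv == v)[0][0]]
            kr_m = res.kappa_reverse[np.where(dv == -v)[0][0]]
            assert kf_p == pytest.approx(kr_m, rel=1e-9)
        assert abs(res.intercept_pA) < 1e-9 * np.abs(res.I_pA).max()

    def test_raising_barrier_lowers_conductance(self, params, barrier_profile):
        gammas = [
            compute_conductance(barrier_profile(h), params).gamma0_pS
            for h in (0.0, 5.0, 10.0, 20.0, 30.0)
        ]
        assert all(a > b for a, b in zip(gammas, gammas[1:]))

    def test_grid_convergence(self, params, barrier_profile):
        g512 = compute_conductance(barrier_profile(10.0, n=512), params).gamma0_pS
        g1024 = compute_conductance(barrier_profile(10.0, n=1024), params).gamma0_pS
        assert abs(g1024 - g512) / g512 < 0.005


class TestMultiIonCorrection:
    @pytest.mark.parametrize("gamma0, expected", [(9.64, 105), (0.92, 10), (0.0, 0)])
    def test_scaling(self, params, gamma0, expected):
        n_i = ion_count(params, rounding="printed")
        assert round(multi_ion_correction(gamma0, n_i)) == expected

    def test_ratio_unaffected_by_correction(self, params):
        n_i = ion_count(params)
        r0 = 0.92 / 9.64
        r = multi_ion_correction(0.92, n_i) / multi_ion_correction(9.64, n_i)
        assert r == pytest.approx(r0, rel=1e-12)

    def test_full_pipeline_reports_consistent_fields(self, params, barrier_profile):
        res = corrected_conductance(barrier_profile(5.0), params, SMALL_SWEEP)
        assert res.gamma_pS == pytest.approx(res.N_I * res.gamma0_pS, rel=1e-12)
        assert res.lambda_D_nm == pytest.approx(debye_length(params), rel=1e-12)


def test_unit_conversion_round_trips():
    assert 1.0 == pytest.approx(C.diffusion_si_to_sim(1.0) / C.M2_PER_S_TO_NM2_PER_NS)
    assert C.EMV_TO_KJMOL == pytest.approx(0.0964853, abs=1e-7)
    assert C.NS_TO_S * C.PER_NS_TO_PER_S == 1.0
    assert C.ANG_TO_NM * C.NM_TO_ANG == 1.0
    assert C.kBT(300.0) == pytest.approx(2.49434, abs=1e-5)
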