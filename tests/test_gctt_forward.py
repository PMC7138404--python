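import numpy as np
import pytest
from scipy import special
from scipy.integrate import cumulative_trapezoid, quad

from vasokin import gctt
from vasokin.aif import BolusShape, gamma_variate
from vasokin.gctt import GCTTParams, forward_model, gctt_residue


def _params(**kw):
    base = dict(v_b=0.04, t_c=8.0, alpha_inv=0.5, v_e=0.25, t_d=0.0,
                e=(0.2,))
    base.update(kw)
    return GCTTParams(**base)


class TestResidue:
    def test_starts_at_one_and_decreases(self):
        t = np.linspace(0, 120, 500)
        r = gctt_residue(t, t_c=8.0, alpha_inv=0.5)
        assert r[0] == 1.0
        assert np.all(np.diff(r) <= 0)
        assert np.all((r >= 0) & (r <= 1))

    def test_integral_equals_mean_transit_time(self):
        # mean-residence-time identity, independent adaptive quadrature
        val, _ = quad(lambda t: gctt_residue(np.array([t]), 8.0, 0.5)[0],
                      0, np.inf)
        assert val == pytest.approx(8.0, rel=1e-8)

    def test_vanishing_heterogeneity_is_plug_flow(self):
        t = np.array([0.0, 4.0, 7.9, 8.1, 12.0])
        r = gctt_residue(t, t_c=8.0, alpha_inv=1e-7)
        np.testing.assert_allclose(r, [1, 1, 1, 0, 0], atol=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gctt_residue(np.array([1.0]), 8.0, 0.0)
        with pytest.raises(ValueError):
            gctt_residue(np.array([-1.0]), 8.0, 0.5)


class TestDerivedHemodynamics:
    def test_flow_and_ktrans_arithmetic(self):
        p = GCTTParams(v_b=0.04, t_c=8.0, alpha_inv=0.5, v_e=0.2, t_d=0.0,
                       e=(0.1, 0.15, 0.2))
        assert p.flow == pytest.approx(0.005)
        assert p.ktrans[2] == pytest.approx(0.001)
        assert all(k <= p.flow for k in p.ktrans)

    def test_kep_infinite_without_interstitium(self):
        p = _params(v_e=0.0, e=(0.2,))
        assert np.isinf(p.kep[0])

    def test_volume_fractions_validated(self):
        with pytest.raises(ValueError):
            GCTTParams(v_b=0.5, t_c=8, alpha_inv=0.5, v_e=0.6, t_d=0,
                       e=(0.1,)).validate()


class TestForwardModel:
    def test_steady_state_content_is_blood_volume(self):
        # constant unit plasma input, no extraction -> tissue content v_b
        dt = 0.5
        t = np.arange(0, 400, dt)
        ca = np.ones_like(t)
        c = forward_model(t, ca[None], _params(e=(0.0,)))
        assert c[-1] == pytest.approx(0.04, abs=1e-3)

    def test_no_compartments_gives_zero_curve(self, config, aifs):
        p = GCTTParams(v_b=1e-12, t_c=8.0, alpha_inv=0.5, v_e=0.2, t_d=0.0,
                       e=(0.0, 0.0, 0.0))
        c = forward_model(config.time_grid, aifs, p)
        assert np.max(np.abs(c)) < 1e-10

    def test_nonnegative_for_nonnegative_input(self, config, aifs):
        p = GCTTParams(v_b=0.05, t_c=10.0, alpha_inv=1.0, v_e=0.3, t_d=2.0,
                       e=(0.05, 0.15, 0.4))
        c = forward_model(config.time_grid, aifs, p)
        assert np.all(c >= -1e-12)

    def test_delay_shifts_onset(self):
        dt = 0.5
        t = np.arange(0, 300, dt)
        ca = gamma_variate(t, 50.0, BolusShape())
        c0 = forward_model(t, ca[None], _params(t_d=0.0))
        c5 = forward_model(t, ca[None], _params(t_d=5.0))
        onset = lambda c: t[np.argmax(c > 1e-6 * c.max())]
        assert onset(c5) - onset(c0) == pytest.approx(5.0, abs=2 * dt)

    def test_grid_refinement_convergence(self):
        # halving dt must shrink the discretisation error
        sh = BolusShape()
        p = _params()
        errs = []
        ref_t = np.arange(0, 200, 0.01)
        ref = forward_model(ref_t, gamma_variate(ref_t, 20.0, sh)[None], p)
        for dt in (2.0, 1.0, 0.5):
            t = np.arange(0, 200, dt)
            c = forward_model(t, gamma_variate(t, 20.0, sh)[None], p)
            step = int(round(dt / 0.01))
            errs.append(np.max(np.abs(c - ref[::step][:c.size])))
        assert errs[0] > errs[1] > errs[2]

    def test_extended_tofts_limit(self):
        """t_c -> 0, with F and Ktrans fixed, reproduces the closed-form
        extended Tofts curve to <1e-4 relative."""
        dt, t_c = 1e-4, 5e-4
        t = np.arange(0, 50, dt)
        sh = BolusShape(amplitude=1.0, alpha=2.5, beta=3.0)
        ca = gamma_variate(t, 5.0, sh)
        v_b, v_e, e_n = 1e-2, 0.2, 4e-4
        p = GCTTParams(v_b=v_b, t_c=t_c, alpha_inv=0.5, v_e=v_e, t_d=0.0,
                       e=(e_n,))
        model = forward_model(t, ca[None], p)
        ktrans = e_n * v_b / t_c
        kep = ktrans / v_e
        a, b = sh.alpha, sh.beta
        lam = 1.0 / b - kep
        s = np.clip(t - 5.0, 0, None)
        conv = (np.exp(a) * (a * b) ** (-a) * np.exp(-kep * s)
                * special.gammainc(a + 1, s * lam) * special.gamma(a + 1)
                / lam ** (a + 1))
        oracle = v_b * ca + ktrans * conv
        err = np.max(np.abs(model - oracle)) / np.max(np.abs(oracle))
        assert err < 1e-4

    def test_plug_flow_limit(self):
        """alpha_inv -> 0 with E=0 reproduces the boxcar convolution
        F * integral of C_a over [t - t_c, t]."""
        dt, t_c = 0.005, 8.0
        t = np.arange(0, 120, dt)
        ca = gamma_variate(t, 10.0, BolusShape(amplitude=1.0))
        p = GCTTParams(v_b=0.04, t_c=t_c, alpha_inv=1e-5, v_e=0.2, t_d=0.0,
                       e=(0.0,))
        model = forward_model(t, ca[None], p)
        integral = np.concatenate([[0.0], cumulative_trapezoid(ca, t)])
        k = int(round(t_c / dt))
        shifted = np.concatenate([np.zeros(k), integral[:-k]])
        oracle = (0.04 / t_c) * (integral - shifted)
        err = np.max(np.abs(model - oracle)) / np.max(np.abs(oracle))
        assert err < 1e-4


class TestSignalConcentration:
    def test_zero_concentration_over_baseline(self):
        t = np.arange(0, 100, 1.0)
        r10 = 1000.0 / 1500.0
        s = np.full_like(t, gctt.spgr_signal(r10, 15.0, 20.0, m0=500.0))
        conc, valid = gctt.signal_to_concentration(
            s, t, (0, 50), t10_ms=1500.0, relaxivity_per_s_mm=4.5,
            tr_ms=15.0, flip_angle_deg=20.0)
        assert valid.all()
        np.testing.assert_allclose(conc, 0.0, atol=1e-10)

    def test_forward_invert_round_trip(self):
        t = np.arange(0, 300, 1.0)
        true_c = np.where(t > 60, 0.5 * np.exp(-(t - 60) / 80.0), 0.0)
        r1 = 1000.0 / 1500.0 + 4.5 * true_c
        s = gctt.spgr_signal(r1, 15.0, 20.0, m0=700.0)
        conc, valid = gctt.signal_to_concentration(
            s, t, (0, 50), t10_ms=1500.0, relaxivity_per_s_mm=4.5,
            tr_ms=15.0, flip_angle_deg=20.0)
        assert valid.all()
        np.testing.assert_allclose(conc, true_c, atol=1e-6 * 0.5)

    def test_small_concentration_linear_regime(self):
        # in a weakly saturated regime (short TR, near-90 flip) signal
        # enhancement is linear in C within 1% up to 0.05 mM
        cs = np.array([0.005, 0.01, 0.02, 0.05])
        r1 = 1000.0 / 1500.0 + 4.5 * cs
        s = gctt.spgr_signal(r1, 8.0, 60.0)
        s0 = gctt.spgr_signal(1000.0 / 1500.0, 8.0, 60.0)
        gain = (s - s0) / cs
        assert np.all(np.abs(gain / gain[0] - 1.0) < 0.01)

    def test_out_of_range_signal_flagged(self):
        t = np.arange(0, 10, 1.0)
        s = np.ones_like(t)
        s[5] = 100.0  # unphysical jump far beyond the invertible range
        conc, valid = gctt.signal_to_concentration(
            s, t, (0, 3), t10_ms=1500.0, relaxivity_per_s_mm=4.5,
            tr_ms=15.0, flip_angle_deg=20.0)
        assert not valid[5]
        assert np.isnan(conc[5])
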