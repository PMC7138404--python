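import numpy as np
import pytest
from scipy import stats as sps

from vasokin import forward_model, generate_aif
from vasokin import synthetic
from vasokin.config import AcquisitionConfig
from vasokin.gctt import GCTTParams

from conftest import random_gctt_params


class TestDCEPhantom:
    def test_noiseless_curves_match_forward_model_exactly(self, config,
                                                          aifs, rng):
        truths = random_gctt_params(rng, 2)
        curves, _ = synthetic.generate_dce_phantom(truths, aifs, config)
        for c, p in zip(curves, truths):
            np.testing.assert_array_equal(
                c, forward_model(config.time_grid, aifs, p))

    def test_bit_reproducible_from_seed(self, config, aifs, rng):
        truths = random_gctt_params(rng, 2)
        a, _ = synthetic.generate_dce_phantom(truths, aifs, config,
                                              noise_sd=0.05)
        b, _ = synthetic.generate_dce_phantom(truths, aifs, config,
                                              noise_sd=0.05)
        np.testing.assert_array_equal(a, b)

    def test_empirical_noise_level_matches_nominal(self, config, aifs, rng):
        truths = random_gctt_params(rng, 12)
        clean, _ = synthetic.generate_dce_phantom(truths, aifs, config)
        noisy, _ = synthetic.generate_dce_phantom(truths, aifs, config,
                                                  noise_sd=0.05, rng=rng)
        resid = noisy - clean
        nominal = 0.05 * np.abs(clean).max(axis=1, keepdims=True)
        # >= 10^4 samples pooled; standardised residual SD within 5% of 1
        assert resid.size >= 10_000
        assert (resid / nominal).std() == pytest.approx(1.0, abs=0.05)

    def test_agent_count_mismatch_rejected(self, config, aifs):
        p = GCTTParams(v_b=0.04, t_c=8, alpha_inv=0.5, v_e=0.2, t_d=1,
                       e=(0.1,))
        with pytest.raises(ValueError):
            synthetic.generate_dce_phantom([p], aifs, config)


class TestIVIMPhantom:
    def test_b0_equals_normalization(self, config):
        sig, _ = synthetic.generate_ivim_phantom(
            1e-3, 0.1, 5e-2, 1500.0, 40.0, config, s0=750.0)
        assert sig[0] == pytest.approx(750.0)

    def test_f_zero_is_monoexponential(self, config):
        b = np.asarray(config.b_values)
        sig, _ = synthetic.generate_ivim_phantom(
            1e-3, 0.0, 5e-2, 1500.0, 40.0, config)
        np.testing.assert_allclose(sig, np.exp(-b * 1e-3), rtol=1e-12)

    def test_noiseless_matches_direct_equation_evaluation(self, config):
        # direct re-evaluation of the signal equation, independent path
        b = np.asarray(config.b_values)
        wb = (1 - np.exp(-4000 / 2200)) * np.exp(-18.5 / 50)
        wt = (1 - np.exp(-4000 / 1500)) * np.exp(-18.5 / 40)
        f, d, ds = 0.10, 1.0e-3, 5.0e-2
        expect = (f * wb * np.exp(-b * ds) + (1 - f) * wt * np.exp(-b * d)) \
            / (f * wb + (1 - f) * wt)
        sig, _ = synthetic.generate_ivim_phantom(
            d, f, ds, 1500.0, 40.0, config)
        np.testing.assert_allclose(sig, expect, atol=1e-12)


class TestT2Phantom:
    def test_closed_form_value(self, config):
        sig, _ = synthetic.generate_t2_phantom(50.0, 1000.0, config)
        te = np.asarray(config.echo_times)
        assert sig[np.where(te == 48.0)[0][0]] == pytest.approx(
            1000.0 * np.exp(-48.0 / 50.0))

    def test_paper_echo_train_has_50_samples(self, config):
        sig, _ = synthetic.generate_t2_phantom(50.0, 1000.0, config)
        assert sig.shape[-1] == 50

    def test_rician_floor_matches_analytic_mean(self, config, rng):
        # late echoes of a short-T2 voxel sit on the Rician noise floor
        n = 40_000
        sigma = 0.05 * 1000.0
        sig, _ = synthetic.generate_t2_phantom(
            np.full(n, 20.0), 1000.0, config, noise_sd=0.05,
            noise_model="rician", rng=rng)
        te = np.asarray(config.echo_times)
        j = np.where(te == 400.0)[0][0]
        nu = 1000.0 * np.exp(-400.0 / 20.0)
        expect = sps.rice.mean(nu / sigma, scale=sigma)
        emp = sig[:, j].mean()
        assert emp == pytest.approx(expect, rel=0.01)


class TestCastPhantom:
    def test_cylinder_volume_close_to_analytic(self):
        tube = synthetic.Tube((100, 700, 700), (2900, 700, 700), 56.0)
        stack, truth = synthetic.generate_cast_phantom([tube], (110, 50, 50))
        raster = (stack > 0).sum() * 28.0 ** 3
        assert raster == pytest.approx(tube.volume_um3, rel=0.10)

    def test_zero_tubes_gives_empty_stack(self):
        stack, truth = synthetic.generate_cast_phantom([], (10, 10, 10))
        assert not stack.any()
        assert truth.params["n_segments"] == 0

    def test_y_junction_truth_counts_three_arms(self):
        c = (700.0, 700.0, 700.0)
        tubes = [synthetic.Tube(c, (1900, 700, 700), 56.0),
                 synthetic.Tube(c, (200, 1300, 700), 56.0),
                 synthetic.Tube(c, (200, 100, 700), 56.0)]
        _, truth = synthetic.generate_cast_phantom(tubes, (70, 60, 50))
        assert truth.params["n_segments"] == 3

    def test_sub_resolution_tube_warns(self):
        tube = synthetic.Tube((100, 400, 400), (900, 400, 400), 10.0)
        with pytest.warns(UserWarning):
            synthetic.generate_cast_phantom([tube], (40, 30, 30))

    def test_vessel_volume_bounded_by_mask(self):
        fat = synthetic.Tube((0, 140, 140), (280, 140, 140), 140.0)
        with pytest.raises(ValueError):
            synthetic.generate_cast_phantom([fat], (3, 3, 3))


class TestQCCohort:
    def test_incomplete_flags_and_sizes(self):
        coh = synthetic.generate_qc_cohort(10, 3, seed=1)
        assert coh["incomplete"].sum() == 3
        assert len(coh["specimen"]) == 10
        # under-filled specimens carry markedly lower cast fractions
        ratio = coh["cast_vvf"] / coh["mri_perfused_pct"]
        assert ratio[coh["incomplete"]].max() < ratio[~coh["incomplete"]].min()
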