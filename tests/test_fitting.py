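"""Noise estimation, signal model, MLE fitting, delta correction and cAIC."""

import numpy as np
import pytest

from esmgre import (
    FitModel,
    ProtocolError,
    caic_compare,
    estimate_noise_sigma,
    fit_map,
    fit_voxel,
    iterative_delta_correction,
    model_signal,
)
from esmgre.fitting import _fit_batch, _rician_loglik, caic
from esmgre.sequence import EchoTrainTiming


class TestNoiseSigma:
    def test_rayleigh_background_recovered(self):
        rng = np.random.default_rng(5)
        sigma = 5.0
        img = np.abs(
            sigma * (rng.standard_normal((80, 80)) + 1j * rng.standard_normal((80, 80)))
        )
        est = estimate_noise_sigma(img, corner_size=20)  # 4 x 400 voxels
        assert est.sigma == pytest.approx(sigma, rel=0.05)

    def test_second_moment_estimator(self):
        rng = np.random.default_rng(6)
        sigma = 2.0
        img = np.abs(
            sigma * (rng.standard_normal((80, 80)) + 1j * rng.standard_normal((80, 80)))
        )
        est = estimate_noise_sigma(img, method="second_moment")
        assert est.sigma == pytest.approx(sigma, rel=0.05)

    def test_all_zero_background(self):
        with pytest.warns(UserWarning, match="all-zero"):
            est = estimate_noise_sigma(np.zeros((50, 50)))
        assert est.sigma == 0.0

    def test_bright_corner_flagged(self):
        rng = np.random.default_rng(7)
        img = np.abs(rng.standard_normal((60, 60)))
        img[:20, :20] += 50.0  # object overlapping one corner
        with pytest.warns(UserWarning, match="brighter"):
            est = estimate_noise_sigma(img, corner_size=20)
        assert est.suspicious


class TestModelSignal:
    def test_monoexponential(self, sim_design):
        train, _ = sim_design
        s = model_signal(2.0, 75.0, train)
        np.testing.assert_allclose(s, 2.0 * np.exp(-train.te / 75.0), rtol=1e-14)

    def test_delta_modulates_even_odd(self, sim_design):
        """Adjacent equal-b echoes carry the factor exp(+-2 delta) on top of
        the T2* decay."""
        train, _ = sim_design
        delta = 0.05
        s = model_signal(1.0, 90.0, train, 0.0, delta=delta)
        s0 = model_signal(1.0, 90.0, train, 0.0, delta=0.0)
        ratio = s / s0
        np.testing.assert_allclose(ratio, np.exp(train.polarity * delta), rtol=1e-14)
        # adjacent prompt echoes: modulation ratio flips by exp(-+2 delta)
        i = 3
        r = (s[i + 1] / s[i]) / (s0[i + 1] / s0[i])
        assert r == pytest.approx(np.exp(2 * delta * train.polarity[i + 1]), rel=1e-12)

    def test_diffusion_scales_shifted_block(self, sim_design):
        train, _ = sim_design
        d = 2.0
        s = model_signal(1.0, 500.0, train, d)
        s0 = model_signal(1.0, 500.0, train, 0.0)
        atten = s / s0
        np.testing.assert_allclose(atten, np.exp(-train.b * 1e-3 * d), rtol=1e-12)
        assert np.all(atten[train.is_shifted] < 0.7)
        assert np.all(atten[~train.is_shifted] > 0.99)


class TestNoiselessRecovery:
    @pytest.mark.parametrize("noise_model", ["gaussian", "rician"])
    def test_exact_model_recovered(self, sim_design, noise_model):
        train, _ = sim_design
        rng = np.random.default_rng(11)
        V = 40
        m0 = rng.uniform(0.3, 1.5, V)
        t2 = rng.uniform(25, 1800, V)
        d = rng.uniform(0, 3, V)
        s = model_signal(m0, t2, train, d)
        sigma = 1e-6 if noise_model == "rician" else None
        theta, ll, conv, _ = _fit_batch(
            s, train, FitModel(noise_model=noise_model), sigma
        )
        assert np.abs(np.exp(theta[:, 0]) / m0 - 1).max() < 1e-3
        assert np.abs((1 / theta[:, 1]) / t2 - 1).max() < 1e-3
        assert np.abs(theta[:, 2] - d).max() < 1e-3 * 3

    def test_fit_voxel_matches_truth(self, sim_design):
        train, _ = sim_design
        s = model_signal(1.0, 140.0, train, 1.2)
        res = fit_voxel(s, train, FitModel(noise_model="gaussian"))
        assert float(res.t2star[0]) == pytest.approx(140.0, rel=1e-3)
        assert float(res.d[0]) == pytest.approx(1.2, abs=1e-3)


def _zoom_grid_mle(s, train, sigma, m0_c, t2_c, d_c, n_grid=20, stages=4):
    """Independent brute-force MLE: a 20^3 lattice refined around its
    arg-max for a few stages (no gradients involved)."""
    spans = (0.6, 0.7)  # fractional half-width for m0/t2; absolute for d
    d_half = 2.0
    best = (m0_c, t2_c, d_c)
    coarse_cells = None
    for _ in range(stages):
        m0g = np.linspace(best[0] * (1 - spans[0]), best[0] * (1 + spans[0]), n_grid)
        t2g = np.geomspace(best[1] * (1 - spans[1]), best[1] * (1 + spans[1]), n_grid)
        dg = np.linspace(max(0.0, best[2] - d_half), best[2] + d_half, n_grid)
        M, T, D = np.meshgrid(m0g, t2g, dg, indexing="ij")
        nu = model_signal(M.ravel(), T.ravel(), train, D.ravel())
        ll = _rician_loglik(s[None, :], nu, sigma)
        i = int(np.argmax(ll))
        best = (float(M.ravel()[i]), float(T.ravel()[i]), float(D.ravel()[i]))
        spans = (spans[0] / 3, spans[1] / 3)
        d_half /= 3
        cells = (
            float(np.diff(m0g).max()),
            float(np.diff(np.log(t2g)).max()),
            float(np.diff(dg).max()),
        )
        if coarse_cells is None:
            coarse_cells = cells
    return best, coarse_cells, float(ll[i])


class TestRicianOracle:
    def test_mle_matches_grid_search(self, sim_design):
        """The optimiser's arg-max agrees with a brute-force 20^3 likelihood
        lattice (refined around its arg-max) to within one lattice cell, on
        random small instances."""
        train, _ = sim_design
        rng = np.random.default_rng(21)
        sigma = 0.03
        for trial in range(20):
            t2_true = rng.uniform(40, 300)
            d_true = rng.uniform(0, 3)
            m0_true = rng.uniform(0.5, 1.5)
            s = np.abs(
                model_signal(m0_true, t2_true, train, d_true)
                + sigma * (rng.standard_normal(train.n_echoes)
                           + 1j * rng.standard_normal(train.n_echoes))
            )
            best, cells, ll_grid = _zoom_grid_mle(
                s, train, sigma, m0_true, t2_true, d_true
            )
            res = fit_voxel(s, train, FitModel(), sigma=sigma)
            nu_mle = model_signal(
                float(res.m0[0]), float(res.t2star[0]), train, float(res.d[0])
            )
            ll_mle = float(_rician_loglik(s[None, :], nu_mle[None, :], sigma)[0])
            # both maximisers attain the same likelihood height ...
            assert ll_mle >= ll_grid - 1e-6
            assert ll_grid >= ll_mle - 0.05
            # ... and agree to within one cell of the 20^3 lattice
            assert abs(float(res.m0[0]) - best[0]) <= cells[0]
            assert abs(np.log(float(res.t2star[0]) / best[1])) <= cells[1]
            assert abs(float(res.d[0]) - best[2]) <= cells[2]


class TestRicianVsGaussianBias:
    def test_gaussian_overestimates_t2star_at_low_tail_snr(self, sim_design):
        """With the last echoes below SNR 2 the noise floor flattens the
        tail; the Gaussian objective absorbs it into a longer T2*, the
        Rician objective does not."""
        train, _ = sim_design
        rng = np.random.default_rng(31)
        V = 500
        t2_true = 50.0
        sigma = 1.0 / 15.0  # SNR(TE1) ~ 14, tail SNR ~ 0
        clean = model_signal(np.ones(V), t2_true, train, 0.7)
        noisy = np.abs(
            clean + sigma * (rng.standard_normal(clean.shape)
                             + 1j * rng.standard_normal(clean.shape))
        )
        tg, _, _, _ = _fit_batch(
            noisy, train, FitModel(noise_model="gaussian"), sigma
        )
        tr_, _, _, _ = _fit_batch(
            noisy, train, FitModel(noise_model="rician"), sigma
        )
        t2_gauss = np.mean(1 / tg[:, 1])
        t2_rice = np.mean(1 / tr_[:, 1])
        assert t2_gauss > t2_rice
        assert abs(t2_gauss - t2_true) > abs(t2_rice - t2_true)


class TestDeltaCorrection:
    def test_zero_delta_data(self, sim_design):
        train, _ = sim_design
        rng = np.random.default_rng(41)
        t2 = rng.uniform(50, 150, 25)
        s = model_signal(np.ones(25), t2, train, 1.0)
        stack = s.T.reshape(train.n_echoes, 5, 5)
        delta, corrected, info = iterative_delta_correction(stack, train)
        assert abs(delta) < 1e-3
        np.testing.assert_allclose(corrected, stack, rtol=2e-3)

    def test_recovers_known_delta(self, sim_design):
        train, _ = sim_design
        rng = np.random.default_rng(42)
        t2 = rng.uniform(50, 150, 25)
        s = model_signal(np.ones(25), t2, train, 1.0, delta=0.05)
        stack = s.T.reshape(train.n_echoes, 5, 5)
        delta, corrected, info = iterative_delta_correction(stack, train)
        assert delta == pytest.approx(0.05, rel=0.01)
        s0 = model_signal(np.ones(25), t2, train, 1.0, delta=0.0)
        np.testing.assert_allclose(
            corrected.reshape(train.n_echoes, -1).T, s0, rtol=1e-3
        )

    def test_sign_flips_with_polarity_labels(self, sim_design):
        train, _ = sim_design
        t2 = np.full(9, 90.0)
        s = model_signal(np.ones(9), t2, train, 0.0, delta=0.04)
        stack = s.T.reshape(train.n_echoes, 3, 3)
        d1, _, _ = iterative_delta_correction(stack, train)
        flipped = EchoTrainTiming(
            te=train.te, is_shifted=train.is_shifted,
            polarity=-train.polarity, echo_slot=train.echo_slot,
            nav_te=train.nav_te, nav_slot=train.nav_slot,
            nav_is_shifted=train.nav_is_shifted, sub_tr=train.sub_tr,
            b=train.b,
        )
        d2, _, _ = iterative_delta_correction(stack, flipped)
        assert d2 == pytest.approx(-d1, rel=1e-3)

    def test_per_voxel_mode(self, sim_design):
        train, _ = sim_design
        t2 = np.full(4, 100.0)
        s = model_signal(np.ones(4), t2, train, 0.0, delta=0.03)
        stack = s.T.reshape(train.n_echoes, 2, 2)
        delta, _, _ = iterative_delta_correction(stack, train, per_voxel=True)
        np.testing.assert_allclose(delta, 0.03, rtol=0.02)


class TestCaic:
    def test_equal_loglik_prefers_simpler_model(self):
        ll = np.array([-100.0])
        assert caic(ll, 2, 64)[0] < caic(ll, 3, 64)[0]

    def test_equal_k_reduces_to_likelihood(self):
        a = caic(np.array([-90.0]), 3, 64)
        b = caic(np.array([-100.0]), 3, 64)
        assert a[0] < b[0]

    def test_undefined_when_too_few_echoes(self):
        assert np.isnan(caic(np.array([-5.0]), 3, 4)[0])

    def test_compare_on_synthetic_fits(self, sim_design):
        train, _ = sim_design
        rng = np.random.default_rng(51)
        sigma = 1 / 50
        V = 60
        # CSF-like voxels: strong diffusion attenuation of the shifted block
        s_csf = np.abs(
            model_signal(np.ones(V), 1500.0, train, 3.0)
            + sigma * (rng.standard_normal((V, train.n_echoes))
                       + 1j * rng.standard_normal((V, train.n_echoes)))
        )
        stack = s_csf.T.reshape(train.n_echoes, V, 1)
        fits = fit_map(stack, train, sigma=sigma)
        cmp_ = caic_compare(fits["with_diffusion"], fits["without_diffusion"])
        assert cmp_["prefer_diffusion"].mean() > 0.9


class TestFitMap:
    def test_single_voxel_consistent_with_fit_voxel(self, sim_design):
        train, _ = sim_design
        rng = np.random.default_rng(61)
        sigma = 1 / 60
        s = np.abs(
            model_signal(1.0, 110.0, train, 1.5)
            + sigma * (rng.standard_normal(train.n_echoes)
                       + 1j * rng.standard_normal(train.n_echoes))
        )
        maps = fit_map(s.reshape(-1, 1, 1), train,
                       FitModel(), sigma=sigma)["fit"]
        ref = fit_voxel(s, train, FitModel(), sigma=sigma)
        assert float(maps.t2star[0, 0]) == pytest.approx(
            float(ref.t2star[0]), rel=5e-3
        )
        assert float(maps.d[0, 0]) == pytest.approx(float(ref.d[0]), abs=0.05)

    def test_all_background_masked(self, sim_design):
        train, _ = sim_design
        rng = np.random.default_rng(62)
        sigma = 0.1
        stack = np.abs(
            sigma * (rng.standard_normal((train.n_echoes, 4, 4))
                     + 1j * rng.standard_normal((train.n_echoes, 4, 4)))
        ) * 0.01
        maps = fit_map(stack, train, FitModel(noise_model="gaussian"),
                       sigma=sigma)["fit"]
        assert np.isnan(maps.t2star).all()

    def test_voxel_order_independence(self, sim_design):
        train, _ = sim_design
        rng = np.random.default_rng(63)
        sigma = 1 / 50
        V = 16
        s = np.abs(
            model_signal(np.ones(V), rng.uniform(40, 200, V), train, 1.0)
            + sigma * (rng.standard_normal((V, train.n_echoes))
                       + 1j * rng.standard_normal((V, train.n_echoes)))
        )
        stack = s.T.reshape(train.n_echoes, 4, 4)
        perm = rng.permutation(V)
        stack_p = s[perm].T.reshape(train.n_echoes, 4, 4)
        a = fit_map(stack, train, FitModel(), sigma=sigma)["fit"].t2star.ravel()
        b = fit_map(stack_p, train, FitModel(), sigma=sigma)["fit"].t2star.ravel()
        np.testing.assert_allclose(np.sort(a), np.sort(b), rtol=1e-10)

    def test_needs_sigma_for_rician(self, sim_design):
        train, _ = sim_design
        s = model_signal(1.0, 100.0, train, 0.0)
        with pytest.raises(ProtocolError):
            fit_voxel(s, train, FitModel(noise_model="rician"))


class TestDiffusionNeglectBias:
    def test_t2star_underestimated_without_diffusion_term(self, sim_design):
        """Diffusion attenuation of the shifted echoes masquerades as faster
        decay when the model omits the b D term."""
        train, _ = sim_design
        s = model_signal(1.0, 120.0, train, 2.0)
        res = fit_voxel(s, train, FitModel(include_diffusion=False,
                                           noise_model="gaussian"))
        assert float(res.t2star[0]) < 120.0
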