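"""Acquisition corruption model and two-step navigator correction."""

import numpy as np
import pytest

from esmgre import (
    FluctuationModel,
    NoiseSpec,
    acquire_kspace,
    assign_navigators_qute,
    ghost_energy,
    low_snr_fallback,
    reconstruct_magnitude,
)
from esmgre.kspace import correct, correct_step1, correct_step2

from conftest import nrmse


@pytest.fixture(scope="module")
def reference(sim_phantom, sim_design, sim_config):
    train, _ = sim_design
    ks = acquire_kspace(sim_phantom, train, sim_config)
    return ks, reconstruct_magnitude(ks)


class TestAcquisition:
    def test_clean_round_trip(self, sim_phantom, sim_design, sim_config, reference):
        train, _ = sim_design
        from esmgre import simulate_echo_images

        _, mag = reference
        truth = np.abs(simulate_echo_images(sim_phantom, train, sim_config))
        assert nrmse(mag, truth) < 1e-12

    def test_constant_offset_preserves_magnitude(
        self, sim_phantom, sim_design, sim_config, reference
    ):
        train, _ = sim_design
        # period >> lines with phase pi/2 -> df0(p) ~ constant 3 Hz
        fl = FluctuationModel(amplitude=3.0, period=1e12, phase=np.pi / 2)
        ks = acquire_kspace(sim_phantom, train, sim_config, fluctuation=fl)
        assert nrmse(reconstruct_magnitude(ks), reference[1]) < 1e-9

    def test_sinusoid_produces_ghosts(
        self, sim_phantom, sim_design, sim_config, reference
    ):
        train, _ = sim_design
        fl = FluctuationModel(amplitude=5.0, period=24.0)
        ks = acquire_kspace(sim_phantom, train, sim_config, fluctuation=fl)
        ge_ref = ghost_energy(reference[1], sim_phantom.support)
        ge = ghost_energy(reconstruct_magnitude(ks), sim_phantom.support)
        assert ge_ref < 1e-20
        assert ge > 1e-3

    def test_parseval(self, reference):
        ks, mag = reference
        e_img = (np.abs(np.fft.ifft2(ks.data.transpose(0, 2, 1))) ** 2).sum()
        e_k = (np.abs(ks.data) ** 2).sum() / (ks.data.shape[1] * ks.data.shape[2])
        assert e_img == pytest.approx(e_k, rel=1e-10)

    def test_shape_mismatch_rejected(self, sim_design, sim_config, sim_phantom):
        train, _ = sim_design
        ks = acquire_kspace(sim_phantom, train, sim_config)
        from esmgre import MultiEchoKSpace, ProtocolError

        with pytest.raises(ProtocolError):
            MultiEchoKSpace(
                data=ks.data[:5], navs=ks.navs, train=train, config=sim_config
            )


class TestStep1:
    def test_identity_without_fluctuation(self, reference):
        ks, mag = reference
        fixed = correct_step1(ks)
        assert nrmse(reconstruct_magnitude(fixed), mag) < 1e-12

    def test_exact_for_model_consistent_fluctuation(
        self, sim_phantom, sim_design, sim_config, reference
    ):
        train, _ = sim_design
        fl = FluctuationModel(amplitude=5.0, period=24.0, drift_per_line=0.02)
        ks = acquire_kspace(sim_phantom, train, sim_config, fluctuation=fl)
        fixed = correct_step1(ks)
        assert nrmse(reconstruct_magnitude(fixed), reference[1]) < 1e-6

    def test_correction_phase_proportional_to_te(
        self, sim_phantom, sim_design, sim_config
    ):
        """The phase removed from echo n scales as TE_n / TE_nav1."""
        train, _ = sim_design
        fl = FluctuationModel(amplitude=4.0, period=16.0)
        ks = acquire_kspace(sim_phantom, train, sim_config, fluctuation=fl)
        fixed = correct_step1(ks)
        hyb0 = np.fft.ifft(ks.data, axis=-1)
        hyb1 = np.fft.ifft(fixed.data, axis=-1)
        ratio = hyb1 * np.conj(hyb0)  # phase = applied correction
        p, x = 11, 32
        applied = np.angle(ratio[:, p, x])
        slope = applied / np.where(train.te == 0, 1, train.te)
        prompt = ~train.is_shifted
        # all prompt echoes share the same phase-per-TE slope
        assert np.nanstd(slope[prompt]) < 1e-6 * (1 + np.nanmax(np.abs(slope)))

    def test_idempotent(self, sim_phantom, sim_design, sim_config):
        train, _ = sim_design
        fl = FluctuationModel(amplitude=5.0, period=24.0)
        ks = acquire_kspace(sim_phantom, train, sim_config, fluctuation=fl)
        once = correct_step1(ks)
        twice = correct_step1(once)
        assert nrmse(np.abs(twice.data), np.abs(once.data)) < 1e-10
        assert np.max(np.abs(twice.data - once.data)) < 1e-8 * np.max(
            np.abs(once.data)
        )

    def test_magnitude_preserved_in_hybrid_space(
        self, sim_phantom, sim_design, sim_config
    ):
        train, _ = sim_design
        fl = FluctuationModel(amplitude=5.0, period=24.0)
        ks = acquire_kspace(
            sim_phantom, train, sim_config, fluctuation=fl,
            noise=NoiseSpec(sigma=0.01, seed=0),
        )
        fixed = correct_step1(ks)
        h0 = np.abs(np.fft.ifft(ks.data, axis=-1))
        h1 = np.abs(np.fft.ifft(fixed.data, axis=-1))
        np.testing.assert_allclose(h1, h0, rtol=1e-10, atol=1e-14)

    def test_missing_navigator_rejected(self, sim_phantom, sim_config):
        from esmgre import ProtocolError, design_sequence

        cfg = sim_config.replace(navigator_slots=())
        train, _ = design_sequence(cfg)
        ks = acquire_kspace(sim_phantom, train, cfg)
        with pytest.raises(ProtocolError):
            correct_step1(ks)


class TestStep2:
    @pytest.fixture()
    def shifted_block_corruption(self, sim_phantom, sim_design, sim_config):
        train, _ = sim_design
        fl = FluctuationModel(
            amplitude=5.0, period=24.0,
            shifted_extra=FluctuationModel(amplitude=0.4, period=17.0, phase=1.0),
        )
        return acquire_kspace(sim_phantom, train, sim_config, fluctuation=fl)

    def test_prompt_echoes_untouched(self, shifted_block_corruption, sim_design):
        train, _ = sim_design
        s1 = correct_step1(shifted_block_corruption)
        s2 = correct_step2(s1)
        prompt = ~train.is_shifted
        np.testing.assert_array_equal(s2.data[prompt], s1.data[prompt])

    def test_identity_when_step1_removed_everything(
        self, sim_phantom, sim_design, sim_config
    ):
        train, _ = sim_design
        fl = FluctuationModel(amplitude=5.0, period=24.0)
        ks = acquire_kspace(sim_phantom, train, sim_config, fluctuation=fl)
        s1 = correct_step1(ks)
        s2 = correct_step2(s1)
        assert np.max(np.abs(s2.data - s1.data)) < 1e-8 * np.max(np.abs(s1.data))

    def test_removes_shifted_block_component(
        self, shifted_block_corruption, reference
    ):
        s2 = correct_step2(correct_step1(shifted_block_corruption))
        assert nrmse(reconstruct_magnitude(s2), reference[1]) < 1e-6

    def test_noop_without_second_navigator(self, sim_phantom, sim_config):
        from esmgre import design_sequence

        cfg = sim_config.replace(n_shifted=0, K=0.0, navigator_slots=(16,))
        train, _ = design_sequence(cfg)
        ks = acquire_kspace(sim_phantom, train, cfg)
        with pytest.warns(UserWarning, match="step 2 skipped"):
            out = correct_step2(ks)
        np.testing.assert_array_equal(out.data, ks.data)


class TestGhostEnergyReduction:
    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_corruption_corrected(
        self, sim_phantom, sim_design, sim_config, seed
    ):
        train, _ = sim_design
        fl = FluctuationModel(amplitude=5.0, period=24.0, jitter=0.5, seed=seed)
        ks = acquire_kspace(
            sim_phantom, train, sim_config, fluctuation=fl,
            noise=NoiseSpec(sigma=0.005, seed=seed),
        )
        fixed, rep = correct(ks, support=sim_phantom.support)
        assert rep.ghost_energy_after < rep.ghost_energy_before


class TestNavigatorAssignment:
    def test_quoted_128_echo_scheme(self):
        out = assign_navigators_qute(128, 4)
        assert out[0] == (1, None) and out[31] == (1, None)
        assert out[32] == (1, 2) and out[63] == (1, 2)
        assert out[64] == (1, 3) and out[95] == (1, 3)
        assert out[96] == (1, 4) and out[127] == (1, 4)

    def test_single_navigator(self):
        assert assign_navigators_qute(16, 1) == [(1, None)] * 16

    def test_two_navigator_halves(self):
        out = assign_navigators_qute(64, 2)
        assert all(o == (1, None) for o in out[:32])
        assert all(o == (1, 2) for o in out[32:])


class TestLowSnrFallback:
    def test_uniform_snr_changes_nothing(self):
        phase = np.linspace(-1, 1, 10)
        out, mask, used = low_snr_fallback(phase, np.full(10, 5.0))
        np.testing.assert_array_equal(out, phase)
        assert mask.all() and not used

    def test_spike_replaced_by_median(self):
        rng = np.random.default_rng(0)
        phase = rng.normal(0.1, 0.01, 32)
        snr = np.full(32, 10.0)
        phase[7] = 3.0
        snr[7] = 0.5
        out, mask, used = low_snr_fallback(phase, snr)
        assert used and not mask[7]
        assert out[7] == pytest.approx(np.median(phase[mask]))

    def test_high_snr_positions_untouched(self):
        rng = np.random.default_rng(1)
        phase = rng.normal(size=20)
        snr = rng.uniform(1, 10, 20)
        out, mask, _ = low_snr_fallback(phase, snr)
        np.testing.assert_array_equal(out[mask], phase[mask])

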