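"""K-space acquisition with field fluctuations and navigator phase correction.

Physiological motion (respiration, pulsation) and scanner drift modulate the
resonance frequency from shot to shot.  A frequency offset ``df0(p)`` during
the acquisition of phase-encode line ``p`` adds a phase ``2 pi df0(p) TE_n``
to every echo on that line, which turns into ghost replicas along the
phase-encode direction after reconstruction.

The correction works in hybrid (x, k_y) space (1D Fourier transform along
the readout).  Step 1 estimates per-line phase offsets from the first
navigator echo (phase-encode-free readout) relative to the first acquired
line and removes them from *all* echoes and later navigators, scaled by
``TE_n / TE_nav1``.  Step 2 repeats the estimate with the already-corrected
second navigator and removes the residual from the shifted echoes only,
scaled by ``TE_n / TE_nav2``.  Phase differences are computed as arguments
of conjugate products, which avoids phase unwrapping for offsets below pi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import DigitalPhantom, NoiseSpec, simulate_echo_images
from .protocol import ProtocolConfig, ProtocolError
from .sequence import EchoTrainTiming

__all__ = [
    "FluctuationModel",
    "MultiEchoKSpace",
    "CorrectionReport",
    "acquire_kspace",
    "correct_step1",
    "correct_step2",
    "correct",
    "assign_navigators_qute",
    "low_snr_fallback",
    "reconstruct_magnitude",
    "ghost_energy",
]


@dataclass(frozen=True)
class FluctuationModel:
    """Per-line resonance-frequency offset: sinusoid + linear drift (Hz).

    ``df0(p) = amplitude sin(2 pi p / period + phase) + drift_per_line * p``,
    with optional Gaussian jitter of standard deviation ``jitter`` (seeded,
    deterministic).  ``shifted_extra`` adds an independent fluctuation that
    acts only while the shifted echo block is acquired, emulating a change in
    field between the early and late parts of the echo train.
    """

    amplitude: float = 0.0        # Hz
    period: float = 24.0          # lines
    phase: float = 0.0            # rad
    drift_per_line: float = 0.0   # Hz / line
    jitter: float = 0.0           # Hz
    seed: int = 0
    shifted_extra: "FluctuationModel | None" = None

    def offsets(self, n_lines: int) -> np.ndarray:
        p = np.arange(n_lines, dtype=float)
        df = (
            self.amplitude * np.sin(2 * np.pi * p / self.period + self.phase)
            + self.drift_per_line * p
        )
        if self.jitter > 0:
            rng = np.random.default_rng(self.seed)
            df = df + self.jitter * rng.standard_normal(n_lines)
        return df


@dataclass
class MultiEchoKSpace:
    """Complex multi-echo k-space plus navigator readouts.

    ``data`` is indexed (echo, phase line, read sample) and ``navs``
    (navigator, phase line, read sample); navigators carry no phase
    encoding.  ``df0_applied``/``df0_shifted_extra`` record the fluctuation
    that corrupted the data (Hz per line), for audit only.
    """

    data: np.ndarray
    navs: np.ndarray
    train: EchoTrainTiming
    config: ProtocolConfig
    df0_applied: np.ndarray | None = None
    df0_shifted_extra: np.ndarray | None = None
    step1_done: bool = False
    step2_done: bool = False

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ProtocolError("k-space data must be (echo, line, read)")
        if self.data.shape[0] != self.train.n_echoes:
            raise ProtocolError("echo count mismatch between data and train")
        if self.navs.shape[0] != self.train.nav_te.size:
            raise ProtocolError("navigator count mismatch with the protocol")

    @property
    def n_lines(self) -> int:
        return self.data.shape[1]

    def hybrid(self, arr: np.ndarray | None = None) -> np.ndarray:
        """1D inverse FFT along the read axis -> (.., line, x) hybrid space."""
        a = self.data if arr is None else arr
        return np.fft.ifft(a, axis=-1)

    def copy(self) -> "MultiEchoKSpace":
        return MultiEchoKSpace(
            data=self.data.copy(), navs=self.navs.copy(), train=self.train,
            config=self.config, df0_applied=self.df0_applied,
            df0_shifted_extra=self.df0_shifted_extra,
            step1_done=self.step1_done, step2_done=self.step2_done,
        )


@dataclass
class CorrectionReport:
    """Per-line phase estimates and bookkeeping of a correction run."""

    step1_phase: np.ndarray | None = None   # (line, x) rad
    step2_phase: np.ndarray | None = None   # (line, x) rad
    snr_mask: np.ndarray | None = None      # (x,) bool, True = above mean
    fallback_used: bool = False
    ghost_energy_before: float | None = None
    ghost_energy_after: float | None = None


def acquire_kspace(
    phantom: DigitalPhantom,
    train: EchoTrainTiming,
    config: ProtocolConfig,
    fluctuation: FluctuationModel | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> MultiEchoKSpace:
    """Simulate line-by-line acquisition of the echo train over the phantom.

    Each phase-encode line ``p`` of echo ``n`` carries an extra phase
    ``2 pi df0(p) TE_n``; navigators are acquired at their train slots
    without phase encoding.  ``noise.sigma`` is the image-domain noise level
    (scaled into k-space so that reconstructed images have that sigma per
    channel).
    """
    nx, ny = phantom.shape
    images = simulate_echo_images(phantom, train, config)  # noiseless
    # navigator images: evaluate the forward model at the navigator TEs
    nav_train = EchoTrainTiming(
        te=train.nav_te, is_shifted=train.nav_is_shifted,
        polarity=np.ones(train.nav_te.size, int),
        echo_slot=train.nav_slot, nav_te=np.array([]),
        nav_slot=np.array([], int), nav_is_shifted=np.array([], bool),
        sub_tr=train.sub_tr,
        b=_nav_b(train),
    )
    nav_images = simulate_echo_images(phantom, nav_train, config)

    df0 = np.zeros(ny) if fluctuation is None else fluctuation.offsets(ny)
    extra = np.zeros(ny)
    if fluctuation is not None and fluctuation.shifted_extra is not None:
        extra = fluctuation.shifted_extra.offsets(ny)

    # k-space: lines along the phase axis (axis 1 of the image)
    data = np.fft.fft2(images, axes=(1, 2)).transpose(0, 2, 1)  # (echo, ky, x->kx)
    te_s = train.te * 1e-3
    eff = df0[None, :] + np.where(train.is_shifted, 1.0, 0.0)[:, None] * extra[None, :]
    data = data * np.exp(1j * 2 * np.pi * eff * te_s[:, None])[:, :, None]

    # navigators: the un-encoded line is the ky = 0 row, re-acquired per line
    nav_rows = np.fft.fft2(nav_images, axes=(1, 2))[:, :, 0]  # (nav, kx)
    nav_te_s = train.nav_te * 1e-3
    nav_eff = df0[None, :] + np.where(train.nav_is_shifted, 1.0, 0.0)[:, None] * extra[None, :]
    navs = (
        nav_rows[:, None, :]
        * np.exp(1j * 2 * np.pi * nav_eff * nav_te_s[:, None])[:, :, None]
    )

    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        sk = noise.sigma * np.sqrt(nx * ny)
        data = data + sk * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
        sk_nav = noise.sigma * np.sqrt(nx * ny)
        navs = navs + sk_nav * (
            rng.standard_normal(navs.shape) + 1j * rng.standard_normal(navs.shape)
        )

    return MultiEchoKSpace(
        data=data, navs=navs, train=train, config=config,
        df0_applied=df0, df0_shifted_extra=(extra if extra.any() else None),
    )


def _nav_b(train: EchoTrainTiming) -> np.ndarray | None:
    """Approximate navigator b-values from the nearest echoes of each block."""
    if train.b is None:
        return None
    out = np.zeros(train.nav_te.size)
    for i, shifted in enumerate(train.nav_is_shifted):
        sel = train.is_shifted == shifted
        out[i] = float(np.median(train.b[sel])) if sel.any() else 0.0
    return out


def _line_phase_offsets(
    nav_hybrid: np.ndarray,
    snr_fallback_sigma: float | None,
) -> tuple[np.ndarray, np.ndarray | None, bool]:
    """Per-(line, x) phase of a navigator relative to the first line.

    Returns (phase, snr_mask, fallback_used).  When ``snr_fallback_sigma``
    is given, low-SNR readout positions are replaced by the median phase of
    the high-SNR positions (per line).
    """
    ref = nav_hybrid[0]
    phase = np.angle(nav_hybrid * np.conj(ref)[None, :])
    if snr_fallback_sigma is None:
        return phase, None, False
    snr = np.abs(nav_hybrid).mean(axis=0) / max(snr_fallback_sigma, 1e-30)
    phase, mask, used = low_snr_fallback(phase, snr)
    return phase, mask, used


def low_snr_fallback(
    phase_map: np.ndarray, snr_map: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Replace phase estimates at below-average-SNR positions by the median.

    Positions ``x`` with SNR below the mean get the median phase over the
    above-mean positions (computed per line).  Returns the corrected map,
    the boolean above-mean mask and whether any replacement happened.
    """
    orig_shape = np.shape(phase_map)
    phase_map = np.atleast_2d(np.asarray(phase_map, float))
    snr_map = np.asarray(snr_map, float)
    mask = snr_map >= snr_map.mean()
    out = phase_map.copy()
    if mask.all():
        return out.reshape(orig_shape), mask, False
    if not mask.any():
        warnings.warn(
            "no above-average-SNR positions; using the global median phase",
            stacklevel=2,
        )
        med = np.median(phase_map, axis=-1, keepdims=True)
        out[...] = np.broadcast_to(med, phase_map.shape)
        return out.reshape(orig_shape), mask, True
    med = np.median(phase_map[..., mask], axis=-1, keepdims=True)
    out[..., ~mask] = np.broadcast_to(med, phase_map.shape)[..., ~mask]
    return out.reshape(orig_shape), mask, True


def correct_step1(
    kspace: MultiEchoKSpace,
    sigma: float | None = None,
    report: CorrectionReport | None = None,
) -> MultiEchoKSpace:
    """First navigator correction (applied to every echo and later navigator).

    In hybrid space, echo ``n`` on line ``p`` is multiplied by
    ``exp(-i (phi_Nu_p(x) - phi_Nu_1(x)) TE_n / TE_nav1)``; line 1 (the
    first acquired line) is the phase reference.  ``sigma`` enables the
    low-SNR median fallback for the per-position phase estimates.
    """
    if kspace.navs.shape[0] < 1:
        raise ProtocolError("step 1 needs the first navigator echo")
    ks = kspace.copy()
    nav1 = np.fft.ifft(ks.navs[0], axis=-1)  # (line, x)
    phase, snr_mask, used = _line_phase_offsets(nav1, sigma)
    te_nav1 = ks.train.nav_te[0]
    scale = ks.train.te / te_nav1

    hyb = np.fft.ifft(ks.data, axis=-1)
    hyb = hyb * np.exp(-1j * phase[None, :, :] * scale[:, None, None])
    ks.data = np.fft.fft(hyb, axis=-1)

    # navigators are corrected too (each at its own TE scaling); aligning
    # the first navigator itself makes the correction idempotent: a second
    # pass estimates zero phase
    nav_scale = ks.train.nav_te / te_nav1
    nav_hyb = np.fft.ifft(ks.navs, axis=-1)
    nav_hyb = nav_hyb * np.exp(-1j * phase[None, :, :] * nav_scale[:, None, None])
    ks.navs = np.fft.fft(nav_hyb, axis=-1)
    ks.step1_done = True
    if report is not None:
        report.step1_phase = phase
        report.snr_mask = snr_mask
        report.fallback_used = report.fallback_used or used
    return ks


def correct_step2(
    kspace: MultiEchoKSpace,
    sigma: float | None = None,
    report: CorrectionReport | None = None,
) -> MultiEchoKSpace:
    """Second navigator correction, applied to the shifted echoes only.

    Residual per-line phases are estimated from the (already corrected)
    shifted-block navigator and removed with scaling ``TE_n / TE_nav2``.
    Prompt echoes pass through bit-identically.  Without a second navigator
    this is a no-op with a warning.
    """
    shifted_navs = np.nonzero(kspace.train.nav_is_shifted)[0]
    if shifted_navs.size == 0:
        warnings.warn("no shifted-block navigator; step 2 skipped", stacklevel=2)
        return kspace.copy()
    inav = int(shifted_navs[0])
    ks = kspace.copy()
    nav2 = np.fft.ifft(ks.navs[inav], axis=-1)
    phase, snr_mask, used = _line_phase_offsets(nav2, sigma)
    te_nav2 = ks.train.nav_te[inav]
    shifted = kspace.train.is_shifted

    scale = ks.train.te[shifted] / te_nav2
    hyb = np.fft.ifft(ks.data[shifted], axis=-1)
    hyb = hyb * np.exp(-1j * phase[None, :, :] * scale[:, None, None])
    ks.data[shifted] = np.fft.fft(hyb, axis=-1)
    # align the shifted navigator itself (idempotence, as in step 1)
    nav_hyb = np.fft.ifft(ks.navs[inav], axis=-1) * np.exp(-1j * phase)
    ks.navs[inav] = np.fft.fft(nav_hyb, axis=-1)
    ks.step2_done = True
    if report is not None:
        report.step2_phase = phase
        if report.snr_mask is None:
            report.snr_mask = snr_mask
        report.fallback_used = report.fallback_used or used
    return ks


def correct(
    kspace: MultiEchoKSpace,
    sigma: float | None = None,
    support: np.ndarray | None = None,
) -> tuple[MultiEchoKSpace, CorrectionReport]:
    """Run the full two-step navigator correction and report ghost energy."""
    rep = CorrectionReport()
    if support is not None:
        rep.ghost_energy_before = ghost_energy(
            reconstruct_magnitude(kspace), support
        )
    ks = correct_step1(kspace, sigma=sigma, report=rep)
    if kspace.train.nav_is_shifted.any():
        ks = correct_step2(ks, sigma=sigma, report=rep)
    if support is not None:
        rep.ghost_energy_after = ghost_energy(reconstruct_magnitude(ks), support)
    return ks, rep


def assign_navigators_qute(
    n_echoes: int, n_navigators: int
) -> list[tuple[int, int | None]]:
    """Block-wise navigator assignment for long unshifted echo trains.

    Echoes are split into ``n_navigators`` contiguous equal blocks; the first
    block uses the first navigator only, and block ``k`` (k >= 2) uses the
    first together with the ``k``-th navigator.  Returns, per echo, a pair
    of 1-based navigator indices ``(first, second-or-None)``.
    """
    if n_navigators < 1:
        raise ProtocolError("need at least one navigator")
    out: list[tuple[int, int | None]] = []
    block = n_echoes / n_navigators
    for e in range(1, n_echoes + 1):
        k = min(int(np.ceil(e / block)), n_navigators)
        out.append((1, k if k >= 2 else None))
    return out


def reconstruct_magnitude(kspace: MultiEchoKSpace) -> np.ndarray:
    """Per-echo magnitude images from full k-space, shape (echo, nx, ny)."""
    imgs = np.fft.ifft2(kspace.data.transpose(0, 2, 1), axes=(1, 2))
    return np.abs(imgs)


def ghost_energy(magnitude: np.ndarray, support: np.ndarray) -> float:
    """Fraction of image energy outside the phantom support.

    ``magnitude`` is (echo, nx, ny) or (nx, ny); ``support`` the boolean
    object mask.  Ghost replicas along the phase-encode direction deposit
    energy outside the support, so the metric grows with ghosting.
    """
    mag = np.atleast_3d(magnitude if magnitude.ndim == 3 else magnitude[None])
    e_total = float((mag**2).sum())
    if e_total == 0:
        return 0.0
    e_out = float((mag[:, ~support] ** 2).sum())
    return e_out / e_total
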