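"""Digital phantom and spoiled-GRE forward signal model.

The voxel signal follows the spoiled gradient-echo steady state with
off-resonance phase, diffusion attenuation from the echo-shift gradients and
additive complex Gaussian noise:

    s(TE_n) = M0 sin(a) (1 - E1) / (1 - cos(a) E1)
              * exp(-TE_n / T2*) * exp(i (phi0 + 2 pi df TE_n))
              * exp(-b(TE_n) D) + eps(0, sigma^2),      E1 = exp(-TR / T1)

with M0 the spin density, ``a`` the flip angle, ``df`` the off-resonance
frequency (Hz), ``D`` the diffusivity (um^2/ms) and ``b`` in s/mm^2.

The bundled phantom is a grid of rectangular blocks emulating gray matter,
white matter, putamen, globus pallidus and CSF on an empty background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .protocol import ProtocolConfig, ProtocolError
from .sequence import EchoTrainTiming

__all__ = [
    "TissueParams",
    "DigitalPhantom",
    "NoiseSpec",
    "DEFAULT_TISSUES",
    "ernst_angle",
    "steady_state_amplitude",
    "simulate_voxel_signal",
    "simulate_echo_images",
    "build_figure2_phantom",
    "sigma_for_snr",
]


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth parameters of one tissue compartment."""

    label: str
    M0: float           # arbitrary units
    T1: float           # ms
    T2star: float       # ms
    D: float = 0.0      # um^2/ms
    delta_f: float = 0.0  # Hz, off-resonance
    phi0: float = 0.0   # rad, initial phase

    def __post_init__(self) -> None:
        if self.T2star <= 0 or self.T1 < self.T2star:
            raise ProtocolError(
                f"tissue {self.label!r}: need T1 >= T2* > 0"
            )
        if self.D < 0 or self.M0 < 0:
            raise ProtocolError(f"tissue {self.label!r}: M0 and D must be >= 0")


#: Literature-typical 3 T values; simulation inputs, not reference values.
DEFAULT_TISSUES: dict[str, TissueParams] = {
    "GM": TissueParams("GM", M0=0.80, T1=1300.0, T2star=55.0, D=0.8),
    "WM": TissueParams("WM", M0=0.65, T1=850.0, T2star=50.0, D=0.7),
    "Put": TissueParams("Put", M0=0.80, T1=1100.0, T2star=40.0, D=0.7),
    "GP": TissueParams("GP", M0=0.75, T1=1000.0, T2star=30.0, D=0.7),
    "CSF": TissueParams("CSF", M0=1.00, T1=4300.0, T2star=1800.0, D=3.0),
}


@dataclass
class DigitalPhantom:
    """Labelled 2D grid of tissue blocks with per-label parameters.

    ``labels`` holds integer labels on a (read x phase) grid; label 0 is the
    empty background (M0 = 0).  ``tissues`` maps label value -> parameters.
    """

    labels: np.ndarray
    tissues: dict[int, TissueParams]

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.tissues)
        if missing:
            raise ProtocolError(f"labels without tissue parameters: {missing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of voxels with nonzero spin density."""
        return self.labels != 0

    def parameter_map(self, name: str) -> np.ndarray:
        out = np.zeros(self.shape, dtype=float)
        for lab, tis in self.tissues.items():
            out[self.labels == lab] = getattr(tis, name)
        return out

    def label_names(self) -> dict[int, str]:
        return {lab: t.label for lab, t in self.tissues.items()}


@dataclass(frozen=True)
class NoiseSpec:
    """Complex-channel Gaussian noise level and seed."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ProtocolError("noise sigma must be >= 0")


def ernst_angle(tr: float, t1: float) -> float:
    """Flip angle (degrees) maximising the spoiled-GRE steady state.

    ``cos(alpha) = exp(-TR/T1)``; approaches 90 deg for TR >> T1 and 0 for
    TR -> 0.
    """
    if tr <= 0 or t1 <= 0:
        raise ProtocolError("TR and T1 must be positive")
    return math.degrees(math.acos(math.exp(-tr / t1)))


def steady_state_amplitude(
    m0: float, flip_angle: float, tr: float, t1: float
) -> float:
    """Spoiled-GRE steady-state prefactor M0 sin(a)(1-E1)/(1-cos(a)E1)."""
    e1 = np.exp(-np.asarray(tr, float) / np.asarray(t1, float))
    a = np.deg2rad(flip_angle)
    val = m0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)
    return float(val) if np.ndim(val) == 0 else val


def simulate_voxel_signal(
    tissue: TissueParams,
    train: EchoTrainTiming,
    config: ProtocolConfig,
    noise: NoiseSpec = NoiseSpec(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Complex echo-train signal of a single voxel.

    Diffusion attenuation uses the per-echo b-values of ``train`` (zero if
    they have not been computed).  Noise is independent Gaussian on the real
    and imaginary channels, reproducible for a fixed seed.
    """
    b = train.b if train.b is not None else np.zeros(train.n_echoes)
    amp = steady_state_amplitude(tissue.M0, config.flip_angle, config.tr, tissue.T1)
    s = (
        amp
        * np.exp(-train.te / tissue.T2star)
        * np.exp(1j * (tissue.phi0 + 2 * np.pi * tissue.delta_f * train.te * 1e-3))
        * np.exp(-b * 1e-3 * tissue.D)
    )
    if noise.sigma > 0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        s = s + noise.sigma * (
            rng.standard_normal(s.shape) + 1j * rng.standard_normal(s.shape)
        )
    return s


def simulate_echo_images(
    phantom: DigitalPhantom,
    train: EchoTrainTiming,
    config: ProtocolConfig,
    noise: NoiseSpec = NoiseSpec(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noisy complex echo images, shape (n_echoes, nx, ny).

    Evaluates the voxelwise forward model on the phantom grid; complex
    Gaussian noise is added per voxel and echo.
    """
    nx, ny = phantom.shape
    b = train.b if train.b is not None else np.zeros(train.n_echoes)
    te = train.te
    out = np.zeros((train.n_echoes, nx, ny), dtype=complex)
    for lab, tis in phantom.tissues.items():
        mask = phantom.labels == lab
        if not mask.any():
            continue
        amp = steady_state_amplitude(tis.M0, config.flip_angle, config.tr, tis.T1)
        sig = (
            amp
            * np.exp(-te / tis.T2star)
            * np.exp(1j * (tis.phi0 + 2 * np.pi * tis.delta_f * te * 1e-3))
            * np.exp(-b * 1e-3 * tis.D)
        )
        out[:, mask] = sig[:, None]
    if noise.sigma > 0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        out = out + noise.sigma * (
            rng.standard_normal(out.shape) + 1j * rng.standard_normal(out.shape)
        )
    return out


def build_figure2_phantom(
    config: ProtocolConfig,
    tissues: dict[str, TissueParams] | None = None,
    margin_frac: float = 0.12,
) -> DigitalPhantom:
    """Rectangular-block brain phantom (GM, WM, Put, GP, CSF) on background.

    Blocks are axis-aligned, non-overlapping, arranged in a row across the
    read direction and sized to the protocol matrix.
    """
    tissues = dict(tissues if tissues is not None else DEFAULT_TISSUES)
    nx, ny = config.matrix
    labels = np.zeros((nx, ny), dtype=np.int32)
    names = list(tissues)
    n = len(names)
    mx = max(1, int(round(margin_frac * nx)))
    my = max(1, int(round(margin_frac * ny)))
    usable_x = nx - 2 * mx
    gap = max(1, usable_x // (6 * n))
    block_w = (usable_x - gap * (n - 1)) // n
    if block_w < 1 or ny - 2 * my < 1:
        raise ProtocolError("matrix too small for the block phantom")
    tismap: dict[int, TissueParams] = {}
    x = mx
    for i, name in enumerate(names, start=1):
        labels[x : x + block_w, my : ny - my] = i
        tismap[i] = tissues[name]
        x += block_w + gap
    return DigitalPhantom(labels=labels, tissues=tismap)


def sigma_for_snr(
    phantom: DigitalPhantom,
    train: EchoTrainTiming,
    config: ProtocolConfig,
    snr: float,
    reference: str = "WM",
) -> float:
    """Noise sigma giving the requested SNR for a reference tissue at TE1."""
    if snr <= 0:
        raise ProtocolError("SNR must be positive")
    ref = None
    for tis in phantom.tissues.values():
        if tis.label == reference:
            ref = tis
            break
    if ref is None:
        raise ProtocolError(f"reference tissue {reference!r} not in phantom")
    amp = steady_state_amplitude(ref.M0, config.flip_angle, config.tr, ref.T1)
    return amp * math.exp(-train.te[0] / ref.T2star) / snr
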