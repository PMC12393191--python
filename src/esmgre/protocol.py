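"""Acquisition-protocol description for the echo-shifted multi-echo GRE sequence.

A :class:`ProtocolConfig` holds everything needed to lay out one sub-TR
interval of the sequence: global timing (TR, number of interleaved slices),
the echo train (number of echoes, how many are shifted into the next sub-TR,
first echo time and echo spacing), the navigator slots, the echo-shift
gradient scaling ``K``, and the hardware/RF conventions from which gradient
lobes are derived.

Units follow the common scanner conventions: times in ms, gradient
amplitudes in mT/m, gradient areas in mT*ms/m, frequencies in Hz and the
gyromagnetic ratio in rad/s/T.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "ProtocolError",
    "TimingOverflowError",
    "ProtocolConfig",
    "compute_sub_tr",
    "default_navigator_slots",
    "get_preset",
    "list_presets",
]

#: Proton gyromagnetic ratio, rad/s/T.
GAMMA_PROTON = 267.522187e6

SCHEMA_VERSION = 1


class ProtocolError(ValueError):
    """Invalid acquisition protocol."""


class TimingOverflowError(ProtocolError):
    """A gradient/readout block does not fit into its sub-TR interval."""


def default_navigator_slots(n_echoes: int, n_shifted: int) -> tuple[int, ...]:
    """Navigator slots in the middle of the prompt and shifted echo blocks.

    Slots are 1-based indices into the unified slot sequence (echoes and
    navigators together).  One navigator is placed mid-way through the prompt
    block; if any echoes are shifted, a second navigator is placed mid-way
    through the shifted block.
    """
    p = n_echoes - n_shifted
    slots = [max(1, (p + 1) // 2 + 1)]
    if n_shifted > 0:
        # prompt block occupies p echoes + 1 navigator = p + 1 slots
        slots.append(p + 1 + (n_shifted + 1) // 2 + 1)
    return tuple(slots)


@dataclass(frozen=True)
class ProtocolConfig:
    """Full timing/geometry/gradient description of one acquisition.

    The defaults mirror the in vivo protocol: TR 3000 ms, 23 slices,
    64 echoes of which 21 are shifted into the next sub-TR interval,
    TE1 = 3 ms, echo spacing 1.47 ms and K = 10.
    """

    tr: float = 3000.0                 # ms
    n_slices: int = 23
    n_echoes: int = 64                 # p + q
    n_shifted: int = 21                # q
    te1: float = 3.0                   # ms
    dte: float = 1.47                  # ms, echo spacing
    dpe: float = 0.8                   # ms, navigator phase rewind + wind
    K: float = 10.0                    # additional-gradient area multiplier
    flip_angle: float = 60.0           # degrees
    slice_thickness: float = 2.0       # mm
    readout_bandwidth: float = 800.0   # Hz/pixel
    matrix: tuple[int, int] = (240, 216)   # (read, phase)
    fov_read: float = 240.0            # mm
    navigator_slots: tuple[int, ...] = (16, 49)  # 1-based slots in the train
    gradient_raster: float = 0.01      # ms
    gamma: float = GAMMA_PROTON        # rad/s/T

    # hardware / RF conventions the gradient design is derived from
    max_grad: float = 40.0             # mT/m, generic lobe amplitude cap
    slew_rate: float = 180.0           # mT/m/ms
    additional_grad_amp: float = 18.0  # mT/m, echo-shift gradient plateau
    rf_duration: float = 2.0           # ms, excitation pulse length
    rf_tbw: float = 2.5                # RF time-bandwidth product
    additional_axis: str = "slice"     # axis carrying the echo-shift gradients
    acq_order: str = "linear"          # phase-encode acquisition order

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ProtocolError("TR must be positive")
        if self.n_slices < 1:
            raise ProtocolError("number of slices must be at least 1")
        if self.n_echoes < 1:
            raise ProtocolError("need at least one echo")
        if not 0 <= self.n_shifted < self.n_echoes:
            raise ProtocolError(
                "number of shifted echoes must satisfy 0 <= n_shifted < n_echoes"
            )
        if self.n_shifted > 0 and self.n_slices < 2:
            raise ProtocolError(
                "echo shifting needs at least 2 slices: shifted echoes form in "
                "the next sub-TR interval"
            )
        if self.K < 0:
            raise ProtocolError("K must be non-negative")
        if self.te1 <= 0 or self.dte <= 0:
            raise ProtocolError("TE1 and echo spacing must be positive")
        if self.gradient_raster <= 0:
            raise ProtocolError("gradient raster must be positive")
        if self.additional_axis not in ("read", "phase", "slice"):
            raise ProtocolError("additional_axis must be read, phase or slice")
        n_slots = self.n_echoes + len(self.navigator_slots)
        slots = tuple(self.navigator_slots)
        if len(set(slots)) != len(slots):
            raise ProtocolError("navigator slots must be unique")
        for s in slots:
            if not 1 <= s <= n_slots:
                raise ProtocolError(
                    f"navigator slot {s} outside train (1..{n_slots})"
                )
        if any(m < 1 for m in self.matrix):
            raise ProtocolError("matrix dimensions must be positive")

    # -- derived quantities ------------------------------------------------
    @property
    def n_prompt(self) -> int:
        """Number of unshifted (prompt) echoes, p."""
        return self.n_echoes - self.n_shifted

    @property
    def sub_tr(self) -> float:
        """Per-slice acquisition window TR / n_slices, ms."""
        return self.tr / self.n_slices

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["matrix"] = list(self.matrix)
        d["navigator_slots"] = list(self.navigator_slots)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        d.pop("schema_version", None)
        if "matrix" in d:
            d["matrix"] = tuple(d["matrix"])
        if "navigator_slots" in d:
            d["navigator_slots"] = tuple(d["navigator_slots"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ProtocolError(f"unknown protocol fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kw) -> "ProtocolConfig":
        return dataclasses.replace(self, **kw)


def compute_sub_tr(config: ProtocolConfig) -> float:
    """TR divided by the number of interleaved slices, in ms.

    With a single slice the quotient is TR itself, but echo shifting is then
    impossible (there is no next sub-TR interval to shift into); a warning is
    emitted in that case.
    """
    if config.n_slices < 1:
        raise ProtocolError("number of slices must be at least 1")
    if config.n_slices == 1:
        warnings.warn(
            "single-slice protocol: sub-TR equals TR and echo shifting is "
            "impossible",
            stacklevel=2,
        )
    return config.tr / config.n_slices


# ---------------------------------------------------------------------------
# presets


def list_presets() -> list[str]:
    root = resources.files("esmgre.presets")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def get_preset(name: str) -> ProtocolConfig:
    """Load a bundled protocol preset by name (see :func:`list_presets`)."""
    root = resources.files("esmgre.presets")
    try:
        text = (root / f"{name}.yaml").read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown preset {name!r}; available: {list_presets()}"
        ) from None
    return ProtocolConfig.from_dict(yaml.safe_load(text))
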