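"""Gradient waveforms, echo-train timing, zeroth moments and b-values.

One sub-TR interval of the sequence is laid out as

* slice-select lobe (RF plays on its plateau) followed by the slice-rephase
  lobe, with the readout pre-dephaser and the phase-encode lobe running in
  parallel on their own axes;
* a contiguous bipolar readout train: ``p`` prompt echoes plus any prompt
  navigator slots, each slot one echo-spacing wide;
* the first *additional* (echo-shift) gradient with area ``-A'``,
  ``A' = K x`` (slice-rephase area);
* the shifted readout slots (``q`` echoes plus the shifted navigator), in
  which the spins excited one sub-TR earlier refocus;
* the second additional gradient ``+2A'``;
* duplicated readout-dephasing and slice-refocusing lobes that restore the
  per-sub-TR gradient balance for passing spins, plus the phase rewinder.

Spins excited by RF pulse ``n`` accumulate ``-A' + 2A' = +A'`` per sub-TR
from the additional gradients; the ``-A'`` lobe of the next sub-TR brings
their net moment to zero exactly during the shifted readout slots, and they
are progressively spoiled (one extra ``A'`` per interval) afterwards.  Spins
excited in the next slice see only ``-A'`` by that time and stay dephased.

All lobe boundaries are rounded to the gradient raster; lobe amplitudes are
then solved from the exact target areas, so zeroth moments evaluated at
raster points are exact up to floating point.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import ProtocolConfig, ProtocolError, TimingOverflowError

__all__ = [
    "Lobe",
    "GradientWaveform",
    "EchoTrainTiming",
    "build_echo_train",
    "build_gradient_waveform",
    "design_sequence",
    "zeroth_moment",
    "compute_b_values",
    "spoiling_threshold",
    "max_slices",
]

AXES = ("read", "phase", "slice")


def _round_raster(t: float, raster: float) -> float:
    return round(round(t / raster) * raster, 9)


def _ceil_raster(t: float, raster: float) -> float:
    return round(math.ceil(t / raster - 1e-9) * raster, 9)


@dataclass(frozen=True)
class Lobe:
    """One trapezoidal gradient lobe.

    ``amplitude`` is signed (mT/m); the lobe ramps from zero to ``amplitude``
    over ``ramp_up`` ms, holds for ``flat`` ms and ramps back to zero over
    ``ramp_down`` ms.  ``label`` annotates its role in the sequence.
    """

    axis: str
    label: str
    start: float       # ms from sub-TR start
    ramp_up: float     # ms
    flat: float        # ms
    ramp_down: float   # ms
    amplitude: float   # mT/m, signed

    @property
    def duration(self) -> float:
        return self.ramp_up + self.flat + self.ramp_down

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def area(self) -> float:
        """Signed area in mT*ms/m."""
        return self.amplitude * (self.flat + 0.5 * (self.ramp_up + self.ramp_down))

    def value(self, t: np.ndarray) -> np.ndarray:
        """Amplitude at times ``t`` (ms), vectorised."""
        t = np.asarray(t, dtype=float)
        tau = t - self.start
        out = np.zeros_like(t)
        if self.ramp_up > 0:
            m = (tau >= 0) & (tau < self.ramp_up)
            out[m] = self.amplitude * tau[m] / self.ramp_up
        m = (tau >= self.ramp_up) & (tau <= self.ramp_up + self.flat)
        out[m] = self.amplitude
        if self.ramp_down > 0:
            tau2 = tau - self.ramp_up - self.flat
            m = (tau2 > 0) & (tau2 < self.ramp_down)
            out[m] = self.amplitude * (1.0 - tau2[m] / self.ramp_down)
        return out


def _trapezoid_for_area(
    area: float, amp_cap: float, slew: float, raster: float, label: str,
    axis: str, start: float,
) -> Lobe:
    """Shortest trapezoid on the raster with the given signed area."""
    a = abs(area)
    if a == 0.0:
        return Lobe(axis, label, start, 0.0, 0.0, 0.0, 0.0)
    ramp = _ceil_raster(amp_cap / slew, raster)
    # triangle if the area is small enough, else trapezoid at (close to) cap
    tri_area = amp_cap * ramp  # area of triangle with both ramps = ramp
    if a <= tri_area:
        # keep both ramps, shrink amplitude
        dur = 2 * ramp
        amp = a / ramp
    else:
        dur = _ceil_raster(a / amp_cap + ramp, raster) + ramp
        amp = a / (dur - ramp)
    flat = round(dur - 2 * ramp, 9)
    amp = math.copysign(amp, area)
    return Lobe(axis, label, start, ramp, flat, ramp, amp)


# ---------------------------------------------------------------------------
# slot layout


def _prompt_slot_count(config: ProtocolConfig) -> int:
    """Number of slots in the prompt block (fixpoint of p + navs inside)."""
    p = config.n_prompt
    navs = tuple(sorted(config.navigator_slots))
    P = p
    for _ in range(len(navs) + 2):
        P_next = p + sum(1 for s in navs if s <= P)
        if P_next == P:
            return P
        P = P_next
    return P


# ---------------------------------------------------------------------------
# echo train


@dataclass
class EchoTrainTiming:
    """Per-echo timing, shift flags, bipolar polarity and b-values.

    Echo times are measured from the RF pulse that excited the spins; shifted
    echoes therefore carry the extra sub-TR interval.  ``b`` is filled by
    :func:`compute_b_values` (``nan`` until then).
    """

    te: np.ndarray             # (n_echoes,) ms
    is_shifted: np.ndarray     # (n_echoes,) bool
    polarity: np.ndarray       # (n_echoes,) +1/-1 readout lobe sign
    echo_slot: np.ndarray      # (n_echoes,) 1-based slot index
    nav_te: np.ndarray         # (n_nav,) ms
    nav_slot: np.ndarray       # (n_nav,) 1-based
    nav_is_shifted: np.ndarray  # (n_nav,) bool
    sub_tr: float              # ms
    b: np.ndarray | None = None  # (n_echoes,) s/mm^2

    @property
    def n_echoes(self) -> int:
        return self.te.size

    @property
    def n_shifted(self) -> int:
        return int(self.is_shifted.sum())

    def to_dict(self) -> dict:
        return {
            "te_ms": self.te.tolist(),
            "is_shifted": self.is_shifted.astype(int).tolist(),
            "polarity": self.polarity.tolist(),
            "echo_slot": self.echo_slot.tolist(),
            "nav_te_ms": self.nav_te.tolist(),
            "nav_slot": self.nav_slot.tolist(),
            "nav_is_shifted": self.nav_is_shifted.astype(int).tolist(),
            "sub_tr_ms": self.sub_tr,
            "b_s_mm2": None if self.b is None else self.b.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EchoTrainTiming":
        return cls(
            te=np.asarray(d["te_ms"], float),
            is_shifted=np.asarray(d["is_shifted"], int).astype(bool),
            polarity=np.asarray(d["polarity"], int),
            echo_slot=np.asarray(d["echo_slot"], int),
            nav_te=np.asarray(d["nav_te_ms"], float),
            nav_slot=np.asarray(d["nav_slot"], int),
            nav_is_shifted=np.asarray(d["nav_is_shifted"], int).astype(bool),
            sub_tr=float(d["sub_tr_ms"]),
            b=None if d.get("b_s_mm2") is None else np.asarray(d["b_s_mm2"], float),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EchoTrainTiming":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "echo": np.arange(1, self.n_echoes + 1),
                "slot": self.echo_slot,
                "te_ms": self.te,
                "is_shifted": self.is_shifted,
                "polarity": self.polarity,
                "b_s_mm2": np.full(self.n_echoes, np.nan) if self.b is None else self.b,
            }
        )


class _SequenceGeometry:
    """Derived lobe geometry shared by the train builder and waveform builder."""

    def __init__(self, config: ProtocolConfig):
        c = config
        raster = c.gradient_raster
        gam = c.gamma

        # RF / slice select: amplitude from slice thickness and RF bandwidth
        self.sub_tr_r = _round_raster(c.sub_tr, raster)
        rf_bw_hz = c.rf_tbw / (c.rf_duration * 1e-3)
        self.g_ss = 2 * math.pi * rf_bw_hz / (gam * c.slice_thickness * 1e-3) * 1e3
        self.ramp_ss = _ceil_raster(self.g_ss / c.slew_rate, raster)
        self.rf_flat = _round_raster(c.rf_duration, raster)
        self.t_rf = self.ramp_ss + self.rf_flat / 2.0  # RF centre in the sub-TR
        self.select_end = 2 * self.ramp_ss + self.rf_flat
        # area seen by spins after the RF centre = what the rephaser cancels
        self.a_rephase = self.g_ss * (self.rf_flat / 2.0 + self.ramp_ss / 2.0)

        # bipolar readout lobe filling one echo-spacing slot exactly
        flat_ro = _round_raster(1e3 / c.readout_bandwidth, raster)
        ramp_ro = _round_raster((c.dte - flat_ro) / 2.0, raster)
        if ramp_ro < raster:
            raise ProtocolError(
                "echo spacing too short for the readout flat-top (1/bandwidth)"
            )
        flat_ro = round(c.dte - 2 * ramp_ro, 9)
        self.flat_ro, self.ramp_ro = flat_ro, ramp_ro
        self.g_ro = (
            2 * math.pi * c.matrix[0]
            / (gam * c.fov_read * 1e-3 * flat_ro * 1e-3) * 1e3
        )
        if self.g_ro / ramp_ro > c.slew_rate * (1 + 1e-9):
            raise ProtocolError(
                "readout gradient exceeds the slew-rate limit within the "
                "available ramp time"
            )
        self.a_lobe = self.g_ro * (flat_ro + ramp_ro)  # full readout lobe area

        # additional (echo-shift) gradients: -A' and +2A'
        self.a_prime = c.K * self.a_rephase
        if c.n_shifted > 0 and self.a_prime > 0:
            amp = min(c.additional_grad_amp, c.max_grad)
            self.lobe_a1 = _trapezoid_for_area(
                -self.a_prime, amp, c.slew_rate, raster, "additional_-A", "", 0.0
            )
            self.lobe_a2 = _trapezoid_for_area(
                2 * self.a_prime, amp, c.slew_rate, raster, "additional_+2A", "", 0.0
            )
            self.d_a1 = self.lobe_a1.duration
            self.d_a2 = self.lobe_a2.duration
        else:
            self.lobe_a1 = self.lobe_a2 = None
            self.d_a1 = self.d_a2 = 0.0

        # key train times (all relative to sub-TR start; RF centre at t_rf)
        self.prompt_slots = _prompt_slot_count(c)
        self.total_slots = c.n_echoes + len(c.navigator_slots)
        # lobe starts may sit on half-raster points so that the echo
        # centres themselves land exactly on the raster
        self.first_lobe_start = _round_raster(
            self.t_rf + c.te1 - c.dte / 2.0, raster / 2.0
        )
        self.prompt_end = round(self.first_lobe_start + self.prompt_slots * c.dte, 9)
        self.shift_start = round(self.prompt_end + self.d_a1, 9)
        self.shifted_slots = self.total_slots - self.prompt_slots
        self.shift_end = round(self.shift_start + self.shifted_slots * c.dte, 9)
        self.acq_end = self.shift_end if c.n_shifted > 0 else self.prompt_end
        self.end_block_start = round(
            self.acq_end + (self.d_a2 if c.n_shifted > 0 else 0.0), 9
        )

        # end-of-interval balancing lobes (durations only, built later)
        ramp_cap = _ceil_raster(c.max_grad / c.slew_rate, raster)
        self.d_spoil_ro = _trapezoid_for_area(
            self.a_lobe / 2, c.max_grad, c.slew_rate, raster, "", "", 0.0
        ).duration
        self.d_dup_reph = _trapezoid_for_area(
            self.a_rephase, c.max_grad, c.slew_rate, raster, "", "", 0.0
        ).duration
        self.d_pe = max(_round_raster(c.dpe, raster), 2 * raster)
        self.required = round(
            self.end_block_start
            + max(self.d_spoil_ro, self.d_dup_reph, self.d_pe), 9
        )

        # feasibility of TE1: rephase and pre-dephaser must fit before the
        # first readout lobe
        self.d_reph = self.d_dup_reph
        self.d_predeph = self.d_spoil_ro
        if self.select_end + max(self.d_reph, self.d_predeph) > \
                self.first_lobe_start + 1e-9:
            raise ProtocolError(
                "TE1 too short: slice rephase / readout pre-dephaser do not "
                "fit between the RF pulse and the first echo"
            )

    def check_fits(self, config: ProtocolConfig) -> None:
        if self.required > self.sub_tr_r + 1e-9:
            raise TimingOverflowError(
                f"readout block needs {self.required:.2f} ms but the sub-TR "
                f"interval is only {config.sub_tr:.2f} ms "
                f"(TR {config.tr:g} ms / {config.n_slices} slices)"
            )


def build_echo_train(config: ProtocolConfig) -> EchoTrainTiming:
    """Lay out the echo train and return per-echo TEs, flags and polarities.

    Prompt echoes sit at ``TE1 + k*dTE`` with navigator slots counting as one
    echo spacing each; shifted echoes are offset by one sub-TR plus the
    duration of the first additional gradient.  All times are rounded to the
    gradient raster.
    """
    geo = _SequenceGeometry(config)
    geo.check_fits(config)
    c = config
    raster = c.gradient_raster
    navs = set(c.navigator_slots)
    P = geo.prompt_slots

    te, shifted, pol, slots = [], [], [], []
    nav_te, nav_slot, nav_shift = [], [], []
    for s in range(1, geo.total_slots + 1):
        if s <= P:
            t_local = c.te1 + (s - 1) * c.dte
            is_shift = False
        else:
            t_local = (
                geo.shift_start - geo.t_rf + (s - P - 0.5) * c.dte
            )
            is_shift = True
        t = _round_raster(t_local + (geo.sub_tr_r if is_shift else 0.0), raster)
        if s in navs:
            nav_te.append(t)
            nav_slot.append(s)
            nav_shift.append(is_shift)
        else:
            te.append(t)
            shifted.append(is_shift)
            pol.append(1 if (s - 1) % 2 == 0 else -1)
            slots.append(s)
    return EchoTrainTiming(
        te=np.asarray(te),
        is_shifted=np.asarray(shifted, bool),
        polarity=np.asarray(pol, int),
        echo_slot=np.asarray(slots, int),
        nav_te=np.asarray(nav_te),
        nav_slot=np.asarray(nav_slot, int),
        nav_is_shifted=np.asarray(nav_shift, bool),
        sub_tr=geo.sub_tr_r,
    )


# ---------------------------------------------------------------------------
# waveform


@dataclass
class GradientWaveform:
    """Piecewise-linear gradient waveform over one sub-TR interval.

    The waveform is periodic with period ``sub_tr``; sampling over several
    periods repeats the single-interval lobe set.  ``t_rf`` is the RF-pulse
    centre within the interval.
    """

    lobes: list[Lobe]
    sub_tr: float
    raster: float
    t_rf: float
    config: ProtocolConfig

    def lobes_on(self, axis: str) -> list[Lobe]:
        return [lb for lb in self.lobes if lb.axis == axis]

    def amplitude(self, axis: str, t: np.ndarray) -> np.ndarray:
        """Amplitude (mT/m) at absolute times ``t`` of the periodic waveform."""
        t = np.asarray(t, dtype=float)
        t_local = np.mod(t, self.sub_tr)
        out = np.zeros_like(t_local)
        for lb in self.lobes_on(axis):
            out += lb.value(t_local)
        return out

    @property
    def step(self) -> float:
        """Sampling step: half the raster, so half-raster lobe breakpoints
        and raster-aligned echo centres are both hit exactly."""
        return self.raster / 2.0

    def sample(self, axis: str, n_periods: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Sample-edge times and amplitudes over ``n_periods`` intervals."""
        n_cells = int(round(self.sub_tr / self.step)) * n_periods
        t = np.arange(n_cells + 1) * self.step
        return t, self.amplitude(axis, t)

    def sample_cells(
        self, axis: str, n_periods: int = 1
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Edge times plus one-sided amplitudes g(t0+), g(t1-) per cell.

        Amplitudes are recovered from quarter-point samples, which stay exact
        for lobes that are linear inside each cell even when the waveform
        jumps at cell boundaries (zero-ramp lobes).
        """
        n_cells = int(round(self.sub_tr / self.step)) * n_periods
        t = np.arange(n_cells + 1) * self.step
        q1 = self.amplitude(axis, t[:-1] + 0.25 * self.step)
        q3 = self.amplitude(axis, t[:-1] + 0.75 * self.step)
        g_left = 1.5 * q1 - 0.5 * q3
        g_right = 1.5 * q3 - 0.5 * q1
        return t, g_left, g_right

    def cumulative_moment(self, axis: str, n_periods: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative zeroth moment (mT*ms/m) at raster edges from t = 0.

        Exact for trapezoidal lobes whose breakpoints lie on the raster
        (the trapezoid rule is exact on linear segments).
        """
        t, gl, gr = self.sample_cells(axis, n_periods)
        cells = 0.5 * (gl + gr) * self.step
        m = np.concatenate([[0.0], np.cumsum(cells)])
        return t, m

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "axis": lb.axis,
                "label": lb.label,
                "start_ms": lb.start,
                "ramp_up_ms": lb.ramp_up,
                "flat_ms": lb.flat,
                "ramp_down_ms": lb.ramp_down,
                "amplitude_mT_m": lb.amplitude,
                "area_mT_ms_m": lb.area,
            }
            for lb in self.lobes
        ]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        d = {
            "sub_tr_ms": self.sub_tr,
            "raster_ms": self.raster,
            "t_rf_ms": self.t_rf,
            "lobes": self.to_dataframe().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(d, indent=1))


def build_gradient_waveform(
    config: ProtocolConfig, axis: str | None = None
) -> GradientWaveform:
    """Build the full sub-TR gradient waveform (optionally a single axis).

    With ``K = 0`` or no shifted echoes the additional gradients vanish and
    the waveform reduces to a conventional bipolar multi-echo readout.
    """
    geo = _SequenceGeometry(config)
    geo.check_fits(config)
    c = config
    raster = c.gradient_raster
    lobes: list[Lobe] = []

    # slice select + rephase
    lobes.append(
        Lobe("slice", "slice_select", 0.0, geo.ramp_ss, geo.rf_flat,
             geo.ramp_ss, geo.g_ss)
    )
    lobes.append(
        _trapezoid_for_area(
            -geo.a_rephase, c.max_grad, c.slew_rate, raster,
            "slice_rephase", "slice", geo.select_end,
        )
    )

    # phase-encode lobe (nominal outermost line), parallel with the rephase
    a_pe = geo.a_lobe / 2 * c.matrix[1] / c.matrix[0]  # nominal encode area
    lobes.append(
        _trapezoid_for_area(
            a_pe, c.max_grad, c.slew_rate, raster, "pe_encode", "phase",
            geo.select_end,
        )
    )

    # readout pre-dephaser ends at the first readout lobe
    pre = _trapezoid_for_area(
        -geo.a_lobe / 2, c.max_grad, c.slew_rate, raster,
        "readout_predephase", "read", 0.0,
    )
    pre = Lobe(
        "read", pre.label, round(geo.first_lobe_start - pre.duration, 9),
        pre.ramp_up, pre.flat, pre.ramp_down, pre.amplitude,
    )
    lobes.append(pre)

    # bipolar readout train (echo + navigator slots share the lobe geometry)
    navs = set(c.navigator_slots)
    P = geo.prompt_slots
    for s in range(1, geo.total_slots + 1):
        if s <= P:
            start = geo.first_lobe_start + (s - 1) * c.dte
        else:
            start = geo.shift_start + (s - P - 1) * c.dte
        sign = 1.0 if (s - 1) % 2 == 0 else -1.0
        label = "navigator_lobe" if s in navs else (
            "readout_lobe_shifted" if s > P else "readout_lobe"
        )
        lobes.append(
            Lobe("read", label, round(start, 9), geo.ramp_ro, geo.flat_ro,
                 geo.ramp_ro, sign * geo.g_ro)
        )
        if s in navs:
            # navigator phase rewind/wind pair on the phase axis (net zero)
            d_half = max(_round_raster(c.dpe / 2, raster), 2 * raster)
            rew = _trapezoid_for_area(
                -a_pe, c.max_grad, c.slew_rate, raster, "nav_pe_rewind",
                "phase", round(start - d_half, 9),
            )
            wind = _trapezoid_for_area(
                a_pe, c.max_grad, c.slew_rate, raster, "nav_pe_wind",
                "phase", round(start + c.dte, 9),
            )
            lobes.extend([rew, wind])

    # additional (echo-shift) gradients
    if geo.lobe_a1 is not None:
        ax = c.additional_axis
        a1, a2 = geo.lobe_a1, geo.lobe_a2
        lobes.append(Lobe(ax, a1.label, geo.prompt_end, a1.ramp_up, a1.flat,
                          a1.ramp_down, a1.amplitude))
        lobes.append(Lobe(ax, a2.label, geo.shift_end, a2.ramp_up, a2.flat,
                          a2.ramp_down, a2.amplitude))

    # duplicated dephasing / refocusing lobes at the end of the interval
    t0 = geo.end_block_start
    n_lobes = geo.total_slots
    read_moment = -geo.a_lobe / 2 + (geo.a_lobe if n_lobes % 2 else 0.0)
    lobes.append(
        _trapezoid_for_area(
            -read_moment, c.max_grad, c.slew_rate, raster,
            "readout_dephase_dup", "read", t0,
        )
    )
    lobes.append(
        _trapezoid_for_area(
            -geo.a_rephase, c.max_grad, c.slew_rate, raster,
            "slice_refocus_dup", "slice", t0,
        )
    )
    lobes.append(
        _trapezoid_for_area(
            -a_pe, c.max_grad, c.slew_rate, raster, "pe_rewind", "phase", t0,
        )
    )

    wf = GradientWaveform(
        lobes=lobes, sub_tr=geo.sub_tr_r, raster=raster, t_rf=geo.t_rf,
        config=c,
    )
    if axis is not None:
        if axis not in AXES:
            raise ProtocolError(f"unknown axis {axis!r}")
        wf = GradientWaveform(
            lobes=wf.lobes_on(axis), sub_tr=geo.sub_tr_r, raster=raster,
            t_rf=geo.t_rf, config=c,
        )
    return wf


def design_sequence(config: ProtocolConfig) -> tuple[EchoTrainTiming, GradientWaveform]:
    """Build the echo train and waveform and fill the per-echo b-values."""
    train = build_echo_train(config)
    wf = build_gradient_waveform(config)
    train.b = compute_b_values(wf, train)
    return train, wf


# ---------------------------------------------------------------------------
# moments, spoiling, b-values


def spoiling_threshold(config: ProtocolConfig, axis: str = "slice") -> float:
    """Gradient area (mT*ms/m) giving 2*pi phase dispersion across a voxel."""
    if axis == "slice":
        dx = config.slice_thickness * 1e-3
    else:
        dx = config.fov_read / config.matrix[0] * 1e-3
    return 2 * math.pi / (config.gamma * dx) * 1e6


def zeroth_moment(
    waveform: GradientWaveform,
    spin_origin: str,
    t: float | np.ndarray,
    axes: Sequence[str] = ("read", "slice"),
) -> dict[str, np.ndarray]:
    """Cumulative gradient area experienced by spins at absolute time ``t``.

    ``spin_origin`` selects the exciting RF pulse: ``"this_slice"`` spins are
    created at ``t_rf`` of the first interval, ``"next_slice"`` spins one
    sub-TR later.  Times are absolute (first interval starts at 0); echo
    centres sit at ``t_rf + TE``.  Returns per-axis moments in mT*ms/m.
    """
    if spin_origin not in ("this_slice", "next_slice"):
        raise ProtocolError("spin_origin must be 'this_slice' or 'next_slice'")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    start = waveform.t_rf + (waveform.sub_tr if spin_origin == "next_slice" else 0.0)
    t_max = max(float(t.max()), start)
    n_periods = int(math.ceil((t_max + waveform.step) / waveform.sub_tr)) + 1
    out: dict[str, np.ndarray] = {}
    for ax in axes:
        edges, m = waveform.cumulative_moment(ax, n_periods)
        vals = np.interp(t, edges, m) - np.interp(start, edges, m)
        vals = np.where(t < start, np.nan, vals)
        out[ax] = vals
    return out


def moment_magnitude(moments: dict[str, np.ndarray]) -> np.ndarray:
    """Root-sum-square over axes of a per-axis moment dict."""
    return np.sqrt(sum(np.asarray(v) ** 2 for v in moments.values()))


def _cell_b_integral(
    m0: np.ndarray, gl: np.ndarray, gr: np.ndarray, h: float
) -> np.ndarray:
    """Exact integral of m(t)^2 per sample cell for piecewise-linear g.

    ``m0`` are moments at cell left edges, ``gl``/``gr`` the one-sided
    amplitudes at the cell's left and right edge; within a cell
    ``m(tau) = m0 + gl tau + (gr-gl) tau^2 / (2h)``.
    """
    a = m0
    b1 = gl
    c = (gr - gl) / (2.0 * h)
    return (
        a * a * h
        + a * b1 * h**2
        + (b1 * b1 + 2.0 * a * c) / 3.0 * h**3
        + 0.5 * b1 * c * h**4
        + 0.2 * c * c * h**5
    )


def compute_b_values(
    waveform: GradientWaveform, echo_train: EchoTrainTiming
) -> np.ndarray:
    """Diffusion-weighting b-value (s/mm^2) at each echo.

    ``b(TE_n) = gamma^2 * integral_0^TEn [integral_0^t G dt']^2 dt`` summed
    over the read and slice axes (and the additional-gradient axis if it is
    the phase axis); phase-encoding lobes are excluded.  The integral starts
    at the RF pulse, so shifted echoes accumulate over both sub-TR intervals
    the spins traverse.
    """
    c = waveform.config
    h = waveform.step
    te_abs = waveform.t_rf + echo_train.te
    n_periods = int(math.ceil((te_abs.max() + h) / waveform.sub_tr)) + 1
    axes = {"read", "slice"}
    if c.additional_axis == "phase":
        axes.add("phase")

    start = waveform.t_rf
    idx_start = int(round(start / h))
    idx_te = np.round(te_abs / h).astype(int)

    total = None
    for ax in axes:
        if ax == "phase":
            # keep only the additional lobes on the phase axis
            sub = GradientWaveform(
                lobes=[lb for lb in waveform.lobes_on("phase")
                       if lb.label.startswith("additional")],
                sub_tr=waveform.sub_tr, raster=waveform.raster,
                t_rf=waveform.t_rf, config=waveform.config,
            )
            t, gl, gr = sub.sample_cells("phase", n_periods)
        else:
            t, gl, gr = waveform.sample_cells(ax, n_periods)
        m = np.concatenate([[0.0], np.cumsum(0.5 * (gl + gr) * h)])
        m = m - m[idx_start]
        cells = _cell_b_integral(m[:-1], gl, gr, h)
        cum = np.concatenate([[0.0], np.cumsum(cells)])
        contrib = cum[idx_te] - cum[idx_start]
        total = contrib if total is None else total + contrib

    # (mT/m * ms)^2 * ms -> s/mm^2 : gamma^2 * 1e-21 ; see module docs
    return waveform.config.gamma**2 * 1e-21 * total


def max_slices(config: ProtocolConfig) -> int:
    """Largest slice count whose sub-TR still fits the full readout block."""
    geo = _SequenceGeometry(config)
    n = int(math.floor(config.tr / geo.required + 1e-9))
    return max(n, 1)
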