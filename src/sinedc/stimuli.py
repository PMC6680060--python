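"""Command waveforms (sine, ZAP chirp, pulses), P/N leak subtraction, ΔF/F.

Waveform amplitudes are specified in mV (conventional units) but sampled
waveforms carry volts, matching the SI convention of the cable solver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .cable import TraceSet

__all__ = [
    "Waveform",
    "SineSpec",
    "ZapSpec",
    "PulseSpec",
    "DffInputs",
    "make_sine",
    "make_zap",
    "make_pulse",
    "instantaneous_frequency",
    "pn_subtract",
    "dff",
]


@dataclass
class Waveform:
    """Uniformly sampled command voltage: t in s, v in V."""

    t: np.ndarray
    v: np.ndarray
    dt: float

    def __post_init__(self):
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have equal length")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def reversed_in_time(self) -> "Waveform":
        return Waveform(t=self.t.copy(), v=self.v[::-1].copy(), dt=self.dt)

    def save_txt(self, path):
        np.savetxt(path, np.column_stack([self.t, self.v]), header="t_s v_V")


@dataclass(frozen=True)
class SineSpec:
    """V(t) = amplitude·sin(2πf t + phase) + v_hold (mV fields)."""

    f_sine: float
    amplitude: float = 15.0
    v_hold: float = -80.0
    phase: float = 0.0

    def __post_init__(self):
        if self.f_sine <= 0:
            raise ValueError("f_sine must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class ZapSpec:
    """Swept-frequency chirp V(t) = a·sin(b·t^c + d) + v_hold.

    The published constants of this family are not recoverable, so the
    canonical constructor :meth:`from_sweep` solves b, d and a time offset
    from (f_low, f_high, duration) for a chosen exponent c; c = 2 gives a
    linear sweep of instantaneous frequency.  The waveform is temporally
    reversed by default so the highest frequencies lead, and constant pads
    (default 200 ms) are added at both ends.
    """

    a: float = 15.0         # mV peak, relative to v_hold
    b: float = 0.0
    c: float = 2.0
    d: float = 0.0
    t_offset: float = 0.0   # s; sweep evaluated on [t_offset, t_offset+duration]
    duration: float = 1.0   # s
    pad: float = 0.2        # s
    reversed: bool = True
    v_hold: float = -80.0   # mV

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @classmethod
    def from_sweep(cls, f_low: float = 5.0, f_high: float = 2500.0,
                   duration: float = 1.0, c: float = 2.0, a: float = 15.0,
                   pad: float = 0.2, reversed: bool = True,
                   v_hold: float = -80.0) -> "ZapSpec":
        """Solve b, d, t_offset so the instantaneous frequency
        f(t) = b·c·t^(c−1)/2π sweeps f_low → f_high over ``duration``."""
        if not 0 < f_low < f_high:
            raise ValueError("need 0 < f_low < f_high")
        if c == 1.0:
            raise ValueError("c = 1 gives a constant frequency; use c > 1")
        ratio = (f_low / f_high) ** (1.0 / (c - 1.0))
        t_end = duration / (1.0 - ratio)
        t0 = t_end * ratio
        b = 2.0 * math.pi * f_high / (c * t_end ** (c - 1.0))
        d = -b * t0 ** c  # zero phase at sweep onset
        return cls(a=a, b=b, c=c, d=d, t_offset=t0, duration=duration,
                   pad=pad, reversed=reversed, v_hold=v_hold)


@dataclass(frozen=True)
class PulseSpec:
    """Step protocol (mV, ms fields): v_hold / v_cmd for pulse_dur."""

    v_hold: float = -90.0
    v_cmd: float = -20.0
    pulse_dur: float = 100.0
    pre_const: float = 20.0
    post_const: float = 100.0

    def __post_init__(self):
        if min(self.pulse_dur, self.pre_const, self.post_const) <= 0:
            raise ValueError("durations must be > 0")


@dataclass
class DffInputs:
    """Fluorescence trace F with baseline F0 and background Fb."""

    F: np.ndarray
    F0: float
    Fb: float

    def __post_init__(self):
        if self.F0 <= self.Fb:
            raise ValueError("F0 must exceed Fb")


def make_sine(spec: SineSpec, duration: float, dt: float) -> Waveform:
    """Sinusoidal command; requires at least 20 samples per cycle."""
    if dt > 1.0 / (20.0 * spec.f_sine):
        raise ValueError(f"dt {dt} undersamples a {spec.f_sine} Hz sine")
    t = np.arange(0.0, duration, dt)
    v = (spec.amplitude * np.sin(2 * np.pi * spec.f_sine * t + spec.phase)
         + spec.v_hold) * 1e-3
    return Waveform(t=t, v=v, dt=dt)


def make_zap(spec: ZapSpec, dt: float) -> Waveform:
    """Chirp with constant pads; reversed so high frequencies lead."""
    n_sweep = int(round(spec.duration / dt))
    ts = spec.t_offset + np.arange(n_sweep) * dt
    sweep = spec.a * np.sin(spec.b * ts ** spec.c + spec.d)
    if spec.reversed:
        sweep = sweep[::-1]
    n_pad = int(round(spec.pad / dt))
    v_rel = np.concatenate([np.zeros(n_pad), sweep, np.zeros(n_pad)])
    v = (v_rel + spec.v_hold) * 1e-3
    t = np.arange(len(v)) * dt
    return Waveform(t=t, v=v, dt=dt)


def make_pulse(spec: PulseSpec, dt: float) -> Waveform:
    """Constant pre-segment, step to v_cmd, constant post-segment."""
    n_pre = int(round(spec.pre_const * 1e-3 / dt))
    n_pulse = int(round(spec.pulse_dur * 1e-3 / dt))
    n_post = int(round(spec.post_const * 1e-3 / dt))
    v = np.concatenate([
        np.full(n_pre, spec.v_hold),
        np.full(n_pulse, spec.v_cmd),
        np.full(n_post, spec.v_hold),
    ]) * 1e-3
    t = np.arange(len(v)) * dt
    return Waveform(t=t, v=v, dt=dt)


def instantaneous_frequency(w: Waveform, v_hold: float):
    """Per-period frequency from holding-potential crossing times.

    Upward crossings of ``v_hold`` (mV) are located with linear interpolation
    between samples; each successive pair of upward crossings defines one full
    period.  Returns (t_mid, f_Hz) arrays.
    """
    level = v_hold * 1e-3
    s = w.v - level
    up = np.where((s[:-1] < 0) & (s[1:] >= 0))[0]
    if len(up) < 3:
        warnings.warn("fewer than 3 holding-level crossings; empty result")
        return np.array([]), np.array([])
    # sub-sample crossing times by linear interpolation
    frac = -s[up] / (s[up + 1] - s[up])
    t_cross = w.t[up] + frac * w.dt
    periods = np.diff(t_cross)
    f = 1.0 / periods
    t_mid = (t_cross[:-1] + t_cross[1:]) / 2.0
    return t_mid, f


def pn_subtract(response: TraceSet, leak_responses: list[TraceSet], scale: int) -> TraceSet:
    """P/N leak subtraction: response − scale·mean(leak responses)."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    n = len(response.i_electrode)
    for lr in leak_responses:
        if len(lr.i_electrode) != n:
            raise ValueError("leak response length mismatch")
    leak = np.mean([lr.i_electrode for lr in leak_responses], axis=0)
    return TraceSet(
        t=response.t.copy(),
        v_cmd=response.v_cmd.copy(),
        i_electrode=response.i_electrode - scale * leak,
        dt=response.dt,
    )


def dff(x: DffInputs) -> np.ndarray:
    """Relative fluorescence change (F − F0)/(F0 − Fb)."""
    return (np.asarray(x.F, dtype=float) - x.F0) / (x.F0 - x.Fb)
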