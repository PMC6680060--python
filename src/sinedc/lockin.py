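"""Sine+DC lock-in estimator for whole-cell capacitance measurements.

The estimator treats the recorded (or simulated) cell as the three-element
circuit Rs — (Rm ∥ Cm).  From the sinusoidal command V(t) = A·sin(ωt+α)+Vhold
and the current response I(t) = A1·sin(ωt+α) + A2·cos(ωt+α) + I_DC it forms
the normalized admittance components A = A1/A, B = A2/A and the DC
conductance Gt = I_DC/(Vhold − Erev), and inverts the circuit exactly:

    Cm = (1/(ωB)) · (A² + B² − A·Gt)² / ((A − Gt)² + B²)
    Rm = (1/Gt) · ((A − Gt)² + B²) / (A² + B² − A·Gt)
    Rs = (A − Gt) / (A² + B² − A·Gt)

On a genuine single-compartment RC cell this inverse is exact at every
frequency; on a branched neuron the result is the *apparent* Cm/Rm/Rs, whose
frequency and location dependence is the object of study.

Phase and component fits use quadrature projection over an integer number of
cycles (exact for noiseless sampled sines, no optimizer nondeterminism).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .cable import LinearCableSystem, input_admittance

__all__ = [
    "LockinConfig",
    "ComponentFit",
    "SineDCEstimate",
    "fit_phase",
    "fit_components",
    "sine_dc",
    "estimate_trace",
    "average_baseline",
    "delta_measurement",
    "accuracy",
    "estimate_from_system",
]


@dataclass(frozen=True)
class LockinConfig:
    """Averaging/windowing defaults of the measurement protocol.

    e_rev is the assumed reversal of the DC current: −60 mV matches the leak
    reversal in simulations; −15 mV is the physiological-recording default.
    A mismatch between e_rev and the true reversal is the leading source of
    Gt bias, so estimate_trace logs the value used.
    """

    e_rev: float = -60.0          # mV
    cycles_per_point: int = 1
    baseline_avg_cycles: int = 10
    baseline_lowpass: float = 20.0  # Hz
    pre_window: float = 1600.0      # ms
    post_window: float = 400.0      # ms

    def __post_init__(self):
        if self.pre_window <= 0 or self.post_window <= 0:
            raise ValueError("windows must be > 0")


@dataclass(frozen=True)
class ComponentFit:
    """Current decomposition at the stimulus frequency."""

    A1: float    # A, in-phase amplitude
    A2: float    # A, quadrature amplitude
    I_DC: float  # A
    alpha: float  # rad
    A: float     # S, A1 normalized by voltage amplitude
    B: float     # S, A2 normalized by voltage amplitude


@dataclass(frozen=True)
class SineDCEstimate:
    """Apparent circuit parameters from one Sine+DC inversion."""

    c_m: float   # pF
    r_m: float   # GΩ
    r_s: float   # MΩ
    g_t: float   # S
    f_sine: float  # Hz
    valid: bool = True

    @property
    def g_m(self) -> float:
        """nS"""
        return 1.0 / self.r_m if self.r_m != 0 else np.inf

    @property
    def g_s(self) -> float:
        """nS"""
        return 1e3 / self.r_s if self.r_s != 0 else np.inf


def fit_phase(v, f: float) -> float:
    """Phase α of the best-fit A·sin(2πft + α) + offset to a Waveform.

    Quadrature projection over the largest integer number of cycles; exact
    for a noiseless sampled sine.  α is returned in (−π, π].
    """
    t, x, dt = v.t, v.v, v.dt
    n_cyc = int(np.floor((t[-1] - t[0] + dt) * f))
    if n_cyc < 2:
        raise ValueError("need at least 2 full cycles to fit the phase")
    n = int(round(n_cyc / (f * dt)))
    t, x = t[:n], x[:n]
    w = 2 * np.pi * f
    s, c = np.sin(w * t), np.cos(w * t)
    a_s = 2.0 * np.mean((x - x.mean()) * s)
    a_c = 2.0 * np.mean((x - x.mean()) * c)
    amp = np.hypot(a_s, a_c)
    if amp < 1e-12:
        raise ValueError("waveform amplitude too small to determine a phase")
    return float(np.arctan2(a_c, a_s))


def fit_components(i, t, f: float, alpha: float, v_amplitude: float) -> ComponentFit:
    """Least-squares fit of A1·sin(ωt+α) + A2·cos(ωt+α) + I_DC to a current.

    ``i`` in A over times ``t`` (s); the window must span an integer number
    of cycles (to within one sample), otherwise spectral leakage would bias
    the DC term.  ``v_amplitude`` (V) normalizes A1, A2 into the admittance
    components A, B (S).
    """
    i = np.asarray(i, dtype=float)
    t = np.asarray(t, dtype=float)
    dt = t[1] - t[0]
    span = t[-1] - t[0] + dt
    n_cyc = span * f
    if abs(n_cyc - round(n_cyc)) > f * dt + 1e-9:
        raise ValueError(f"window spans {n_cyc:.4f} cycles; need an integer count")
    w = 2 * np.pi * f
    design = np.column_stack([np.sin(w * t + alpha), np.cos(w * t + alpha),
                              np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, i, rcond=None)
    a1, a2, idc = (float(c) for c in coef)
    return ComponentFit(A1=a1, A2=a2, I_DC=idc, alpha=alpha,
                        A=a1 / v_amplitude, B=a2 / v_amplitude)


def sine_dc(A: float, B: float, g_t: float, f: float) -> SineDCEstimate:
    """Invert the three-element circuit from normalized components (S).

    Precondition violations (B ≤ 0, A ≤ Gt, A²+B² ≤ A·Gt) yield an estimate
    flagged invalid rather than an exception: dendritic-recording protocols
    legitimately drive the apparent parameters out of range.
    """
    omega = 2 * np.pi * f
    denom1 = A * A + B * B - A * g_t
    denom2 = (A - g_t) ** 2 + B * B
    if B == 0 or denom1 <= 0 or denom2 <= 0 or g_t == 0:
        return SineDCEstimate(c_m=np.nan, r_m=np.nan, r_s=np.nan,
                              g_t=g_t, f_sine=f, valid=False)
    c_m = (1.0 / (omega * B)) * denom1 ** 2 / denom2
    r_m = (1.0 / g_t) * denom2 / denom1
    r_s = (A - g_t) / denom1
    valid = bool(B > 0 and A > g_t > 0)
    return SineDCEstimate(
        c_m=c_m * 1e12, r_m=r_m / 1e9, r_s=r_s / 1e6,
        g_t=g_t, f_sine=f, valid=valid,
    )


def estimate_trace(v, i_or_trace, f_sine: float, config: LockinConfig = LockinConfig(),
                   v_hold: float | None = None, settle_cycles: int = 0) -> pd.DataFrame:
    """Per-cycle Sine+DC estimates from a command waveform and current trace.

    ``v`` is the command Waveform (V), ``i_or_trace`` a current array (A) or
    TraceSet on the same sampling.  The first ``settle_cycles`` cycles are
    discarded.  Returns one row per analyzed cycle with columns
    t, c_m_pF, r_m_GOhm, r_s_MOhm, g_t_S, valid.
    """
    i = getattr(i_or_trace, "i_electrode", i_or_trace)
    alpha = fit_phase(v, f_sine)
    if v_hold is None:
        v_hold = float(np.mean(v.v)) * 1e3  # mV
    amp = _sine_amplitude(v, f_sine)
    dt = v.dt
    n_per = int(round(1.0 / (f_sine * dt)))
    if n_per < 4:
        raise ValueError("sampling too coarse for per-cycle analysis")
    n_cycles = len(i) // n_per
    rows = []
    drive = v_hold - config.e_rev  # mV
    if abs(drive) < 1e-9:
        raise ValueError("v_hold equals e_rev; Gt undefined")
    for k in range(settle_cycles, n_cycles):
        sl = slice(k * n_per, (k + 1) * n_per)
        fit = fit_components(i[sl], v.t[sl], f_sine, alpha, amp)
        g_t = fit.I_DC / (drive * 1e-3)
        est = sine_dc(fit.A, fit.B, g_t, f_sine)
        rows.append({
            "cycle": k,
            "t": float(v.t[k * n_per]),
            "c_m_pF": est.c_m,
            "r_m_GOhm": est.r_m,
            "r_s_MOhm": est.r_s,
            "g_t_S": est.g_t,
            "valid": est.valid,
        })
    df = pd.DataFrame(rows)
    df.attrs["e_rev_mV"] = config.e_rev
    df.attrs["v_hold_mV"] = v_hold
    df.attrs["f_sine_Hz"] = f_sine
    return df


def _sine_amplitude(v, f: float) -> float:
    """Amplitude (V) of the command sine via quadrature projection."""
    t, x, dt = v.t, v.v, v.dt
    n_cyc = int(np.floor((t[-1] - t[0] + dt) * f))
    n = int(round(n_cyc / (f * dt)))
    t, x = t[:n], x[:n]
    w = 2 * np.pi * f
    a_s = 2.0 * np.mean((x - x.mean()) * np.sin(w * t))
    a_c = 2.0 * np.mean((x - x.mean()) * np.cos(w * t))
    return float(np.hypot(a_s, a_c))


def average_baseline(series: pd.DataFrame, config: LockinConfig = LockinConfig()) -> pd.DataFrame:
    """Baseline processing: block-average cycles, then zero-phase low-pass.

    The per-cycle series (sampling rate = f_sine) is averaged in blocks of
    ``baseline_avg_cycles`` and filtered with a zero-phase 4th-order
    Butterworth at ``baseline_lowpass`` Hz where enough points exist.
    """
    n_avg = config.baseline_avg_cycles
    cols = ["c_m_pF", "r_m_GOhm", "r_s_MOhm", "g_t_S"]
    n_blocks = len(series) // n_avg
    if n_blocks == 0:
        raise ValueError("series shorter than one averaging block")
    out = {}
    trimmed = series.iloc[: n_blocks * n_avg]
    grp = np.repeat(np.arange(n_blocks), n_avg)
    for c in cols + ["t"]:
        out[c] = trimmed[c].groupby(grp).mean().to_numpy()
    df = pd.DataFrame(out)
    fs = series.attrs.get("f_sine_Hz", np.nan) / n_avg
    if np.isfinite(fs) and fs > 2.0 * config.baseline_lowpass and len(df) > 15:
        b, a = butter(4, config.baseline_lowpass / (fs / 2.0))
        for c in cols:
            df[c] = filtfilt(b, a, df[c].to_numpy())
    df.attrs.update(series.attrs)
    return df


def delta_measurement(pre: pd.DataFrame, post: pd.DataFrame,
                      config: LockinConfig = LockinConfig()) -> dict:
    """Stimulus-evoked changes: post-window mean minus pre-window mean.

    Uses the last ``pre_window`` ms of ``pre`` and the first ``post_window``
    ms of ``post`` (all rows if a window exceeds the available span).
    Returns ΔCm in fF, ΔRm in MΩ, ΔRs in kΩ, plus the conductance inverses
    ΔGm (nS) and ΔGs (nS).
    """
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("empty pre or post series")
    pre_w = pre[pre["t"] >= pre["t"].iloc[-1] - config.pre_window * 1e-3]
    post_w = post[post["t"] <= post["t"].iloc[0] + config.post_window * 1e-3]
    if len(pre_w) == 0 or len(post_w) == 0:
        raise ValueError("insufficient window data")

    def mean(df, c):
        return float(df[c].mean())

    d_cm = (mean(post_w, "c_m_pF") - mean(pre_w, "c_m_pF")) * 1e3      # fF
    d_rm = (mean(post_w, "r_m_GOhm") - mean(pre_w, "r_m_GOhm")) * 1e3  # MΩ
    d_rs = (mean(post_w, "r_s_MOhm") - mean(pre_w, "r_s_MOhm")) * 1e3  # kΩ
    d_gm = (1.0 / mean(post_w, "r_m_GOhm") - 1.0 / mean(pre_w, "r_m_GOhm"))  # nS
    d_gs = (1e3 / mean(post_w, "r_s_MOhm") - 1e3 / mean(pre_w, "r_s_MOhm"))  # nS
    return {"d_cm_fF": d_cm, "d_rm_MOhm": d_rm, "d_rs_kOhm": d_rs,
            "d_gm_nS": d_gm, "d_gs_nS": d_gs}


def accuracy(delta_measured: float, delta_theory: float) -> float:
    """Measured change divided by the implemented (theoretical) change."""
    if delta_theory == 0:
        raise ValueError("delta_theory must be nonzero")
    return delta_measured / delta_theory


def estimate_from_system(sys: LinearCableSystem, f: float,
                         v_hold: float = -80.0,
                         e_rev: float = -60.0) -> SineDCEstimate:
    """Frequency-domain Sine+DC estimate (the oracle engine).

    A and B come from the phasor input admittance at f; the DC conductance is
    Gt = I_DC/(Vhold − Erev) with I_DC = Y(0)·(Vhold − e_pas).  When the
    configured e_rev equals the cell's true leak reversal, Gt reduces to the
    DC input conductance.
    """
    y = input_admittance(sys, f)
    y0 = input_admittance(sys, 0.0).real
    e_pas_mV = float(sys.e_pas[sys.electrode_comp]) * 1e3
    drive = (v_hold - e_rev) * 1e-3
    if drive == 0:
        raise ValueError("v_hold equals e_rev; Gt undefined")
    i_dc = y0 * (v_hold - e_pas_mV) * 1e-3
    g_t = i_dc / drive
    return sine_dc(y.real, y.imag, g_t, f)
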