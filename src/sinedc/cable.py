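"""Passive compartmental cable system with a series-resistance clamp electrode.

The membrane of every compartment is a parallel RC (c = area·cm_spec,
g = area/rm_spec, reversal e_pas); compartments are linked by axial
conductances from the tapered-frustum integration in :mod:`.morphology`, and
optionally by gap-junction conductances between compartments of different
cells.  The voltage-clamp electrode is an ideal source in series with Rs
entering one compartment (no pipette capacitance).

Two solution paths are provided and must agree:

* time domain — fixed-step Crank–Nicolson (or backward Euler) integration of
  C·dV/dt = −G·V + b(t), returning the electrode current trace;
* frequency domain — the phasor system (G + iωC)·v = e·gs, giving the input
  admittance Y(f) seen by the ideal source through Rs.  This is the oracle
  for the lock-in estimator and the fast engine for parameter sweeps.

Internally everything is SI (V, A, S, F, s); constructors take conventional
units (mV, MΩ, µF/cm², kΩ·cm², Ω·cm) as stated per field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .morphology import DiscretizedCell

__all__ = [
    "PassiveParams",
    "Electrode",
    "LinearCableSystem",
    "TraceSet",
    "assemble",
    "steady_state",
    "simulate",
    "input_admittance",
    "TABLE1_PRESETS",
]


@dataclass(frozen=True)
class PassiveParams:
    """Specific passive parameters: cm µF/cm², rm kΩ·cm², ri Ω·cm, e_pas mV."""

    cm_spec: float = 0.9016
    rm_spec: float = 36.0
    ri: float = 224.0
    e_pas: float = -60.0

    def __post_init__(self):
        if self.cm_spec <= 0 or self.rm_spec <= 0 or self.ri <= 0:
            raise ValueError("cm_spec, rm_spec and ri must be positive")


# Best-fit passive parameters of the three reference cells.  cm_spec carries
# the per-cell precision used for the published ΔCm(theory) values
# (0.864/0.868/0.9016 µF/cm² for cells 2/12/13).
TABLE1_PRESETS = {
    2: PassiveParams(cm_spec=0.864, rm_spec=43.0, ri=223.0, e_pas=-60.0),
    12: PassiveParams(cm_spec=0.868, rm_spec=25.0, ri=223.0, e_pas=-60.0),
    13: PassiveParams(cm_spec=0.9016, rm_spec=36.0, ri=224.0, e_pas=-60.0),
}


@dataclass(frozen=True)
class Electrode:
    """Clamp electrode: series resistance (MΩ) and attachment site."""

    rs: float = 50.0
    site: tuple[int, int, float] = (0, 0, 0.5)  # (cell index, section id, pos)

    def __post_init__(self):
        if self.rs <= 0:
            raise ValueError("rs must be > 0")


@dataclass
class TraceSet:
    """Uniformly sampled command voltage and electrode current (SI units)."""

    t: np.ndarray      # s
    v_cmd: np.ndarray  # V
    i_electrode: np.ndarray  # A
    dt: float          # s

    def __post_init__(self):
        if not (len(self.t) == len(self.v_cmd) == len(self.i_electrode)):
            raise ValueError("trace channels must have equal length")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def save_txt(self, path):
        np.savetxt(
            path,
            np.column_stack([self.t, self.v_cmd, self.i_electrode]),
            header="t_s v_cmd_V i_electrode_A",
        )

    @classmethod
    def load_txt(cls, path):
        data = np.loadtxt(path)
        t = data[:, 0]
        return cls(t=t, v_cmd=data[:, 1], i_electrode=data[:, 2],
                   dt=float(t[1] - t[0]))


@dataclass
class LinearCableSystem:
    """Assembled linear system in SI units.

    ``g_total`` is the symmetric positive-definite conductance matrix: axial
    and gap-junction Laplacian, membrane leaks, electrode conductance and
    boundary conductances on the diagonal.  The constant part of the source
    vector (leak and boundary terms toward e_pas) lives in ``b_const``; the
    command voltage enters as gs·v_cmd at the electrode compartment.
    """

    c: np.ndarray             # F, per compartment
    g_total: sp.csc_matrix    # S
    b_const: np.ndarray       # A
    electrode_comp: int
    gs: float                 # S (1/Rs)
    e_pas: np.ndarray         # V per compartment
    n_cells: int = 1

    @property
    def n(self) -> int:
        return len(self.c)

    def summary(self) -> dict:
        y0 = input_admittance(self, 0.0)
        return {
            "n_compartments": self.n,
            "n_cells": self.n_cells,
            "total_capacitance_pF": float(self.c.sum() * 1e12),
            "input_resistance_MOhm": float(1.0 / y0.real / 1e6),
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=1)


def _compartment_index(cells, offsets, cell_idx, section_id, pos):
    return offsets[cell_idx] + cells[cell_idx].compartment_at(section_id, pos)


def assemble(
    cells: list[DiscretizedCell] | DiscretizedCell,
    passive: PassiveParams | list[PassiveParams],
    electrode: Electrode,
    gap_contacts=None,
    boundary_contacts=None,
) -> LinearCableSystem:
    """Build the linear system for one cell or a coupled network.

    ``gap_contacts``: iterable of (cell_a, (sec, pos), cell_b, (sec, pos),
    g_j in pS).  ``boundary_contacts``: iterable of (cell, (sec, pos), g_j in
    pS) — conductances clamped to the resting potential e_pas (open-boundary
    condition).
    """
    if isinstance(cells, DiscretizedCell):
        cells = [cells]
    if isinstance(passive, PassiveParams):
        passive = [passive] * len(cells)
    offsets = np.concatenate([[0], np.cumsum([c.n for c in cells])])[:-1]
    n = int(sum(c.n for c in cells))

    c = np.zeros(n)
    g_m = np.zeros(n)
    e_pas = np.zeros(n)
    rows, cols, vals = [], [], []

    for ci, (cell, pp) in enumerate(zip(cells, passive)):
        off = offsets[ci]
        areas = cell.areas()  # µm²
        c[off:off + cell.n] = areas * pp.cm_spec * 1e-14       # -> F
        g_m[off:off + cell.n] = areas / pp.rm_spec * 1e-11     # -> S
        e_pas[off:off + cell.n] = pp.e_pas * 1e-3              # -> V
        for i, j, g in cell.adjacency:
            rows += [off + i, off + j, off + i, off + j]
            cols += [off + j, off + i, off + i, off + j]
            vals += [-g, -g, g, g]

    if gap_contacts:
        for ca, site_a, cb, site_b, gj_pS in gap_contacts:
            i = _compartment_index(cells, offsets, ca, *site_a)
            j = _compartment_index(cells, offsets, cb, *site_b)
            if i == j:
                raise ValueError("gap contact links a compartment to itself")
            g = gj_pS * 1e-12
            rows += [i, j, i, j]
            cols += [j, i, i, j]
            vals += [-g, -g, g, g]

    g_bnd = np.zeros(n)
    if boundary_contacts:
        for ci, site, gj_pS in boundary_contacts:
            i = _compartment_index(cells, offsets, ci, *site)
            g_bnd[i] += gj_pS * 1e-12

    k = _compartment_index(cells, offsets, *electrode.site)
    gs = 1.0 / (electrode.rs * 1e6)

    lap = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    diag = sp.diags(g_m + g_bnd)
    g_total = (lap + diag + sp.coo_matrix(([gs], ([k], [k])), shape=(n, n))).tocsc()
    b_const = g_m * e_pas + g_bnd * e_pas

    return LinearCableSystem(
        c=c,
        g_total=g_total,
        b_const=b_const,
        electrode_comp=k,
        gs=gs,
        e_pas=e_pas,
        n_cells=len(cells),
    )


def steady_state(sys: LinearCableSystem, v_cmd: float):
    """DC solution with the command at ``v_cmd`` (mV).

    Returns (compartment voltages in mV, holding current in pA), where the
    holding current is (v_cmd − v_electrode)/Rs.
    """
    v_cmd_V = v_cmd * 1e-3
    b = sys.b_const.copy()
    b[sys.electrode_comp] += sys.gs * v_cmd_V
    v = spla.spsolve(sys.g_total, b)
    i_hold = sys.gs * (v_cmd_V - v[sys.electrode_comp])
    return v * 1e3, i_hold * 1e12


def simulate(sys: LinearCableSystem, stim, dt: float | None = None,
             method: str = "crank_nicolson") -> TraceSet:
    """Integrate the clamped system for the command waveform ``stim``.

    ``stim`` is a Waveform (t in s, v in V).  The state starts from the DC
    steady state at the first command sample.  Returns the electrode
    current trace at the stimulus sampling.
    """
    if dt is None:
        dt = stim.dt
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if abs(dt - stim.dt) > 1e-15:
        # resample the command onto the requested grid
        t = np.arange(stim.t[0], stim.t[-1] + dt / 2, dt)
        v_cmd = np.interp(t, stim.t, stim.v)
    else:
        t, v_cmd = stim.t, stim.v

    n = sys.n
    k = sys.electrode_comp
    C = sp.diags(sys.c).tocsc()
    G = sys.g_total

    # initial condition: steady state at the first command value
    b0 = sys.b_const.copy()
    b0[k] += sys.gs * v_cmd[0]
    v = spla.spsolve(G, b0)

    i_out = np.empty(len(t))
    i_out[0] = sys.gs * (v_cmd[0] - v[k])

    if method == "crank_nicolson":
        lhs = (C / dt + G / 2.0).tocsc()
        rhs_mat = (C / dt - G / 2.0).tocsc()
        solver = spla.splu(lhs)
        for m in range(1, len(t)):
            b = rhs_mat @ v + sys.b_const
            b[k] += sys.gs * 0.5 * (v_cmd[m - 1] + v_cmd[m])
            v = solver.solve(b)
            i_out[m] = sys.gs * (v_cmd[m] - v[k])
    elif method == "backward_euler":
        lhs = (C / dt + G).tocsc()
        solver = spla.splu(lhs)
        cdt = sys.c / dt
        for m in range(1, len(t)):
            b = cdt * v + sys.b_const
            b[k] += sys.gs * v_cmd[m]
            v = solver.solve(b)
            i_out[m] = sys.gs * (v_cmd[m] - v[k])
    else:
        raise ValueError(f"unknown method {method!r}")

    return TraceSet(t=t, v_cmd=v_cmd, i_electrode=i_out, dt=dt)


def input_admittance(sys: LinearCableSystem, f: float) -> complex:
    """Complex admittance Y(f) seen by the ideal source through Rs (S).

    Solves the phasor problem (G + iωC)·v = e_k·gs for a unit command and
    returns gs·(1 − v_k).  At f = 0 this equals the DC input conductance; the
    real and imaginary parts are the normalized in-phase and quadrature
    current components used by the Sine+DC estimator.
    """
    if f < 0:
        raise ValueError("f must be >= 0")
    k = sys.electrode_comp
    n = sys.n
    e = np.zeros(n)
    e[k] = sys.gs
    if f == 0.0:
        v = spla.spsolve(sys.g_total, e)
        return complex(sys.gs * (1.0 - v[k]))
    omega = 2.0 * np.pi * f
    A = (sys.g_total + 1j * omega * sp.diags(sys.c)).tocsc()
    v = spla.spsolve(A, e.astype(complex))
    return complex(sys.gs * (1.0 - v[k]))
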