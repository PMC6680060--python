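"""Synthetic AII-amacrine-like morphologies, RC fixtures and noisy traces.

Real AII amacrine cell reconstructions are not publicly deposited, so this
module generates stand-in morphologies that emulate the published emulation
targets: a soma with one thick apical dendrite descending along the −Y axis,
lobular appendages on short stalks at path distances spanning ~6–39 µm from
the soma center, a thin, recursively branching arboreal subtree below, and a
total membrane surface area calibrated to a target (2073 µm² for the
reference cell) by a global diameter scaling of the non-soma sections.

The generator does not attempt to match unpublished reconstruction
statistics; only surface area, lobular path distances and passive totals are
treated as constraints.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .morphology import (
    Morphology,
    MorphologyError,
    MorphSection,
    Point3D,
    surface_area,
)

__all__ = [
    "AiiGenParams",
    "NoiseSpec",
    "generate_aii",
    "generate_rc_cell",
    "add_current_noise",
    "generate_population",
]


@dataclass(frozen=True)
class AiiGenParams:
    """Generator knobs; defaults emulate the reference cell (#13 preset)."""

    soma_diam: float = 8.0
    apical_length: float = 22.0
    apical_diam_proximal: float = 2.5
    apical_diam_distal: float = 1.2
    n_lobular: int = 18
    lobular_diam: float = 1.5
    lobular_distance_range: tuple[float, float] = (6.0, 39.0)
    arboreal_depth_band: tuple[float, float] = (26.0, 64.0)
    arboreal_branch_orders: int = 6
    target_area: float = 2073.0
    seed: int = 13

    def __post_init__(self):
        if self.target_area <= 0:
            raise MorphologyError("target_area must be > 0")
        if self.n_lobular < 1:
            raise MorphologyError("n_lobular must be >= 1")
        lo, hi = self.lobular_distance_range
        if lo >= hi:
            raise MorphologyError("lobular distance range must be increasing")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian current noise (pA standard deviation)."""

    current_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.current_sd < 0:
            raise MorphologyError("current_sd must be >= 0")


# Lobular appendages sit on stalks off the apical dendrite.  Proximal ones
# use a minimal stalk; distal path distances are reached by longer stalk
# processes that run laterally (with a shallow downward pitch) rather than
# deeper, keeping the cell's depth within a realistic plexiform-layer span.
_STALK_LEN = 1.0        # µm, minimum
_STALK_MAX = 20.0       # µm, longest lateral stalk process
_STALK_DIAM = 0.5
_STALK_PITCH = math.radians(15.0)  # below horizontal
_APPENDAGE_LEN = 2.0

# per-order arboreal geometry: length (µm), diameter (µm), pitch from the
# vertical (deg).  Orders beyond the table reuse the last row.
_ARBOREAL_LEN = (14.0, 12.0, 10.0, 9.0, 8.0, 7.0)
_ARBOREAL_DIAM = (1.0, 0.8, 0.65, 0.5, 0.4, 0.35)
_ARBOREAL_PITCH = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0)


def generate_aii(params: AiiGenParams = AiiGenParams()) -> Morphology:
    """Generate one AII-like morphology, calibrated to ``params.target_area``."""
    p = params
    rng = np.random.default_rng(p.seed)
    soma_half = p.soma_diam / 2.0

    lo, hi = p.lobular_distance_range
    reach = soma_half + 0.9 * p.apical_length + _STALK_MAX + _APPENDAGE_LEN / 2.0
    if hi > reach:
        raise MorphologyError(
            f"lobular distance {hi} µm exceeds apical reach ({reach:.1f} µm)"
        )

    sections: dict[int, MorphSection] = {}
    next_id = [0]

    def add(parent, parent_pos, points, label) -> int:
        sid = next_id[0]
        next_id[0] += 1
        sections[sid] = MorphSection(
            id=sid, parent_id=parent, parent_pos=parent_pos, points=points, label=label
        )
        return sid

    # soma: cylinder along Y, length = diameter, centered at the origin
    soma_id = add(
        None,
        1.0,
        [
            Point3D(0, soma_half, 0, p.soma_diam),
            Point3D(0, 0, 0, p.soma_diam),
            Point3D(0, -soma_half, 0, p.soma_diam),
        ],
        "soma",
    )

    # apical dendrite: straight, descending, linear taper
    n_ap = max(int(p.apical_length / 2.0) + 1, 2)
    ys = np.linspace(-soma_half, -soma_half - p.apical_length, n_ap)
    ds = np.linspace(p.apical_diam_proximal, p.apical_diam_distal, n_ap)
    apical_id = add(
        soma_id, 1.0, [Point3D(0, y, 0, d) for y, d in zip(ys, ds)], "apical"
    )
    apical = sections[apical_id]
    L_ap = apical.length

    # lobular appendages: stalk + bulge at evenly spaced path distances
    targets = np.linspace(lo, hi, p.n_lobular)
    app_half = _APPENDAGE_LEN / 2.0
    for k, dist in enumerate(targets):
        # attachment arc s along the apical; any remaining path distance is
        # provided by a lateral stalk process of length >= _STALK_LEN
        s = min(max(dist - soma_half - _STALK_LEN - app_half, 0.1), 0.9 * L_ap)
        stalk_len = max(dist - soma_half - s - app_half, _STALK_LEN)
        pos = s / L_ap
        origin = apical.interp_at(pos)
        phi = rng.uniform(0, 2 * math.pi)
        ux = math.cos(phi) * math.cos(_STALK_PITCH)
        uz = math.sin(phi) * math.cos(_STALK_PITCH)
        uy = -math.sin(_STALK_PITCH)
        sx, sy, sz = origin.x, origin.y, origin.z
        n_stalk = max(int(stalk_len / 2.0) + 1, 2)
        ts = np.linspace(0.0, stalk_len, n_stalk)
        stalk_pts = [
            Point3D(sx + ux * t, sy + uy * t, sz + uz * t, _STALK_DIAM) for t in ts
        ]
        stalk_id = add(apical_id, pos, stalk_pts, "lobular_stalk")
        bx, by, bz = (sx + ux * stalk_len, sy + uy * stalk_len, sz + uz * stalk_len)
        frac = np.array([0.0, 0.3, 0.7, 1.0]) * _APPENDAGE_LEN
        diam = np.array([0.8, 1.0, 1.0, 0.55]) * p.lobular_diam
        app_pts = [
            Point3D(bx + ux * f, by + uy * f, bz + uz * f, d)
            for f, d in zip(frac, diam)
        ]
        add(stalk_id, 1.0, app_pts, "lobular_appendage")

    # arboreal subtree: recursive binary branching from the apical tip
    def grow(parent, parent_pos, base_xyz, azimuth, order):
        if order > p.arboreal_branch_orders:
            return
        i = min(order - 1, len(_ARBOREAL_LEN) - 1)
        L, d = _ARBOREAL_LEN[i], _ARBOREAL_DIAM[i]
        pitch = math.radians(_ARBOREAL_PITCH[i])
        az = azimuth + rng.uniform(-0.2, 0.2)
        dx = math.sin(pitch) * math.cos(az)
        dz = math.sin(pitch) * math.sin(az)
        dy = -math.cos(pitch)
        x0, y0, z0 = base_xyz
        npts = max(int(L / 2.0) + 1, 3)
        ts = np.linspace(0.0, L, npts)
        pts = [Point3D(x0 + dx * t, y0 + dy * t, z0 + dz * t, d) for t in ts]
        sid = add(parent, parent_pos, pts, "arboreal")
        tip = (x0 + dx * L, y0 + dy * L, z0 + dz * L)
        spread = math.pi / 2 ** min(order, 3)
        grow(sid, 1.0, tip, az - spread, order + 1)
        grow(sid, 1.0, tip, az + spread, order + 1)

    tip = apical.points[-1]
    root_az = rng.uniform(0, 2 * math.pi)
    grow(apical_id, 1.0, (tip.x, tip.y, tip.z), root_az, 1)
    grow(apical_id, 1.0, (tip.x, tip.y, tip.z), root_az + math.pi, 1)

    m = Morphology(sections=sections, soma_id=soma_id)
    return _calibrate_area(m, p.target_area)


def _calibrate_area(m: Morphology, target: float) -> Morphology:
    """Globally scale non-soma diameters so total area hits ``target``."""
    soma_id = m.soma_id
    base = {
        sid: [pt.diam for pt in sec.points]
        for sid, sec in m.sections.items()
        if sid != soma_id
    }

    def apply(scale: float):
        for sid, diams in base.items():
            sec = m.sections[sid]
            sec.points = [
                Point3D(pt.x, pt.y, pt.z, d * scale)
                for pt, d in zip(sec.points, diams)
            ]

    def objective(scale: float) -> float:
        apply(scale)
        return surface_area(m) - target

    lo_s, hi_s = 0.05, 20.0
    if objective(lo_s) > 0 or objective(hi_s) < 0:
        raise MorphologyError("area calibration out of range")
    s = brentq(objective, lo_s, hi_s, xtol=1e-10, rtol=1e-12)
    apply(s)
    return m


def generate_rc_cell(cm_total: float, rm_total: float):
    """Single-compartment fixture: (Morphology, PassiveParams).

    ``cm_total`` in pF, ``rm_total`` in GΩ.  The soma is a cylinder with
    length equal to its diameter whose area A satisfies A·cm_spec = cm_total
    exactly (cm_spec = 1 µF/cm²) and rm_spec = rm_total·A.
    """
    from .cable import PassiveParams

    if cm_total <= 0 or rm_total <= 0:
        raise MorphologyError("cm_total and rm_total must be > 0")
    cm_spec = 1.0  # µF/cm²
    area_um2 = cm_total * 1e2 / cm_spec  # pF / (µF/cm²) -> µm²
    # cylinder with L = d: area = π d² -> d
    d = math.sqrt(area_um2 / math.pi)
    half = d / 2.0
    soma = MorphSection(
        id=0,
        parent_id=None,
        points=[Point3D(0, half, 0, d), Point3D(0, -half, 0, d)],
        label="soma",
    )
    m = Morphology(sections={0: soma}, soma_id=0)
    # rm_total (GΩ) = rm_spec (kΩ·cm²) / area: rm_spec = rm_total·1e9 Ω · area_cm2 / 1e3
    area_cm2 = area_um2 * 1e-8
    rm_spec = rm_total * 1e9 * area_cm2 / 1e3  # kΩ·cm²
    passive = PassiveParams(cm_spec=cm_spec, rm_spec=rm_spec, ri=100.0, e_pas=-60.0)
    return m, passive


def add_current_noise(trace, spec: NoiseSpec):
    """Add seed-reproducible Gaussian noise (sd in pA) to the current channel."""
    from .cable import TraceSet

    if spec.current_sd == 0.0:
        return TraceSet(t=trace.t.copy(), v_cmd=trace.v_cmd.copy(),
                        i_electrode=trace.i_electrode.copy(), dt=trace.dt)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.current_sd * 1e-12, size=trace.i_electrode.shape)
    return TraceSet(
        t=trace.t.copy(),
        v_cmd=trace.v_cmd.copy(),
        i_electrode=trace.i_electrode + noise,
        dt=trace.dt,
    )


def generate_population(n: int, jitter_fraction: float, base: AiiGenParams) -> list[Morphology]:
    """n morphologies with multiplicatively jittered generator parameters."""
    if n < 1:
        raise MorphologyError("n must be >= 1")
    rng = np.random.default_rng(base.seed)
    cells = []
    for k in range(n):
        j = lambda v: float(v * (1.0 + jitter_fraction * rng.uniform(-1, 1)))
        lo, hi = base.lobular_distance_range
        params = replace(
            base,
            soma_diam=j(base.soma_diam),
            apical_length=j(base.apical_length),
            lobular_diam=j(base.lobular_diam),
            target_area=j(base.target_area),
            seed=int(base.seed + 1000 * (k + 1)),
        )
        cells.append(generate_aii(params))
    return cells
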