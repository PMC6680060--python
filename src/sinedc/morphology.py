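"""Branched neuronal morphologies: SWC I/O, measurement, perturbation, meshing.

A :class:`Morphology` is a tree of :class:`MorphSection` objects, each an
ordered chain of 3D reconstruction points with local diameters (µm).  Surface
areas are computed with the lateral frustum formula between consecutive
points.  :func:`discretize` applies the d_lambda rule — each segment shorter
than a fixed fraction of the AC length constant at a reference frequency —
and produces the compartment areas and axial resistances consumed by the
cable solver.

All geometry is in µm; axial resistances in the discretized cell are in Ω and
axial conductances in S (conventional reporting units; the cable solver
converts to SI internally).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Point3D",
    "MorphSection",
    "Morphology",
    "DiscretizationSpec",
    "DiscretizedCell",
    "read_swc",
    "write_swc",
    "surface_area",
    "path_distance",
    "increase_surface",
    "discretize",
    "morphology_summary",
    "SWC_TYPE_FOR_LABEL",
    "LABEL_FOR_SWC_TYPE",
]

# SWC has no concept of lobular structures; custom types >= 5 encode them.
SWC_TYPE_FOR_LABEL = {
    "soma": 1,
    "arboreal": 3,
    "apical": 4,
    "lobular_stalk": 5,
    "lobular_appendage": 6,
    "other": 7,
}
LABEL_FOR_SWC_TYPE = {v: k for k, v in SWC_TYPE_FOR_LABEL.items()}

LABELS = tuple(SWC_TYPE_FOR_LABEL)


class MorphologyError(ValueError):
    """Structural or validation problem in a morphology or SWC file."""


@dataclass(frozen=True)
class Point3D:
    """Reconstruction point: position (µm) and local diameter (µm)."""

    x: float
    y: float
    z: float
    diam: float

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z, self.diam)):
            raise MorphologyError("non-finite point coordinates")
        if self.diam <= 0:
            raise MorphologyError(f"non-positive diameter {self.diam}")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class MorphSection:
    """Unbranched chain of points; attaches to a parent at ``parent_pos``."""

    id: int
    parent_id: int | None
    points: list[Point3D]
    label: str = "other"
    parent_pos: float = 1.0

    def __post_init__(self):
        if self.label not in LABELS:
            raise MorphologyError(f"unknown label {self.label!r}")
        if self.parent_id == self.id:
            raise MorphologyError("section cannot be its own parent")
        if not 0.0 <= self.parent_pos <= 1.0:
            raise MorphologyError("parent_pos outside [0, 1]")
        if len(self.points) < 1:
            raise MorphologyError("section needs at least one point")

    # -- geometry helpers -------------------------------------------------

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each point, starting at 0."""
        if len(self.points) == 1:
            return np.zeros(1)
        xyz = np.array([p.xyz for p in self.points])
        steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length(self) -> float:
        return float(self.arc_lengths()[-1])

    def interp_at(self, pos: float) -> Point3D:
        """Point (position and diameter) at normalized arc position ``pos``."""
        if not 0.0 <= pos <= 1.0:
            raise MorphologyError(f"pos {pos} outside [0, 1]")
        arcs = self.arc_lengths()
        if arcs[-1] == 0.0:
            return self.points[0]
        s = pos * arcs[-1]
        i = int(np.searchsorted(arcs, s, side="right")) - 1
        i = min(max(i, 0), len(self.points) - 2)
        seg = arcs[i + 1] - arcs[i]
        f = 0.0 if seg == 0 else (s - arcs[i]) / seg
        a, b = self.points[i], self.points[i + 1]
        return Point3D(
            a.x + f * (b.x - a.x),
            a.y + f * (b.y - a.y),
            a.z + f * (b.z - a.z),
            a.diam + f * (b.diam - a.diam),
        )


@dataclass
class Morphology:
    """Tree of sections keyed by id, with a designated soma root."""

    sections: dict[int, MorphSection] = field(default_factory=dict)
    soma_id: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not self.sections:
            raise MorphologyError("morphology has no sections")
        if self.soma_id not in self.sections:
            raise MorphologyError("soma_id does not resolve")
        roots = [s for s in self.sections.values() if s.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        for s in self.sections.values():
            if s.parent_id is not None and s.parent_id not in self.sections:
                raise MorphologyError(f"section {s.id}: unresolved parent {s.parent_id}")
        # connectivity: walk up from every section to the root without cycles
        for s in self.sections.values():
            seen, cur = set(), s
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise MorphologyError("cycle in section graph")
                seen.add(cur.id)
                cur = self.sections[cur.parent_id]

    @property
    def root(self) -> MorphSection:
        return next(s for s in self.sections.values() if s.parent_id is None)

    def children_of(self, sec_id: int) -> list[MorphSection]:
        return [s for s in self.sections.values() if s.parent_id == sec_id]

    def sections_with_label(self, label: str) -> list[MorphSection]:
        return [s for s in self.sections.values() if s.label == label]

    def all_points(self) -> np.ndarray:
        """(n, 4) array of every reconstruction point: x, y, z, diam."""
        return np.array([[p.x, p.y, p.z, p.diam] for s in self.sections.values() for p in s.points])

    def translated(self, dx: float, dy: float, dz: float) -> "Morphology":
        secs = {}
        for sid, s in self.sections.items():
            pts = [Point3D(p.x + dx, p.y + dy, p.z + dz, p.diam) for p in s.points]
            secs[sid] = replace(s, points=pts)
        return Morphology(sections=secs, soma_id=self.soma_id)

    def copy(self) -> "Morphology":
        return self.translated(0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> Morphology:
    """Read a 7-column SWC file into a :class:`Morphology`.

    Radius (column 6) is doubled into local diameter.  Sections are cut at
    branch points and wherever the SWC type changes, so unbranched runs of a
    single type become a single section.  A child section's attachment
    position is the arc fraction of its parent point within the parent
    section.
    """
    rows: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise MorphologyError(f"{path}:{lineno}: expected 7 columns")
            pid, ptype = int(cols[0]), int(cols[1])
            x, y, z, r = (float(c) for c in cols[2:6])
            parent = int(cols[6])
            if r <= 0:
                raise MorphologyError(f"{path}:{lineno}: non-positive radius")
            if pid in rows:
                raise MorphologyError(f"{path}:{lineno}: duplicate point id {pid}")
            rows[pid] = (ptype, x, y, z, 2.0 * r, parent)
            order.append(pid)

    if not rows:
        raise MorphologyError(f"{path}: empty SWC file")
    for pid in order:
        parent = rows[pid][5]
        if parent != -1 and parent not in rows:
            raise MorphologyError(f"point {pid}: unresolvable parent id {parent}")

    children: dict[int, list[int]] = {pid: [] for pid in order}
    roots = []
    for pid in order:
        parent = rows[pid][5]
        if parent == -1:
            roots.append(pid)
        else:
            children[parent].append(pid)
    if len(roots) != 1:
        raise MorphologyError(f"expected one SWC root, found {len(roots)}")

    def to_point(pid):
        t, x, y, z, d, _ = rows[pid]
        return Point3D(x, y, z, d)

    sections: dict[int, MorphSection] = {}
    sec_of_point: dict[int, tuple[int, int]] = {}  # point id -> (section id, index)
    next_sec = [0]

    def new_section(start_pid, parent_sec, parent_pos):
        """Follow the same-type chain starting at ``start_pid``.

        The chain continues through a point as long as exactly one child has
        the same SWC type (other children branch off as new sections); two or
        more same-type children mark a branch point and end the chain.
        """
        sid = next_sec[0]
        next_sec[0] += 1
        stype = rows[start_pid][0]
        chain = [start_pid]
        cur = start_pid
        while True:
            same = [k for k in children[cur] if rows[k][0] == stype]
            if len(same) == 1:
                cur = same[0]
                chain.append(cur)
            else:
                break
        pts = [to_point(p) for p in chain]
        sections[sid] = MorphSection(
            id=sid,
            parent_id=parent_sec,
            points=pts,
            label=LABEL_FOR_SWC_TYPE.get(stype, "other"),
            parent_pos=parent_pos,
        )
        for i, p in enumerate(chain):
            sec_of_point[p] = (sid, i)
        # recurse into children of every chain point that starts a new section
        for p in chain:
            for kid in children[p]:
                if kid in chain:
                    continue
                arcs = sections[sid].arc_lengths()
                idx = chain.index(p)
                pos = 1.0 if arcs[-1] == 0 else float(arcs[idx] / arcs[-1])
                new_section(kid, sid, pos)

    new_section(roots[0], None, 1.0)
    soma = [sid for sid, s in sections.items() if s.label == "soma"]
    soma_id = soma[0] if soma else sections[0].id
    return Morphology(sections=sections, soma_id=soma_id)


def write_swc(m: Morphology, path) -> None:
    """Write ``m`` as 7-column SWC (labels encoded per the documented map)."""
    if not m.sections:
        raise MorphologyError("cannot write empty morphology")
    m.validate()
    lines = ["# SWC written by sinedc; types: " + json.dumps(SWC_TYPE_FOR_LABEL)]
    next_id = [1]
    last_ids: dict[tuple[int, int], int] = {}  # (section, point index) -> SWC id

    def emit(sec: MorphSection, parent_swc: int):
        stype = SWC_TYPE_FOR_LABEL[sec.label]
        prev = parent_swc
        for i, p in enumerate(sec.points):
            pid = next_id[0]
            next_id[0] += 1
            lines.append(
                f"{pid} {stype} {p.x:.17g} {p.y:.17g} {p.z:.17g} "
                f"{p.diam / 2.0:.17g} {prev}"
            )
            last_ids[(sec.id, i)] = pid
            prev = pid
        for child in sorted(m.children_of(sec.id), key=lambda s: s.id):
            arcs = sec.arc_lengths()
            # attach to the parent point nearest the requested arc position
            idx = int(np.argmin(np.abs(arcs / max(arcs[-1], 1e-12) - child.parent_pos)))
            emit(child, last_ids[(sec.id, idx)])

    emit(m.root, -1)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------

def _frustum_area(d1: float, d2: float, length: float) -> float:
    r1, r2 = d1 / 2.0, d2 / 2.0
    slant = math.sqrt(length * length + (r2 - r1) ** 2)
    return math.pi * (r1 + r2) * slant


def _section_area(sec: MorphSection, lo: float = 0.0, hi: float = 1.0) -> float:
    """Lateral frustum area of a section over arc fraction [lo, hi].

    Single-point sections (point somata) are treated as a cylinder with
    length equal to its diameter, hence area π·d².
    """
    if len(sec.points) == 1:
        d = sec.points[0].diam
        return math.pi * d * d * (hi - lo)
    arcs = sec.arc_lengths()
    total = arcs[-1]
    if total == 0.0:
        return 0.0
    s_lo, s_hi = lo * total, hi * total
    area = 0.0
    for i in range(len(sec.points) - 1):
        a, b = arcs[i], arcs[i + 1]
        seg = b - a
        if seg <= 0:
            continue
        left, right = max(a, s_lo), min(b, s_hi)
        if right <= left:
            continue
        d1, d2 = sec.points[i].diam, sec.points[i + 1].diam
        fa, fb = (left - a) / seg, (right - a) / seg
        da = d1 + fa * (d2 - d1)
        db = d1 + fb * (d2 - d1)
        area += _frustum_area(da, db, right - left)
    return area


def surface_area(m: Morphology, section_subset=None) -> float:
    """Total membrane surface area in µm² (optionally over a section subset)."""
    if section_subset is not None:
        ids = list(section_subset)
        if not ids:
            warnings.warn("empty section subset: surface area is 0")
            return 0.0
    else:
        ids = list(m.sections)
    return float(sum(_section_area(m.sections[i]) for i in ids))


def _soma_center_pos(soma: MorphSection) -> float:
    return 0.5


def path_distance(m: Morphology, section: int, pos: float = 0.5) -> float:
    """Arc distance (µm) from the soma center to (section, pos).

    The origin is the arc midpoint of the soma section.  Distances accumulate
    along section arcs through each attachment point.
    """
    if section not in m.sections:
        raise MorphologyError(f"no section {section}")
    if not 0.0 <= pos <= 1.0:
        raise MorphologyError("pos outside [0, 1]")
    soma = m.sections[m.soma_id]

    def dist_to_soma_center(sec_id: int, p: float) -> float:
        sec = m.sections[sec_id]
        if sec_id == m.soma_id:
            return abs(p - _soma_center_pos(soma)) * sec.length
        if sec.parent_id is None:
            # rootless-of-soma tree: measure from the root start
            return p * sec.length
        return p * sec.length + dist_to_soma_center(sec.parent_id, sec.parent_pos)

    return float(dist_to_soma_center(section, pos))


def _with_point_at(sec: MorphSection, frac: float, tol: float = 1e-9) -> None:
    """Insert an interpolated reconstruction point at arc fraction ``frac``
    unless one already sits there (in place)."""
    arcs = sec.arc_lengths()
    total = arcs[-1]
    if total == 0.0:
        return
    fracs = arcs / total
    if np.any(np.abs(fracs - frac) < tol):
        return
    p = sec.interp_at(frac)
    idx = int(np.searchsorted(fracs, frac))
    sec.points.insert(idx, p)


def increase_surface(m: Morphology, section: int, rng=(0.0, 1.0), delta_area: float = 0.0) -> Morphology:
    """Return a copy with diameters in ``rng`` of ``section`` scaled so the
    total surface area grows by ``delta_area`` µm² (within 1e-3 µm²).

    Boundary points are interpolated into the section at the range edges so
    that arbitrary sub-ranges can be perturbed regardless of the original
    point spacing.
    """
    if section not in m.sections:
        raise MorphologyError(f"no section {section}")
    lo, hi = float(rng[0]), float(rng[1])
    if not (0.0 <= lo < hi <= 1.0):
        raise MorphologyError("degenerate or invalid range")
    if delta_area < 0:
        raise MorphologyError("delta_area must be >= 0")
    out = m.copy()
    if delta_area == 0.0:
        return out
    sec = out.sections[section]
    if len(sec.points) > 1:
        if sec.length == 0.0:
            raise MorphologyError("cannot scale a zero-length section")
        _with_point_at(sec, lo)
        _with_point_at(sec, hi)
    arcs = sec.arc_lengths()
    total = arcs[-1]
    fracs = arcs / total if total > 0 else np.zeros(len(sec.points))
    inside = [(lo - 1e-9) <= f <= (hi + 1e-9) for f in fracs]
    if len(sec.points) == 1:
        inside = [True]
    base = [p.diam for p in sec.points]
    a0 = surface_area(out)

    def scaled(scale: float):
        sec.points = [
            Point3D(p.x, p.y, p.z, d * scale if ins else d)
            for p, d, ins in zip(sec.points, base, inside)
        ]

    def objective(scale: float) -> float:
        scaled(scale)
        return surface_area(out) - a0 - delta_area

    hi_scale = 2.0
    while objective(hi_scale) < 0:
        hi_scale *= 2.0
        if hi_scale > 1e6:
            raise MorphologyError("cannot reach requested delta_area")
    s = brentq(objective, 1.0, hi_scale, xtol=1e-12, rtol=1e-12)
    scaled(s)
    return out


# ---------------------------------------------------------------------------
# Discretization (d_lambda rule)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizationSpec:
    """d_lambda rule: segments shorter than d_lambda·λ(f_ref)."""

    d_lambda: float = 0.1
    f_ref: float = 100.0

    def __post_init__(self):
        if not 0.0 < self.d_lambda <= 1.0:
            raise MorphologyError("d_lambda outside (0, 1]")
        if self.f_ref <= 0:
            raise MorphologyError("f_ref must be > 0")


def lambda_ac(diam_um: float, f_hz: float, ri_ohm_cm: float, cm_uf_cm2: float) -> float:
    """AC length constant in µm (diam µm, Ri Ω·cm, cm µF/cm², f Hz)."""
    return 1e5 * 0.5 * math.sqrt(diam_um / (math.pi * f_hz * ri_ohm_cm * cm_uf_cm2))


@dataclass
class Compartment:
    section_id: int
    center_pos: float  # normalized [0, 1] along the section
    area: float        # µm²
    r_half_prox: float  # Ω, center to proximal segment boundary
    r_half_dist: float  # Ω, center to distal segment boundary


@dataclass
class DiscretizedCell:
    """Compartments at segment centers plus tree adjacency (conductance in S)."""

    compartments: list[Compartment]
    adjacency: list[tuple[int, int, float]]
    nseg: dict[int, int]
    morphology: Morphology

    @property
    def n(self) -> int:
        return len(self.compartments)

    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.compartments])

    def compartment_at(self, section_id: int, pos: float) -> int:
        """Index of the compartment whose center is nearest (section, pos)."""
        best, best_d = None, None
        for i, c in enumerate(self.compartments):
            if c.section_id != section_id:
                continue
            d = abs(c.center_pos - pos)
            if best is None or d < best_d:
                best, best_d = i, d
        if best is None:
            raise MorphologyError(f"no compartments on section {section_id}")
        return best


def _axial_resistance(sec: MorphSection, lo: float, hi: float, ri_ohm_cm: float) -> float:
    """Axial resistance (Ω) over arc fraction [lo, hi], exact for linear taper.

    For a frustum piece with end radii ra, rb and length L (µm):
    R = Ri·L / (π·ra·rb) · 1e4 with Ri in Ω·cm.
    """
    if hi <= lo:
        return 0.0
    if len(sec.points) == 1:
        d = sec.points[0].diam
        L = d * (hi - lo)  # point soma treated as cylinder of length = diam
        r = d / 2.0
        return ri_ohm_cm * L / (math.pi * r * r) * 1e4
    arcs = sec.arc_lengths()
    total = arcs[-1]
    if total == 0.0:
        return 0.0
    s_lo, s_hi = lo * total, hi * total
    res = 0.0
    for i in range(len(sec.points) - 1):
        a, b = arcs[i], arcs[i + 1]
        seg = b - a
        if seg <= 0:
            continue
        left, right = max(a, s_lo), min(b, s_hi)
        if right <= left:
            continue
        r1, r2 = sec.points[i].diam / 2.0, sec.points[i + 1].diam / 2.0
        fa, fb = (left - a) / seg, (right - a) / seg
        ra = r1 + fa * (r2 - r1)
        rb = r1 + fb * (r2 - r1)
        res += ri_ohm_cm * (right - left) / (math.pi * ra * rb) * 1e4
    return res


def _section_mean_diam(sec: MorphSection) -> float:
    if len(sec.points) == 1:
        return sec.points[0].diam
    arcs = sec.arc_lengths()
    total = arcs[-1]
    if total == 0:
        return sec.points[0].diam
    w = np.diff(arcs)
    d = np.array([p.diam for p in sec.points])
    mid = (d[:-1] + d[1:]) / 2.0
    return float(np.sum(mid * w) / total)


def _nseg_for(length: float, lam: float, d_lambda: float) -> int:
    """Smallest odd positive integer n with length / n < d_lambda·λ."""
    if length == 0.0:
        return 1
    n = int(math.floor(length / (d_lambda * lam))) + 1
    if n % 2 == 0:
        n += 1
    return n


def discretize(m: Morphology, spec: DiscretizationSpec, passive) -> DiscretizedCell:
    """Mesh ``m`` into compartments per the d_lambda rule.

    ``passive`` provides ``ri`` (Ω·cm) and ``cm_spec`` (µF/cm²).  Compartments
    sit at segment centers; adjacent compartments are linked by the series sum
    of their facing half-segment axial resistances.
    """
    comps: list[Compartment] = []
    adjacency: list[tuple[int, int, float]] = []
    nseg_map: dict[int, int] = {}
    index_of: dict[tuple[int, int], int] = {}  # (section, segment) -> comp index

    ordered = _tree_order(m)
    for sec in ordered:
        L = sec.length if len(sec.points) > 1 else sec.points[0].diam
        if L == 0.0:
            warnings.warn(f"section {sec.id} has zero length; collapsed into parent")
            nseg = 1
        else:
            lam = lambda_ac(_section_mean_diam(sec), spec.f_ref, passive.ri, passive.cm_spec)
            nseg = _nseg_for(L, lam, spec.d_lambda)
        nseg_map[sec.id] = nseg
        for k in range(nseg):
            lo, hi = k / nseg, (k + 1) / nseg
            center = (lo + hi) / 2.0
            comp = Compartment(
                section_id=sec.id,
                center_pos=center,
                area=_section_area(sec, lo, hi),
                r_half_prox=_axial_resistance(sec, lo, center, passive.ri),
                r_half_dist=_axial_resistance(sec, center, hi, passive.ri),
            )
            index_of[(sec.id, k)] = len(comps)
            comps.append(comp)
        for k in range(nseg - 1):
            i, j = index_of[(sec.id, k)], index_of[(sec.id, k + 1)]
            r = comps[i].r_half_dist + comps[j].r_half_prox
            adjacency.append((i, j, 1.0 / r if r > 0 else math.inf))

    # connect each child section to its parent at parent_pos
    for sec in ordered:
        if sec.parent_id is None:
            continue
        parent = m.sections[sec.parent_id]
        pn = nseg_map[parent.id]
        pos = sec.parent_pos
        pk = min(int(pos * pn), pn - 1)
        pi = index_of[(parent.id, pk)]
        pc = comps[pi]
        # resistance from the parent compartment center to the attachment point
        if pos >= pc.center_pos:
            r_parent = _axial_resistance(parent, pc.center_pos, pos, passive.ri)
        else:
            r_parent = _axial_resistance(parent, pos, pc.center_pos, passive.ri)
        ci = index_of[(sec.id, 0)]
        r = r_parent + comps[ci].r_half_prox
        adjacency.append((pi, ci, 1.0 / r if r > 0 else math.inf))

    return DiscretizedCell(compartments=comps, adjacency=adjacency, nseg=nseg_map, morphology=m)


def _tree_order(m: Morphology) -> list[MorphSection]:
    """Sections in root-first order."""
    out, stack = [], [m.root]
    while stack:
        sec = stack.pop()
        out.append(sec)
        stack.extend(sorted(m.children_of(sec.id), key=lambda s: -s.id))
    return out


def morphology_summary(m: Morphology) -> dict:
    """JSON-ready report: total and per-label areas, lobular path distances."""
    per_label = {}
    for label in LABELS:
        ids = [s.id for s in m.sections_with_label(label)]
        if ids:
            per_label[label] = surface_area(m, ids)
    lobular = {
        s.id: path_distance(m, s.id, 0.5) for s in m.sections_with_label("lobular_appendage")
    }
    return {
        "total_area_um2": surface_area(m),
        "area_by_label_um2": per_label,
        "n_sections": len(m.sections),
        "lobular_path_distances_um": lobular,
    }
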