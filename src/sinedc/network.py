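"""Hexagonally coupled cell networks with sector-based gap-junction placement.

Identical copies of one morphology sit on a 5×5 trapezoidal hexagonal grid
(interior cells have six neighbors).  For each neighbor pair, N contact
points are drawn from the reconstruction points inside a 120° sector of the
XZ plane facing the neighbor (apex at the projected center of mass) and a
height band along Y, sorted by height and paired by rank; each contact gets
the pairwise junctional conductance divided by N.  Edge cells receive the
same complement of contacts toward each missing neighbor, clamped to the
resting potential ("open boundary").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cable import Electrode, PassiveParams, assemble
from .lockin import estimate_from_system
from .morphology import DiscretizationSpec, Morphology, discretize

__all__ = [
    "GridLayout",
    "SectorSpec",
    "ContactPoint",
    "NetworkModel",
    "make_grid",
    "center_of_mass",
    "sector_candidates",
    "sector_points",
    "build_network",
    "assemble_network",
    "measure_network",
]

# axial-coordinate offsets of the six hexagonal neighbors, with their bearing
# in the XZ plane for a trapezoidal (sheared-row) grid
_HEX_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))


@dataclass(frozen=True)
class GridLayout:
    rows: int
    cols: int
    spacing: float  # µm
    positions: tuple[tuple[float, float], ...]  # (x, z) per cell
    neighbor_pairs: tuple[tuple[int, int], ...]
    center: int

    def index(self, row: int, col: int) -> int:
        return row * self.cols + col

    def neighbors_of(self, idx: int) -> list[int]:
        out = []
        for a, b in self.neighbor_pairs:
            if a == idx:
                out.append(b)
            elif b == idx:
                out.append(a)
        return out

    def bearing(self, a: int, b: int) -> float:
        """Direction (deg in the XZ plane) from cell a toward cell b."""
        ax, az = self.positions[a]
        bx, bz = self.positions[b]
        return math.degrees(math.atan2(bz - az, bx - ax))

    def missing_directions(self, idx: int) -> list[float]:
        """Bearings of absent hexagonal neighbors (edge cells only)."""
        row, col = divmod(idx, self.cols)
        out = []
        for dc, dr in _HEX_OFFSETS:
            r2, c2 = row + dr, col + dc
            if not (0 <= r2 < self.rows and 0 <= c2 < self.cols):
                x1, z1 = self._pos(row, col)
                x2, z2 = self._pos(r2, c2)
                out.append(math.degrees(math.atan2(z2 - z1, x2 - x1)))
        return out

    def _pos(self, row, col):
        return ((col + 0.5 * row) * self.spacing,
                row * self.spacing * math.sqrt(3) / 2.0)


def make_grid(rows: int = 5, cols: int = 5, spacing: float = 30.0) -> GridLayout:
    """Trapezoidal hexagonal grid; every interior cell has six neighbors."""
    positions = []
    for r in range(rows):
        for c in range(cols):
            positions.append(((c + 0.5 * r) * spacing, r * spacing * math.sqrt(3) / 2.0))
    pairs = set()
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            for dc, dr in _HEX_OFFSETS:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    j = r2 * cols + c2
                    pairs.add((min(i, j), max(i, j)))
    center = (rows // 2) * cols + cols // 2
    return GridLayout(rows=rows, cols=cols, spacing=spacing,
                      positions=tuple(positions),
                      neighbor_pairs=tuple(sorted(pairs)), center=center)


@dataclass(frozen=True)
class SectorSpec:
    """Contact-placement rule: 120° sector, Y height band, N contacts."""

    theta: float = 120.0
    height_band: tuple[float, float] = (-78.0, -40.0)
    n_contacts: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.theta <= 360:
            raise ValueError("theta outside (0, 360]")
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")


@dataclass(frozen=True)
class ContactPoint:
    cell_a: int
    cell_b: int               # -1 marks an open-boundary contact
    site_a: tuple[int, float]  # (section id, pos)
    site_b: tuple[int, float] | None
    g_j: float                # pS


@dataclass
class NetworkModel:
    layout: GridLayout
    morphology: Morphology
    contacts: list[ContactPoint]
    boundary_contacts: list[ContactPoint]
    sector: SectorSpec
    g_pair: float  # pS

    def to_json(self) -> str:
        return json.dumps({
            "rows": self.layout.rows,
            "cols": self.layout.cols,
            "spacing": self.layout.spacing,
            "g_pair_pS": self.g_pair,
            "seed": self.sector.seed,
            "n_contacts": self.sector.n_contacts,
            "contacts": [
                {"a": c.cell_a, "b": c.cell_b, "site_a": list(c.site_a),
                 "site_b": list(c.site_b) if c.site_b else None, "g_j_pS": c.g_j}
                for c in self.contacts + self.boundary_contacts
            ],
        }, indent=1)


def center_of_mass(m: Morphology) -> np.ndarray:
    """Unweighted mean of all reconstruction points (x, y, z)."""
    pts = m.all_points()
    return pts[:, :3].mean(axis=0)


def _candidate_points(m: Morphology):
    """(section id, pos, x, y, z) for every reconstruction point."""
    out = []
    for sec in m.sections.values():
        arcs = sec.arc_lengths()
        total = arcs[-1]
        for i, p in enumerate(sec.points):
            pos = 0.5 if total == 0 else float(arcs[i] / total)
            out.append((sec.id, pos, p.x, p.y, p.z))
    return out


def sector_candidates(m: Morphology, direction: float,
                      spec: SectorSpec) -> list[tuple[int, float, float]]:
    """All reconstruction points inside the sector: (section id, pos, y).

    ``direction`` is the sector bisector (deg, XZ plane, apex at the
    projected center of mass); the angular interval is half-open,
    [direction − θ/2, direction + θ/2), so adjacent sectors partition the
    plane.  Candidates are restricted to Y within the height band.
    """
    com = center_of_mass(m)
    y_lo, y_hi = min(spec.height_band), max(spec.height_band)
    half = spec.theta / 2.0
    cands = []
    for sec_id, pos, x, y, z in _candidate_points(m):
        if not (y_lo <= y <= y_hi):
            continue
        ang = math.degrees(math.atan2(z - com[2], x - com[0]))
        rel = (ang - direction + half) % 360.0
        if 0.0 <= rel < spec.theta:
            cands.append((sec_id, pos, y))
    return cands


def sector_points(m: Morphology, direction: float, spec: SectorSpec,
                  n: int | None = None) -> list[tuple[int, float]]:
    """Seeded sample of sector candidate points, sorted ascending by height.

    ``n`` defaults to spec.n_contacts.  Returns [(section id, pos), ...].
    """
    n = spec.n_contacts if n is None else n
    cands = sector_candidates(m, direction, spec)
    if len(cands) < n:
        raise ValueError(
            f"sector at {direction:.0f}° has only {len(cands)} candidate points "
            f"(need {n})"
        )
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(cands), size=n, replace=False)
    chosen = sorted((cands[i] for i in idx), key=lambda c: c[2])
    return [(sec_id, pos) for sec_id, pos, _ in chosen]


def _pair_seed(base: int, a: int, b: int, side: int) -> int:
    return (base * 1000003 + a * 10007 + b * 101 + side) % (2**31 - 1)


def build_network(m: Morphology, layout: GridLayout, g_pair: float,
                  spec: SectorSpec) -> NetworkModel:
    """Place gap-junction contacts for every neighbor pair and the boundary.

    Per-contact conductance is g_pair/n_contacts.  The two point sets of a
    pair are drawn in the sectors facing each other and matched by height
    rank, so contacts join processes at comparable depths.
    """
    contacts: list[ContactPoint] = []
    g_each = g_pair / spec.n_contacts
    for a, b in layout.neighbor_pairs:
        dir_ab = layout.bearing(a, b)
        dir_ba = layout.bearing(b, a)
        pts_a = sector_points(m, dir_ab, _with_seed(spec, _pair_seed(spec.seed, a, b, 0)))
        pts_b = sector_points(m, dir_ba, _with_seed(spec, _pair_seed(spec.seed, a, b, 1)))
        for sa, sb in zip(pts_a, pts_b):
            contacts.append(ContactPoint(cell_a=a, cell_b=b, site_a=sa,
                                         site_b=sb, g_j=g_each))
    boundary: list[ContactPoint] = []
    for idx in range(layout.rows * layout.cols):
        for k, direction in enumerate(layout.missing_directions(idx)):
            pts = sector_points(
                m, direction, _with_seed(spec, _pair_seed(spec.seed, idx, 7919 + k, 2))
            )
            for site in pts:
                boundary.append(ContactPoint(cell_a=idx, cell_b=-1,
                                             site_a=site, site_b=None, g_j=g_each))
    return NetworkModel(layout=layout, morphology=m, contacts=contacts,
                        boundary_contacts=boundary, sector=spec, g_pair=g_pair)


def _with_seed(spec: SectorSpec, seed: int) -> SectorSpec:
    return SectorSpec(theta=spec.theta, height_band=spec.height_band,
                      n_contacts=spec.n_contacts, seed=seed)


def assemble_network(model: NetworkModel, passive: PassiveParams,
                     electrode: Electrode,
                     disc: DiscretizationSpec = DiscretizationSpec()):
    """Discretize once, replicate per cell, and assemble the coupled system."""
    cell = discretize(model.morphology, disc, passive)
    n_cells = model.layout.rows * model.layout.cols
    cells = [cell] * n_cells
    gap = [(c.cell_a, c.site_a, c.cell_b, c.site_b, c.g_j) for c in model.contacts]
    bnd = [(c.cell_a, c.site_a, c.g_j) for c in model.boundary_contacts]
    return assemble(cells, passive, electrode, gap_contacts=gap,
                    boundary_contacts=bnd)


def measure_network(model: NetworkModel, passive: PassiveParams,
                    f_list, rs_list, v_hold: float = -80.0,
                    e_rev: float = -60.0,
                    disc: DiscretizationSpec = DiscretizationSpec(),
                    electrode_site: tuple[int, float] | None = None) -> pd.DataFrame:
    """Sine+DC estimates on the center cell over a frequency × Rs grid.

    Uses the frequency-domain engine (proven equivalent to time-domain
    integration by the solver's oracle tests).  ``electrode_site`` defaults
    to the soma center of the center cell.
    """
    soma = model.morphology.soma_id
    site = electrode_site or (soma, 0.5)
    rows = []
    for rs in rs_list:
        electrode = Electrode(rs=rs, site=(model.layout.center, site[0], site[1]))
        sys = assemble_network(model, passive, electrode, disc)
        for f in f_list:
            est = estimate_from_system(sys, f, v_hold=v_hold, e_rev=e_rev)
            rows.append({
                "f_Hz": f, "rs_MOhm": rs, "g_pair_pS": model.g_pair,
                "c_m_pF": est.c_m, "r_m_GOhm": est.r_m, "r_s_MOhm": est.r_s,
                "valid": est.valid,
            })
    return pd.DataFrame(rows)
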