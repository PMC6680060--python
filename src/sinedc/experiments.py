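"""Simulation campaigns: frequency sweeps, lobular perturbations, networks.

Each function builds the systems it needs, runs the Sine+DC estimator over a
condition grid and returns a long-format pandas DataFrame with full
provenance columns.  The default engine is the frequency-domain oracle
(identical to time-domain integration within the solver's tested tolerance
and orders of magnitude faster for grids); time-domain spot checks live in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cable import Electrode, PassiveParams, assemble
from .lockin import accuracy, estimate_from_system
from .morphology import (
    DiscretizationSpec,
    Morphology,
    discretize,
    increase_surface,
    path_distance,
    surface_area,
)
from .network import SectorSpec, build_network, make_grid, measure_network

__all__ = [
    "SweepConfig",
    "run_baseline_sweep",
    "run_lobular_delta",
    "run_distance_analysis",
    "run_param_variants",
    "run_network_experiment",
    "run_dendritic_recording",
    "delta_cm_theory_fF",
    "delta_rm_theory_MOhm",
]

DEFAULT_FREQS = (100.0, 200.0, 400.0, 1000.0, 2000.0, 4000.0, 5000.0, 10000.0)
DEFAULT_RS = (1.0, 50.0, 250.0)
DEFAULT_GJ = (0.0, 100.0, 200.0, 400.0, 700.0, 800.0, 1600.0, 3200.0, 5000.0)


@dataclass(frozen=True)
class SweepConfig:
    """Shared condition grid for the simulation campaigns."""

    f_list: tuple = DEFAULT_FREQS
    rs_list: tuple = DEFAULT_RS
    gj_list: tuple = DEFAULT_GJ
    delta_area_list: tuple = (0.1, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)
    v_hold: float = -80.0   # mV
    amplitude: float = 15.0  # mV peak
    e_rev: float = -60.0    # mV
    d_lambda: float = 0.01
    f_ref: float = 100.0
    seed: int = 13

    def __post_init__(self):
        if not (self.f_list and self.rs_list and self.gj_list):
            raise ValueError("condition lists must be nonempty")

    @property
    def disc(self) -> DiscretizationSpec:
        return DiscretizationSpec(d_lambda=self.d_lambda, f_ref=self.f_ref)


def delta_cm_theory_fF(delta_area_um2: float, cm_spec: float) -> float:
    """Implemented capacitance increase: ΔA·cm_spec (µm², µF/cm² → fF)."""
    return delta_area_um2 * cm_spec * 10.0


def delta_rm_theory_MOhm(area_um2: float, delta_area_um2: float, rm_spec: float) -> float:
    """Expected ΔRm from adding ΔA of membrane with the same rm_spec.

    The whole-cell resistance Rm = rm_spec/area in parallel with the patch
    resistance rm_spec/ΔA; the change is −Rm²/(Rm + Rpatch), in MΩ.
    """
    rm = rm_spec * 1e3 / (area_um2 * 1e-8)        # Ω
    rp = rm_spec * 1e3 / (delta_area_um2 * 1e-8)  # Ω
    return -(rm * rm / (rm + rp)) / 1e6


def _isolated_system(m: Morphology, passive: PassiveParams, rs: float,
                     disc: DiscretizationSpec, site=None):
    cell = discretize(m, disc, passive)
    soma_site = site or (m.soma_id, 0.5)
    electrode = Electrode(rs=rs, site=(0, soma_site[0], soma_site[1]))
    return assemble(cell, passive, electrode)


def run_baseline_sweep(cell: Morphology, passive: PassiveParams,
                       config: SweepConfig = SweepConfig()) -> pd.DataFrame:
    """Apparent Cm/Rm/Rs versus frequency × Rs for an isolated cell."""
    area = surface_area(cell)
    cm_theory = area * passive.cm_spec * 1e-2            # pF
    rm_theory = passive.rm_spec * 1e3 / (area * 1e-8) / 1e9  # GΩ
    rows = []
    for rs in config.rs_list:
        sys = _isolated_system(cell, passive, rs, config.disc)
        for f in config.f_list:
            est = estimate_from_system(sys, f, config.v_hold, config.e_rev)
            rows.append({
                "f_Hz": f, "rs_MOhm": rs,
                "c_m_pF": est.c_m, "r_m_GOhm": est.r_m, "r_s_MOhm": est.r_s,
                "c_m_theory_pF": cm_theory, "r_m_theory_GOhm": rm_theory,
                "cm_accuracy": est.c_m / cm_theory,
                "valid": est.valid,
            })
    return pd.DataFrame(rows)


def run_lobular_delta(cell: Morphology, passive: PassiveParams,
                      lobular_ids, delta_area_list=None,
                      config: SweepConfig = SweepConfig()) -> pd.DataFrame:
    """ΔCm/ΔRm/ΔRs per (site, ΔA, f, Rs) for single-site surface increases."""
    deltas = config.delta_area_list if delta_area_list is None else tuple(delta_area_list)
    rows = []
    for rs in config.rs_list:
        base = _isolated_system(cell, passive, rs, config.disc)
        base_est = {f: estimate_from_system(base, f, config.v_hold, config.e_rev)
                    for f in config.f_list}
        for sec_id in lobular_ids:
            dist = path_distance(cell, sec_id, 0.5)
            for dA in deltas:
                perturbed = increase_surface(cell, sec_id, (0.0, 1.0), dA)
                sys_p = _isolated_system(perturbed, passive, rs, config.disc)
                theory = delta_cm_theory_fF(dA, passive.cm_spec)
                for f in config.f_list:
                    e0, e1 = base_est[f], estimate_from_system(
                        sys_p, f, config.v_hold, config.e_rev)
                    d_cm = (e1.c_m - e0.c_m) * 1e3
                    rows.append({
                        "section": sec_id, "distance_um": dist,
                        "delta_area_um2": dA, "f_Hz": f, "rs_MOhm": rs,
                        "d_cm_fF": d_cm,
                        "d_rm_MOhm": (e1.r_m - e0.r_m) * 1e3,
                        "d_rs_kOhm": (e1.r_s - e0.r_s) * 1e3,
                        "d_cm_theory_fF": theory,
                        "accuracy": accuracy(d_cm, theory),
                    })
    return pd.DataFrame(rows)


def run_distance_analysis(cell: Morphology, passive: PassiveParams,
                          config: SweepConfig = SweepConfig(),
                          delta_area: float = 0.5,
                          rs: float | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ΔCm versus path distance for every lobular appendage, plus line fits.

    Also runs the simultaneous all-site increase and reports the additivity
    of single-site responses.  Returns (per-site table, per-frequency fits).
    """
    rs = config.rs_list[1] if rs is None and len(config.rs_list) > 1 else (rs or config.rs_list[0])
    lobulars = [s.id for s in cell.sections_with_label("lobular_appendage")]
    if len(lobulars) < 2:
        raise ValueError("need at least two lobular appendages")
    single = run_lobular_delta(
        cell, passive, lobulars, (delta_area,),
        replace(config, rs_list=(rs,)),
    )
    # simultaneous increase at every lobular
    perturbed = cell
    for sec_id in lobulars:
        perturbed = increase_surface(perturbed, sec_id, (0.0, 1.0), delta_area)
    base = _isolated_system(cell, passive, rs, config.disc)
    sys_p = _isolated_system(perturbed, passive, rs, config.disc)
    fits = []
    for f in config.f_list:
        sub = single[single["f_Hz"] == f]
        slope, intercept = np.polyfit(sub["distance_um"], sub["d_cm_fF"], 1)
        e0 = estimate_from_system(base, f, config.v_hold, config.e_rev)
        e1 = estimate_from_system(sys_p, f, config.v_hold, config.e_rev)
        simultaneous = (e1.c_m - e0.c_m) * 1e3
        fits.append({
            "f_Hz": f,
            "slope_fF_per_um": slope,
            "intercept_fF": intercept,
            "sum_of_singles_fF": float(sub["d_cm_fF"].sum()),
            "simultaneous_fF": simultaneous,
            "total_theory_fF": delta_cm_theory_fF(delta_area, passive.cm_spec) * len(lobulars),
        })
    return single, pd.DataFrame(fits)


def run_param_variants(cell: Morphology, passive: PassiveParams,
                       config: SweepConfig = SweepConfig(),
                       rm_high: float = 200.0, ri_low: float = 70.0,
                       lobular_ids=None) -> pd.DataFrame:
    """Baseline sweeps (and optional ΔCm sweeps) for the 2×2 Rm × Ri variants."""
    variants = {
        "original": passive,
        "rm_high": replace(passive, rm_spec=rm_high),
        "ri_low": replace(passive, ri=ri_low),
        "rm_high_ri_low": replace(passive, rm_spec=rm_high, ri=ri_low),
    }
    frames = []
    for name, pp in variants.items():
        df = run_baseline_sweep(cell, pp, config)
        df["variant"] = name
        if lobular_ids:
            dd = run_lobular_delta(cell, pp, lobular_ids, (0.5,),
                                   replace(config, rs_list=(config.rs_list[0],)))
            dd = dd.rename(columns={"accuracy": "delta_accuracy"})
            dd["variant"] = name
            frames.append(dd)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_network_experiment(cell: Morphology, passive: PassiveParams,
                           config: SweepConfig = SweepConfig(),
                           sector: SectorSpec | None = None,
                           lobular_ids=None,
                           rs: float | None = None) -> pd.DataFrame:
    """Baseline and center-cell ΔCm over the junctional-conductance grid."""
    layout = make_grid(5, 5)
    sector = sector or _default_sector(cell, config.seed)
    rs = rs or (config.rs_list[1] if len(config.rs_list) > 1 else config.rs_list[0])
    frames = []
    for gj in config.gj_list:
        model = build_network(cell, layout, gj, sector)
        base = measure_network(model, passive, config.f_list, [rs],
                               config.v_hold, config.e_rev, config.disc)
        base["kind"] = "baseline"
        base["section"] = -1
        frames.append(base)
        for sec_id in (lobular_ids or []):
            perturbed = increase_surface(cell, sec_id, (0.0, 1.0), 0.5)
            model_p = build_network(perturbed, layout, gj, sector)
            post = measure_network(model_p, passive, config.f_list, [rs],
                                   config.v_hold, config.e_rev, config.disc)
            d = base[["f_Hz", "rs_MOhm"]].copy()
            d["g_pair_pS"] = gj
            d["d_cm_fF"] = (post["c_m_pF"].to_numpy() - base["c_m_pF"].to_numpy()) * 1e3
            d["d_cm_theory_fF"] = delta_cm_theory_fF(0.5, passive.cm_spec)
            d["kind"] = "delta"
            d["section"] = sec_id
            frames.append(d)
    return pd.concat(frames, ignore_index=True)


def _default_sector(cell: Morphology, seed: int) -> SectorSpec:
    """Height band for gap-junction contacts: the deeper half of the
    plexiform span below the soma (strata S3 proximal part through S5)."""
    pts = cell.all_points()
    y_min = float(pts[:, 1].min())
    soma = cell.sections[cell.soma_id]
    y_border = min(p.y for p in soma.points)
    hi = y_min + 0.5 * (y_border - y_min)
    return SectorSpec(height_band=(y_min, hi), seed=seed)


def run_dendritic_recording(cell: Morphology, passive: PassiveParams,
                            config: SweepConfig = SweepConfig(),
                            f_max: float = 40000.0,
                            delta_area: float = 0.5,
                            rs: float | None = None,
                            lobular_ids=None) -> pd.DataFrame:
    """ΔCm versus frequency with the electrode on each lobular appendage.

    Flags negative ΔCm at each frequency and reports the crossover frequency
    (first sign change from negative to positive) per recording site.
    """
    rs = rs or (config.rs_list[1] if len(config.rs_list) > 1 else config.rs_list[0])
    f_list = sorted({*config.f_list, 20000.0, f_max})
    f_list = [f for f in f_list if f <= f_max]
    lobulars = (list(lobular_ids) if lobular_ids is not None
                else [s.id for s in cell.sections_with_label("lobular_appendage")])
    rows = []
    for sec_id in lobulars:
        site = (sec_id, 0.5)
        base = _isolated_system(cell, passive, rs, config.disc, site=site)
        perturbed = increase_surface(cell, sec_id, (0.0, 1.0), delta_area)
        sys_p = _isolated_system(perturbed, passive, rs, config.disc, site=site)
        theory = delta_cm_theory_fF(delta_area, passive.cm_spec)
        d_by_f = []
        for f in f_list:
            e0 = estimate_from_system(base, f, config.v_hold, config.e_rev)
            e1 = estimate_from_system(sys_p, f, config.v_hold, config.e_rev)
            d_by_f.append((f, (e1.c_m - e0.c_m) * 1e3))
        crossover = _crossover_frequency(d_by_f)
        for f, d_cm in d_by_f:
            rows.append({
                "section": sec_id, "f_Hz": f, "rs_MOhm": rs,
                "d_cm_fF": d_cm, "d_cm_theory_fF": theory,
                "negative": d_cm < 0,
                "crossover_Hz": crossover,
            })
    return pd.DataFrame(rows)


def _crossover_frequency(d_by_f) -> float:
    """First frequency where ΔCm turns from negative to positive (NaN if none)."""
    prev_f, prev_d = None, None
    for f, d in d_by_f:
        if prev_d is not None and prev_d < 0 <= d:
            return f
        prev_f, prev_d = f, d
    return float("nan")
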