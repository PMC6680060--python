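"""Shared fixtures: one calibrated synthetic cell, meshes and systems.

Session scope keeps the suite fast: the generated morphology and its
discretizations are reused by every module's tests.
"""

import numpy as np
import pytest

import sinedc as sd


@pytest.fixture(scope="session")
def aii():
    """Calibrated synthetic AII-like morphology (reference-cell defaults)."""
    return sd.generate_aii(sd.AiiGenParams())


@pytest.fixture(scope="session")
def preset13():
    return sd.TABLE1_PRESETS[13]


@pytest.fixture(scope="session")
def preset12():
    return sd.TABLE1_PRESETS[12]


@pytest.fixture(scope="session")
def disc_fine():
    return sd.DiscretizationSpec(d_lambda=0.01, f_ref=100.0)


@pytest.fixture(scope="session")
def aii_cell(aii, disc_fine, preset13):
    return sd.discretize(aii, disc_fine, preset13)


@pytest.fixture(scope="session")
def aii_sys(aii, aii_cell, preset13):
    """Isolated cell, somatic electrode, Rs = 50 MΩ."""
    return sd.assemble(aii_cell, preset13,
                       sd.Electrode(rs=50.0, site=(0, aii.soma_id, 0.5)))


@pytest.fixture(scope="session")
def rc_cell():
    """(morphology, passive) for a 10 pF / 1 GΩ single-compartment fixture."""
    return sd.generate_rc_cell(10.0, 1.0)


@pytest.fixture(scope="session")
def rc_sys(rc_cell):
    m, pp = rc_cell
    cell = sd.discretize(m, sd.DiscretizationSpec(), pp)
    return sd.assemble(cell, pp, sd.Electrode(rs=10.0, site=(0, 0, 0.5)))


@pytest.fixture(scope="session")
def lobular_ids(aii):
    """Lobular appendage section ids sorted by path distance from the soma."""
    ids = [s.id for s in aii.sections_with_label("lobular_appendage")]
    return sorted(ids, key=lambda i: sd.path_distance(aii, i, 0.5))


@pytest.fixture(scope="session")
def aii_trace_2k(aii_sys):
    """Time-domain AII response to 10 analyzed cycles of a 2 kHz sine."""
    f, dt = 2000.0, 1e-6
    settle = 20  # cycles; clamp settling is ~1 ms << 10 ms
    w = sd.make_sine(sd.SineSpec(f_sine=f, amplitude=15.0, v_hold=-80.0),
                     (settle + 10) / f, dt)
    tr = sd.simulate(aii_sys, w, dt)
    return w, tr, f, settle
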