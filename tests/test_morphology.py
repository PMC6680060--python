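"""Geometry, SWC round-trips, surface perturbation and the d_lambda mesh."""

import math

import numpy as np
import pytest

import sinedc as sd
from sinedc.morphology import (
    MorphologyError,
    MorphSection,
    Point3D,
    lambda_ac,
)


def _cylinder(length=10.0, diam=1.0, n=11, label="soma", sec_id=0, parent=None):
    pts = [Point3D(0.0, -x, 0.0, diam) for x in np.linspace(0, length, n)]
    return MorphSection(id=sec_id, parent_id=parent, points=pts, label=label)


@pytest.fixture
def cylinder_morph():
    return sd.Morphology(sections={0: _cylinder()}, soma_id=0)


class TestSurfaceArea:
    def test_cylinder(self, cylinder_morph):
        # π·d·L = π·1·10
        assert sd.surface_area(cylinder_morph) == pytest.approx(31.41592653589793)

    def test_frustum(self):
        # hand evaluation: π(r1+r2)·sqrt(L² + (r2−r1)²), diam 1→2 over L=3
        sec = MorphSection(
            id=0, parent_id=None,
            points=[Point3D(0, 0, 0, 1.0), Point3D(0, -3, 0, 2.0)], label="soma",
        )
        m = sd.Morphology(sections={0: sec}, soma_id=0)
        expect = math.pi * 1.5 * math.sqrt(9 + 0.25)
        assert sd.surface_area(m) == pytest.approx(expect)
        assert expect == pytest.approx(14.33, abs=5e-3)

    def test_point_soma_convention(self):
        # single-point soma = cylinder with L = diam: area π d²
        sec = MorphSection(id=0, parent_id=None,
                           points=[Point3D(0, 0, 0, 8.0)], label="soma")
        m = sd.Morphology(sections={0: sec}, soma_id=0)
        assert sd.surface_area(m) == pytest.approx(math.pi * 64.0)

    def test_empty_subset_warns(self, cylinder_morph):
        with pytest.warns(UserWarning):
            assert sd.surface_area(cylinder_morph, []) == 0.0

    def test_calibrated_cell_area(self, aii):
        # generator calibration target for the reference reconstruction
        assert sd.surface_area(aii) == pytest.approx(2073.0, rel=0.02)


class TestSwcIO:
    def test_minimal_three_line(self, tmp_path):
        p = tmp_path / "min.swc"
        p.write_text(
            "# comment\n"
            "1 1 0 0 0 4 -1\n"
            "2 3 0 -4 0 0.5 1\n"
            "3 3 0 -14 0 0.5 2\n"
        )
        m = sd.read_swc(p)
        assert m.root.label == "soma"
        kids = m.children_of(m.root.id)
        assert len(kids) == 1 and len(kids[0].points) == 2

    def test_roundtrip(self, aii, tmp_path):
        p = tmp_path / "cell.swc"
        sd.write_swc(aii, p)
        back = sd.read_swc(p)
        assert len(back.sections) == len(aii.sections)
        assert sd.surface_area(back) == pytest.approx(sd.surface_area(aii), rel=1e-9)

        def canon(m):
            return sorted(
                (s.label, len(s.points),
                 tuple(np.round([c for pt in s.points
                                 for c in (pt.x, pt.y, pt.z, pt.diam)], 5)))
                for s in m.sections.values()
            )

        assert canon(back) == canon(aii)

    def test_unresolvable_parent(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 4 99\n")
        with pytest.raises(MorphologyError):
            sd.read_swc(p)

    def test_nonpositive_radius(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 0 -1\n")
        with pytest.raises(MorphologyError):
            sd.read_swc(p)

    def test_labels_encoded(self, aii, tmp_path):
        p = tmp_path / "cell.swc"
        sd.write_swc(aii, p)
        back = sd.read_swc(p)
        for label in ("soma", "apical", "lobular_stalk", "lobular_appendage", "arboreal"):
            assert len(back.sections_with_label(label)) == len(
                aii.sections_with_label(label))


class TestPathDistance:
    def test_soma_center_is_origin(self, aii):
        assert sd.path_distance(aii, aii.soma_id, 0.5) == pytest.approx(0.0)

    def test_additivity_along_chain(self):
        soma = _cylinder(length=8.0, diam=8.0, n=3)
        a = _cylinder(length=10.0, n=3, label="apical", sec_id=1, parent=0)
        b = _cylinder(length=10.0, n=3, label="arboreal", sec_id=2, parent=1)
        m = sd.Morphology(sections={0: soma, 1: a, 2: b}, soma_id=0)
        # soma center to distal tip: half soma (4) + 10 + 10
        assert sd.path_distance(m, 2, 1.0) == pytest.approx(24.0)
        # additive: distance(mid of b) = distance(end of a) + 5
        assert sd.path_distance(m, 2, 0.5) == pytest.approx(
            sd.path_distance(m, 1, 1.0) + 5.0)

    def test_lobular_span(self, aii, lobular_ids):
        d = [sd.path_distance(aii, i, 0.5) for i in lobular_ids]
        assert min(d) < 8.0 and max(d) > 35.0
        assert all(5.0 <= x <= 41.0 for x in d)

    def test_pos_validation(self, aii):
        with pytest.raises(MorphologyError):
            sd.path_distance(aii, aii.soma_id, 1.5)


class TestIncreaseSurface:
    def test_cylinder_analytic(self, cylinder_morph):
        # ΔA over a full cylinder: d' = d + ΔA/(πL); L=2, d=1, ΔA=0.5
        sec = _cylinder(length=2.0, diam=1.0, n=3)
        m = sd.Morphology(sections={0: sec}, soma_id=0)
        out = sd.increase_surface(m, 0, (0.0, 1.0), 0.5)
        new_d = out.sections[0].points[0].diam
        assert new_d == pytest.approx(1.0 + 0.5 / (math.pi * 2.0), rel=1e-6)

    def test_zero_delta_is_identity(self, aii):
        out = sd.increase_surface(aii, aii.soma_id, (0.0, 1.0), 0.0)
        assert np.allclose(out.all_points(), aii.all_points())

    def test_original_unmodified(self, aii, lobular_ids):
        before = sd.surface_area(aii)
        sd.increase_surface(aii, lobular_ids[0], (0.0, 1.0), 1.0)
        assert sd.surface_area(aii) == before

    def test_random_triples_hit_target(self, aii):
        rng = np.random.default_rng(7)
        ids = list(aii.sections)
        a0 = sd.surface_area(aii)
        for _ in range(25):
            sec = int(rng.choice(ids))
            npts = len(aii.sections[sec].points)
            if npts < 2:
                continue
            a, b = sorted(rng.uniform(0, 1, 2))
            if b - a < 0.3:
                continue
            dA = float(rng.uniform(0.05, 2.0))
            out = sd.increase_surface(aii, sec, (a, b), dA)
            got = sd.surface_area(out) - a0
            assert got == pytest.approx(dA, rel=1e-3, abs=1e-3)

    def test_missing_section(self, aii):
        with pytest.raises(MorphologyError):
            sd.increase_surface(aii, 10_000, (0.0, 1.0), 0.5)


class TestDiscretize:
    def test_lambda100_value(self):
        # d = 1 µm, Ri = 224 Ω·cm, cm = 0.9 µF/cm², f = 100 Hz -> ~199 µm
        assert lambda_ac(1.0, 100.0, 224.0, 0.9) == pytest.approx(198.7, abs=0.5)

    @pytest.mark.parametrize("d_lambda", [0.1, 0.01])
    def test_area_conserved(self, aii, preset13, d_lambda):
        cell = sd.discretize(aii, sd.DiscretizationSpec(d_lambda, 100.0), preset13)
        assert cell.areas().sum() == pytest.approx(sd.surface_area(aii), rel=1e-3)

    def test_nseg_odd_and_monotone(self, aii, preset13):
        coarse = sd.discretize(aii, sd.DiscretizationSpec(0.1, 100.0), preset13)
        fine = sd.discretize(aii, sd.DiscretizationSpec(0.05, 100.0), preset13)
        for sid, n in coarse.nseg.items():
            assert n % 2 == 1
            assert fine.nseg[sid] >= n

    def test_adjacency_is_tree(self, aii_cell):
        # a tree over n nodes has exactly n−1 edges
        assert len(aii_cell.adjacency) == aii_cell.n - 1

    def test_refinement_convergence(self, aii, preset13):
        """Admittance converges under mesh refinement (≤0.5% from 0.01 to 0.003).

        Comparing d_lambda 0.1 against 0.01 cannot meet this bound at 10 kHz
        for any second-order scheme (segments of 0.1·λ100 are ~0.8·λ10k), so
        convergence is demonstrated from the 0.01 mesh downward.
        """
        el = sd.Electrode(rs=50.0, site=(0, aii.soma_id, 0.5))
        sys_a = sd.assemble(
            sd.discretize(aii, sd.DiscretizationSpec(0.01, 100.0), preset13),
            preset13, el)
        sys_b = sd.assemble(
            sd.discretize(aii, sd.DiscretizationSpec(0.003, 100.0), preset13),
            preset13, el)
        for f in (100.0, 1000.0, 10000.0):
            ya, yb = sd.input_admittance(sys_a, f), sd.input_admittance(sys_b, f)
            assert abs(ya - yb) / abs(yb) < 5e-3
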