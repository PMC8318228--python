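"""Programmed behaviours: retargeting, constriction, lumen repulsion."""

import numpy as np
import pytest

import blastomech as bm
from blastomech import behaviors, mechanics
from blastomech.behaviors import (
    LumenSource,
    apical_constriction_targets,
    lumen_repulsion_force,
    open_lumen,
    positional_constriction_profile,
    retarget_shape,
)
from blastomech.cell_mesh import APICAL, CellShapeSpec, layout_local
from blastomech.neighborhoods import Population


CUBOIDAL = CellShapeSpec(apical_radius=0.5, height=1.0)
COLUMNAR = CellShapeSpec(apical_radius=0.5, height=2.0)


def build_pop(spec=CUBOIDAL):
    pop = Population()
    pop.add_cell(bm.build_epithelial_cell(spec), "TE", (0, 0, 0))
    pop.rebuild_cell_pairs()
    return pop


class TestRetargetShape:
    def test_identity_retarget_changes_nothing(self):
        pop = build_pop(COLUMNAR)
        before = pop.sp_req.copy()
        retarget_shape(pop, 0, COLUMNAR)
        assert np.allclose(pop.sp_req, before, atol=1e-12)
        assert mechanics.elastic_energy(pop) == pytest.approx(0.0, abs=1e-20)

    def test_elongation_doubles_axial_spring_targets(self):
        """Cuboidal -> columnar: ring-to-ring (axial) equilibrium lengths
        double while in-ring chords are unchanged."""
        pop = build_pop(CUBOIDAL)
        cell = pop.cells[0]
        before = pop.sp_req.copy()
        retarget_shape(pop, 0, COLUMNAR)
        d = pop.pos[pop.sp_j] - pop.pos[pop.sp_i]
        dz = np.abs(d[:, 2])
        dxy = np.linalg.norm(d[:, :2], axis=1)
        membrane = pop.sp_j < cell.nucleus
        axial = membrane & (dz > 0.1) & (dxy < 1e-9)
        same_ring = membrane & (dz < 1e-9)
        assert axial.sum() == 3 * 8  # one vertical strut per azimuth per gap
        assert np.allclose(pop.sp_req[axial] / before[axial], 2.0, rtol=1e-9)
        assert np.allclose(pop.sp_req[same_ring], before[same_ring],
                           atol=1e-12)

    def test_positions_untouched_by_retarget(self):
        pop = build_pop(CUBOIDAL)
        before = pop.pos.copy()
        retarget_shape(pop, 0, COLUMNAR)
        assert np.array_equal(pop.pos, before)

    def test_relaxation_reaches_target_height(self, params):
        pop = build_pop(CUBOIDAL)
        retarget_shape(pop, 0, COLUMNAR)
        mechanics.relax(pop, params, tol=1e-10, max_steps=50_000)
        cell = pop.cells[0]
        height = abs(pop.pos[cell.m_stop - 1, 2] - pop.pos[cell.m_start, 2])
        assert abs(height - 2.0) / 2.0 < 0.05

    def test_incompatible_mesh_family_rejected(self):
        pop = build_pop(CUBOIDAL)
        with pytest.raises(ValueError, match="incompatible mesh family"):
            retarget_shape(pop, 0, CellShapeSpec(n_vertices=42, basis="square"))


class TestApicalConstriction:
    def test_zero_shrinkage_changes_nothing(self):
        pop = build_pop(COLUMNAR)
        before = pop.sp_req.copy()
        apical_constriction_targets(pop, 0, 0.0)
        assert np.allclose(pop.sp_req, before, atol=1e-15)

    def test_full_constriction_collapses_apical_chords(self):
        """d = R sends apical-ring chord equilibrium lengths to zero."""
        pop = build_pop(COLUMNAR)
        cell = pop.cells[0]
        apical_constriction_targets(pop, 0, cell.spec.apical_radius)
        ring = set(range(cell.m_start + 1, cell.m_start + 9))
        chords = [(k, i, j) for k, (i, j) in enumerate(zip(pop.sp_i, pop.sp_j))
                  if int(i) in ring and int(j) in ring]
        assert chords
        for k, _, _ in chords:
            assert pop.sp_req[k] == pytest.approx(0.0, abs=1e-12)

    def test_half_constriction_matches_geometric_oracle(self):
        """d = R/2: chords scale by (R-d)/R; apico-lateral lengths equal the
        distance from the displaced apical vertex to its fixed lateral
        neighbour, computed by hand."""
        R, h = 0.5, 2.0
        pop = build_pop(CellShapeSpec(apical_radius=R, height=h))
        cell = pop.cells[0]
        before = pop.sp_req.copy()
        apical_constriction_targets(pop, 0, R / 2)
        ring = list(range(cell.m_start + 1, cell.m_start + 9))
        # chord between adjacent ring vertices: 2 r sin(pi/8)
        expected_chord = 2 * (R / 2) * np.sin(np.pi / 8)
        for k, (i, j) in enumerate(zip(pop.sp_i, pop.sp_j)):
            if int(i) in ring and int(j) in ring:
                d_ang = abs(ring.index(int(i)) - ring.index(int(j)))
                if min(d_ang, 8 - d_ang) == 1:
                    assert pop.sp_req[k] == pytest.approx(expected_chord,
                                                          rel=1e-12)
        # apico-lateral: apical vertex at radius R/2, z=-h/2; lateral ring 1
        # vertex directly below at radius R, z=-h/6
        angle = 2 * np.pi * 0.5 / 8
        a = np.array([R / 2 * np.cos(angle), R / 2 * np.sin(angle), -h / 2])
        b = np.array([R * np.cos(angle), R * np.sin(angle), -h / 6])
        expected_al = np.linalg.norm(b - a)
        i, j = cell.m_start + 1, cell.m_start + 9  # same azimuth, rings 0/1
        k = int(np.flatnonzero((pop.sp_i == i) & (pop.sp_j == j))[0])
        assert pop.sp_req[k] == pytest.approx(expected_al, rel=1e-12)
        # basal springs untouched
        basal = set(range(cell.m_stop - 9, cell.m_stop))
        for k, (i, j) in enumerate(zip(pop.sp_i, pop.sp_j)):
            if int(i) in basal and int(j) in basal:
                assert pop.sp_req[k] == before[k]

    def test_constriction_is_reversible(self):
        """Constricting by d and then by -d restores the targets exactly."""
        pop = build_pop(COLUMNAR)
        before = pop.sp_req.copy()
        apical_constriction_targets(pop, 0, 0.3)
        apical_constriction_targets(pop, 0, -0.3)
        assert np.allclose(pop.sp_req, before, atol=1e-12)

    def test_overconstriction_rejected(self):
        pop = build_pop(COLUMNAR)
        with pytest.raises(ValueError, match="exceeds apical radius"):
            apical_constriction_targets(pop, 0, 0.6)


class TestConstrictionProfile:
    def _sheet(self, rows, cols):
        pop = Population()
        for i in range(rows):
            for j in range(cols):
                mesh = bm.build_epithelial_cell(CUBOIDAL, center=(i, j, 0.0))
                pop.add_cell(mesh, "TE", (i, j, 0))
        pop.rebuild_cell_pairs()
        return pop

    def test_3x3_sheet_constricts_center_only(self):
        pop = self._sheet(3, 3)
        spec = positional_constriction_profile(pop, range(9))
        center = [c.id for c in pop.cells if c.lattice[:2] == (1, 1)][0]
        assert spec.profile[center] == pytest.approx(0.5)
        assert sum(1 for d in spec.profile.values() if d == 0.0) == 8

    def test_single_cell_sheet_is_its_own_middle(self):
        pop = self._sheet(1, 1)
        spec = positional_constriction_profile(pop, [0])
        assert spec.profile[0] == pytest.approx(0.5)

    def test_step_profile_takes_only_extreme_values(self):
        pop = self._sheet(5, 5)
        spec = positional_constriction_profile(pop, range(25))
        assert set(np.round(list(spec.profile.values()), 12)) == {0.0, 0.5}

    def test_empty_sheet_rejected(self):
        pop = self._sheet(1, 1)
        with pytest.raises(ValueError, match="empty"):
            positional_constriction_profile(pop, [])


class TestLumenRepulsion:
    def test_zero_on_target_sphere(self, params):
        src = LumenSource(origin=np.zeros(3), r_lum=0.25,
                          target_idx=np.array([0]))
        f = lumen_repulsion_force(src, np.array([0.25, 0.0, 0.0]), params)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_pushes_outward_inside_the_sphere(self, params):
        src = LumenSource(origin=np.zeros(3), r_lum=0.25,
                          target_idx=np.array([0]))
        pos = np.array([0.1, 0.0, 0.0])
        f = lumen_repulsion_force(src, pos, params)
        assert f[0] > 0  # away from the origin

    def test_magnitude_matches_formula_oracle(self, params):
        """|F| = 2 J rho |e^{2 rho (r-R)} - e^{rho (r-R)}| at J=2.5, rho=1,
        R_lum=0.25, r=0.1."""
        src = LumenSource(origin=np.zeros(3), r_lum=0.25,
                          target_idx=np.array([0]))
        f = lumen_repulsion_force(src, np.array([0.1, 0.0, 0.0]), params)
        expected = abs(5.0 * (np.exp(-0.3) - np.exp(-0.15)))
        assert np.linalg.norm(f) == pytest.approx(expected, rel=1e-12)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError, match="R_lum"):
            LumenSource(origin=np.zeros(3), r_lum=0.0, target_idx=np.array([0]))


class TestOpenLumen:
    def test_activation_targets_only_apical_rosette_particles(self, params):
        pop = bm.build_rosette_epiblast(params=params)
        source = open_lumen(pop, r_lum=0.25)
        apical = np.flatnonzero(pop.labels == APICAL)
        assert set(source.target_idx) <= set(apical)
        idx, forces = source.forces(pop, params)
        assert np.array_equal(idx, source.target_idx)

    def test_without_contact_there_is_nothing_to_break(self, params):
        pop = Population()
        for k in range(2):
            mesh = bm.build_epithelial_cell(COLUMNAR, center=(5.0 * k, 0, 0))
            pop.add_cell(mesh, "EPI", (k, 0, 0))
        pop.rebuild_cell_pairs()
        pop.refresh_links(params)
        with pytest.raises(ValueError):
            open_lumen(pop, r_lum=0.25)

    def test_broken_apical_links_stay_broken(self, params):
        pop = bm.build_rosette_epiblast(params=params)
        n_before = len(pop.link_a)
        open_lumen(pop, r_lum=0.25)
        pop.refresh_links(params)
        apical = set(np.flatnonzero(pop.labels == APICAL))
        for a, b in zip(pop.link_a, pop.link_b):
            assert not (int(a) in apical and int(b) in apical
                        and (min(int(a), int(b)), max(int(a), int(b)))
                        in pop._blacklist)
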