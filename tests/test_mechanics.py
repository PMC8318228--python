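"""Forces, overdamped integration and elastic energy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import blastomech as bm
from blastomech import mechanics
from blastomech.mechanics import (
    SimParams,
    elastic_energy,
    external_forces,
    internal_and_cytoskeleton_forces,
    morse_force,
    morse_scalar,
)


class TestMorseForce:
    def test_zero_exactly_at_equilibrium(self):
        f = morse_force(2.5, 1.0, 0.7, 0.7, np.array([1.0, 0, 0]))
        assert np.all(f == 0.0)

    def test_scalar_formula_oracle(self):
        # 2*J*rho*(e^{2 rho d} - e^{rho d}) at J=2.5, rho=1, r=1, r_eq=0.5
        expected = 2 * 2.5 * 1.0 * (np.exp(1.0) - np.exp(0.5))
        got = morse_force(2.5, 1.0, 1.0, 0.5, np.array([1.0, 0, 0]))
        assert got[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(5.347802788794585, rel=1e-12)

    @given(st.floats(0.05, 3.0), st.floats(0.05, 3.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sign_restores_equilibrium(self, r, r_eq):
        """Stretched springs attract (+u toward partner), compressed repel."""
        s = float(morse_scalar(2.5, 1.0, r, r_eq))
        assert np.sign(s) == np.sign(r - r_eq) or abs(r - r_eq) < 1e-12

    def test_force_cap_limits_magnitude(self):
        s = morse_scalar(2.5, 1.0, 10.0, 0.5, cap=250.0)
        assert s == 250.0

    def test_coincident_particles_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            morse_force(2.5, 1.0, 0.0, 0.5, np.zeros(3))


class TestInternalForces:
    def test_resting_cell_has_zero_forces_and_energy(self, single_cell_pop,
                                                     params):
        pop = single_cell_pop()
        acc = internal_and_cytoskeleton_forces(pop, params)
        assert np.all(acc == 0.0)
        assert elastic_energy(pop) == 0.0

    def test_action_reaction_gives_zero_net_force(self, single_cell_pop,
                                                  params):
        pop = single_cell_pop()
        pop.pos *= 1.1  # uniform inflation
        acc = internal_and_cytoskeleton_forces(pop, params)
        assert np.allclose(acc.sum(axis=0), 0.0, atol=1e-12)

    def test_inflated_cell_forces_point_inward(self, single_cell_pop, params):
        pop = single_cell_pop()
        center = pop.pos.mean(axis=0)
        pop.pos = center + 1.1 * (pop.pos - center)
        acc = internal_and_cytoskeleton_forces(pop, params)
        mem = pop.is_membrane
        inward = np.einsum("ij,ij->i", acc[mem], center - pop.pos[mem])
        assert np.all(inward > 0)

    def test_nucleus_receives_reaction_of_cytoskeleton(self, single_cell_pop,
                                                       params):
        """Intracellular force equals minus the sum of membrane-cyto forces."""
        pop = single_cell_pop()
        rng = np.random.default_rng(0)
        pop.pos[pop.is_membrane] += 0.03 * rng.standard_normal(
            (int(pop.is_membrane.sum()), 3))
        acc = internal_and_cytoskeleton_forces(pop, params)
        cell = pop.cells[0]
        chi = pop.pos[cell.nucleus]
        total = np.zeros(3)
        for i in cell.membrane_idx:
            d = chi - pop.pos[i]
            r = np.linalg.norm(d)
            r_eq = pop.sp_req[(pop.sp_j == cell.nucleus) & (pop.sp_i == i)][0]
            total += morse_force(params.j_epi, params.rho, r, r_eq, d / r)
        assert np.allclose(acc[cell.nucleus], -total, rtol=1e-9, atol=1e-12)


class TestExternalForces:
    def test_isolated_cell_gets_none(self, single_cell_pop, params):
        pop = single_cell_pop()
        pop.refresh_links(params)
        assert np.all(external_forces(pop, params) == 0.0)

    def test_two_adhered_resting_cells_transmit_nothing(self, two_cell_pop,
                                                        params):
        pop = two_cell_pop(("TE", "EPI"))
        pop.refresh_links(params)
        assert len(pop.link_a) > 0
        assert np.all(external_forces(pop, params) == 0.0)

    def test_transmitted_force_copies_partner_internal_sum(self, two_cell_pop,
                                                           params):
        """A linked particle receives exactly its partner's internal +
        cytoskeleton force sum."""
        pop = two_cell_pop(("TE", "EPI"))
        pop.refresh_links(params)
        # perturb one particle of cell 0 and inspect its linked partner
        a = int(pop.link_a[0])
        b = int(pop.link_b[0])
        pop.pos[pop.cells[0].m_start + 3] += (0.05, 0.02, -0.04)
        internal = internal_and_cytoskeleton_forces(pop, params)
        ext = external_forces(pop, params)
        links_of_b = [(x, y) for x, y in zip(pop.link_a, pop.link_b)
                      if b in (int(x), int(y))]
        expected = sum(internal[int(x) if int(y) == b else int(y)]
                       for x, y in links_of_b)
        assert np.allclose(ext[b], expected, atol=1e-14)


class TestStep:
    def test_resting_population_is_stationary(self, two_cell_pop, params):
        pop = two_cell_pop()
        pop.refresh_links(params)
        before = pop.pos.copy()
        mechanics.step(pop, params, n=10)
        assert np.array_equal(pop.pos, before)

    def test_relaxation_energy_never_increases(self, single_cell_pop, params):
        pop = single_cell_pop()
        pop.pos[5] += 0.1
        energies = [elastic_energy(pop)]
        for _ in range(400):
            mechanics.step(pop, params)
            energies.append(elastic_energy(pop))
        assert np.all(np.diff(energies) <= 1e-12)
        assert energies[-1] < 1e-3 * energies[0]

    def test_displacement_inversely_proportional_to_friction(
            self, single_cell_pop, params):
        pop1 = single_cell_pop()
        pop2 = single_cell_pop()
        pop1.pos[5] += 0.1
        pop2.pos[5] += 0.1
        mechanics.step(pop1, params)
        mechanics.step(pop2, params.with_(lambda_med=2 * params.lambda_med,
                                          lambda_chi=2 * params.lambda_chi))
        d1 = pop1.pos[pop1.is_membrane] - pop2.pos[pop2.is_membrane]
        # pop2 moved half as far from the same start
        start = single_cell_pop()
        start.pos[5] += 0.1
        move1 = pop1.pos - start.pos
        move2 = pop2.pos - start.pos
        assert np.allclose(move1, 2.0 * move2, atol=1e-15)

    def test_translation_invariance_of_forces(self, two_cell_pop, params):
        pop = two_cell_pop(("TE", "EPI"))
        pop.refresh_links(params)
        pop.pos[3] += 0.05
        f1 = mechanics.total_forces(pop, params)
        pop.pos += np.array([3.0, -1.0, 2.0])
        f2 = mechanics.total_forces(pop, params)
        assert np.allclose(f1, f2, atol=1e-9)

    def test_trajectory_is_deterministic(self, single_cell_pop, params):
        runs = []
        for _ in range(2):
            pop = single_cell_pop()
            pop.pos[5] += 0.1
            mechanics.step(pop, params, n=50)
            runs.append(pop.pos.copy())
        assert np.array_equal(runs[0], runs[1])


class TestElasticEnergy:
    def test_single_stretched_spring_contributes_delta_squared(
            self, single_cell_pop, params):
        pop = single_cell_pop()
        delta = 0.07
        pop.sp_req = pop.sp_req.copy()
        pop.sp_req[10] += delta
        assert elastic_energy(pop) == pytest.approx(delta ** 2, rel=1e-12)

    def test_matches_bruteforce_sum_over_springs(self, two_cell_pop, params):
        pop = two_cell_pop()
        rng = np.random.default_rng(1)
        pop.pos += 0.02 * rng.standard_normal(pop.pos.shape)
        total = 0.0
        for i, j, r_eq in zip(pop.sp_i, pop.sp_j, pop.sp_req):
            r = np.linalg.norm(pop.pos[j] - pop.pos[i])
            total += (r_eq - r) ** 2
        assert elastic_energy(pop) == pytest.approx(total, rel=1e-12)

    def test_per_cell_energies_sum_to_total(self, two_cell_pop, params):
        pop = two_cell_pop()
        rng = np.random.default_rng(2)
        pop.pos += 0.02 * rng.standard_normal(pop.pos.shape)
        per_cell = mechanics.per_cell_elastic_energy(pop)
        assert per_cell.sum() == pytest.approx(elastic_energy(pop), rel=1e-12)
        assert elastic_energy(pop, [0]) == pytest.approx(per_cell[0], rel=1e-12)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SimParams(dt=0.0)
    with pytest.raises(ValueError):
        SimParams(j_te=-1.0)
    with pytest.raises(ValueError):
        SimParams(lambda_chi=-2.0)
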