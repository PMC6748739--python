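"""Surface engine: occluder groups, SASA, direct CSA, BSA, modes."""

import math

import numpy as np
import pytest

from contactsurf import (
    Atom,
    InvalidStateError,
    aggregate_to_residues,
    classify_points,
    compute_contacts,
    compute_sasa,
    delta_sasa_csa,
    derive_bsa,
    run_mode,
)
from contactsurf.engine import (
    SCOPE_CROSS,
    build_group_tables,
    contacts_from_tables,
    sphere_area,
)
from contactsurf.fixtures import (
    analytic_cap_area,
    make_buried_cage,
    make_crowding_pair,
    make_fig1_triple,
    make_random_cluster,
    make_two_sphere,
)

PROBE = 1.4


def _sphere_areas(atoms):
    return np.array([sphere_area(a.vdw_radius, PROBE) for a in atoms])


class TestClassifyPoints:
    def test_isolated_atom_fully_accessible(self, lattice):
        atom = Atom(1, "C1", "C", [0, 0, 0], 1.6)
        table = classify_points(atom, [], lattice, PROBE)
        assert table.accessible_points == table.total_points == lattice.count
        assert table.groups == {}

    def test_single_occluder_buried_fraction_matches_cap(self, lattice):
        # buried fraction of the expanded sphere = h / (2 R) for a cap of
        # height h; computed from the closed form, not the engine
        sys2 = make_two_sphere()
        a, b = sys2.atoms
        table = classify_points(a, [b], lattice, PROBE)
        assert set(table.groups) == {(2,)}
        cap, _ = analytic_cap_area(a.vdw_radius, b.vdw_radius, 3.0, PROBE)
        expected_fraction = cap / sphere_area(a.vdw_radius, PROBE)
        fraction = table.groups[(2,)] / table.total_points
        assert fraction == pytest.approx(expected_fraction, rel=0.02)

    def test_shared_patch_produces_all_three_groups(self, lattice):
        triple = make_fig1_triple()
        a, b, c = triple.atoms
        table = classify_points(a, [b, c], lattice, PROBE)
        assert set(table.groups) == {(2,), (3,), (2, 3)}
        assert all(count > 0 for count in table.groups.values())
        assert table.accessible_points + table.buried_points() == table.total_points


class TestSasa:
    def test_isolated_atom_full_expanded_sphere(self, lattice):
        atom = Atom(1, "C1", "C", [0, 0, 0], 1.6)
        assert compute_sasa([atom], lattice)[0] == pytest.approx(36 * math.pi)

    def test_two_sphere_matches_cap_complement(self, lattice):
        sys2 = make_two_sphere()  # r=1.6 both, d=3.0 -> SASA(A) = 27 pi
        sasa = compute_sasa(sys2.atoms, lattice)
        assert sasa[0] == pytest.approx(27 * math.pi, rel=0.01)
        assert sasa[1] == pytest.approx(27 * math.pi, rel=0.01)

    def test_distant_atoms_unperturbed(self, lattice):
        atoms = [Atom(1, "C1", "C", [0, 0, 0], 1.6),
                 Atom(2, "C1", "C", [10, 0, 0], 1.6)]
        assert compute_sasa(atoms, lattice) == pytest.approx([36 * math.pi] * 2)


class TestContacts:
    def test_two_sphere_csa_matches_analytic_cap(self, lattice):
        sys2 = make_two_sphere()
        matrix = compute_contacts(sys2.atoms, lattice)
        assert matrix.values[0, 1] == pytest.approx(sys2.expected["buried_a"], rel=0.01)
        assert matrix.values[1, 0] == pytest.approx(sys2.expected["buried_b"], rel=0.01)

    def test_matrix_asymmetric_for_unequal_radii(self, lattice):
        sys2 = make_two_sphere(r_a=1.2, r_b=2.0, d=3.0)
        matrix = compute_contacts(sys2.atoms, lattice)
        # areas live on different expanded spheres
        assert abs(matrix.values[0, 1] - matrix.values[1, 0]) > 1.0

    def test_beyond_cutoff_exactly_zero(self, lattice):
        sys2 = make_two_sphere(d=10.0)
        matrix = compute_contacts(sys2.atoms, lattice)
        assert matrix.values[0, 1] == 0.0 and matrix.values[1, 0] == 0.0

    def test_diagonal_zero_and_entries_nonnegative(self, coarse_lattice):
        cluster = make_random_cluster(30, seed=7)
        matrix = compute_contacts(cluster.atoms, coarse_lattice)
        assert np.all(matrix.values >= 0)
        assert np.all(np.diag(matrix.values) == 0)

    def test_csa_bounded_by_buried_patch_in_counting_arithmetic(self, coarse_lattice):
        # fractional attribution can only split, never inflate: CSA(A,B)
        # is at most the sampled area of A's points inside B
        cluster = make_random_cluster(25, seed=11)
        tables = build_group_tables(cluster.atoms, coarse_lattice, PROBE)
        matrix = contacts_from_tables(cluster.atoms, tables, coarse_lattice, PROBE)
        serials = [a.serial for a in cluster.atoms]
        for i, (atom, table) in enumerate(zip(cluster.atoms, tables)):
            area1 = coarse_lattice.point_weight * atom.expanded_radius(PROBE) ** 2
            for j, s in enumerate(serials):
                in_b = sum(c for g, c in table.groups.items() if s in g)
                assert matrix.values[i, j] <= in_b * area1 + 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conservation_identity_random_clusters(self, coarse_lattice, seed):
        # SASA(A) + sum_B CSA(A,B) = 4 pi (r_A + probe)^2 for every atom
        cluster = make_random_cluster(40, seed=seed)
        tables = build_group_tables(cluster.atoms, coarse_lattice, PROBE)
        matrix = contacts_from_tables(cluster.atoms, tables, coarse_lattice, PROBE)
        sasa = compute_sasa(cluster.atoms, coarse_lattice)
        total = sasa + matrix.values.sum(axis=1)
        np.testing.assert_allclose(total, _sphere_areas(cluster.atoms), rtol=1e-9)


class TestFig1Attribution:
    def test_csa_is_exclusive_patch_plus_half_shared(self, lattice):
        # recomputed independently from the group table
        triple = make_fig1_triple()
        a = triple.atoms[0]
        tables = build_group_tables(triple.atoms, lattice, PROBE)
        matrix = contacts_from_tables(triple.atoms, tables, lattice, PROBE)
        area1 = lattice.point_weight * a.expanded_radius(PROBE) ** 2
        groups = tables[0].groups
        expected = groups[(2,)] * area1 + groups[(2, 3)] * area1 / 2
        assert matrix.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_mirror_symmetry_equal_contacts(self, lattice):
        triple = make_fig1_triple()
        a = triple.atoms[0]
        matrix = compute_contacts(triple.atoms, lattice)
        tolerance = lattice.point_weight * a.expanded_radius(PROBE) ** 2
        assert abs(matrix.values[0, 1] - matrix.values[0, 2]) <= tolerance

    def test_conservation_on_triple(self, lattice):
        triple = make_fig1_triple()
        matrix = compute_contacts(triple.atoms, lattice)
        sasa = compute_sasa(triple.atoms, lattice)
        total = sasa[0] + matrix.values[0, 1] + matrix.values[0, 2]
        assert total == pytest.approx(triple.expected["sphere_area_a"], rel=1e-9)


class TestAggregation:
    def test_residue_totals_preserved_exactly(self, coarse_lattice):
        cluster = make_random_cluster(30, seed=5)
        atom_matrix = compute_contacts(cluster.atoms, coarse_lattice)
        res_matrix = aggregate_to_residues(atom_matrix)
        assert res_matrix.total() == pytest.approx(atom_matrix.total(), rel=1e-12)

    def test_single_atom_residues_equal_atom_matrix(self, lattice):
        sys2 = make_two_sphere()
        atom_matrix = compute_contacts(sys2.atoms, lattice)
        res_matrix = aggregate_to_residues(atom_matrix)
        np.testing.assert_array_equal(res_matrix.values, atom_matrix.values)

    def test_fig1_residue_entry_sums_atom_entries(self, lattice):
        # A alone in residue 1; B and C share chain B residues 2, 3 -> use
        # the residue matrix row of A against both B-chain residues
        triple = make_fig1_triple()
        atom_matrix = compute_contacts(triple.atoms, lattice)
        res_matrix = aggregate_to_residues(atom_matrix)
        row = res_matrix.row_labels.index("A/UNK 1")
        total_a = res_matrix.values[row].sum()
        assert total_a == pytest.approx(atom_matrix.values[0, 1:].sum(), abs=1e-12)

    def test_residue_matrix_not_aggregatable_again(self, lattice):
        sys2 = make_two_sphere()
        res = aggregate_to_residues(compute_contacts(sys2.atoms, lattice))
        with pytest.raises(ValueError):
            aggregate_to_residues(res)


class TestBsa:
    def test_two_atom_bsa_equals_csa(self, lattice):
        sys2 = make_two_sphere()
        matrix = compute_contacts(sys2.atoms, lattice)
        bsa = derive_bsa(matrix)
        assert bsa[0] == pytest.approx(matrix.values[0, 1])

    def test_empty_selection_gives_zero(self, lattice):
        sys2 = make_two_sphere()
        matrix = compute_contacts(sys2.atoms, lattice)
        assert np.all(derive_bsa(matrix, columns=[]) == 0)

    def test_isolated_atom_zero_bsa(self, lattice):
        atom = Atom(1, "C1", "C", [0, 0, 0], 1.6)
        matrix = compute_contacts([atom], lattice)
        assert derive_bsa(matrix)[0] == 0.0


class TestDeltaSasa:
    def test_distant_objects_zero_interface(self, lattice):
        sys2 = make_two_sphere(d=50.0)
        delta, total = delta_sasa_csa(sys2.atoms, lattice)
        assert total == 0.0 and np.all(delta == 0)

    def test_single_occluder_pair_matches_direct_csa(self, lattice):
        # with one occluder per side the two definitions coincide
        sys2 = make_two_sphere()
        _, delta_total = delta_sasa_csa(sys2.atoms, lattice)
        matrix = compute_contacts(sys2.atoms, lattice)
        direct_total = matrix.values[0, 1] + matrix.values[1, 0]
        assert delta_total == pytest.approx(direct_total, rel=1e-9)

    def test_crowding_underestimates_direct_csa(self, lattice):
        crowd = make_crowding_pair()
        _, delta_total = delta_sasa_csa(crowd.atoms, lattice)
        matrix = compute_contacts(crowd.atoms, lattice)
        obj = np.array([a.object_id for a in crowd.atoms])
        direct_total = matrix.values[obj[:, None] != obj[None, :]].sum()
        assert delta_total < direct_total

    def test_requires_exactly_two_objects(self, lattice):
        atoms = [Atom(1, "C1", "C", [0, 0, 0], 1.6, object_id=0)]
        with pytest.raises(ValueError):
            delta_sasa_csa(atoms, lattice)


class TestModes:
    def test_mode0_sasa_only(self, lattice):
        sys2 = make_two_sphere()
        result = run_mode(sys2.atoms, 0, lattice)
        assert result.matrices == {} and result.bsa is None
        assert result.sasa.shape == (2,)

    def test_invalid_mode_rejected(self, lattice):
        sys2 = make_two_sphere()
        with pytest.raises(ValueError):
            run_mode(sys2.atoms, 5, lattice)

    @pytest.mark.parametrize("mode", [1, 4])
    def test_intermolecular_modes_need_two_objects(self, lattice, mode):
        atoms = [Atom(1, "C1", "C", [0, 0, 0], 1.6), Atom(2, "C1", "C", [3, 0, 0], 1.6)]
        with pytest.raises(InvalidStateError):
            run_mode(atoms, mode, lattice)

    def test_cross_scope_requires_objects(self, lattice):
        atoms = [Atom(1, "C1", "C", [0, 0, 0], 1.6), Atom(2, "C1", "C", [3, 0, 0], 1.6)]
        with pytest.raises(InvalidStateError):
            build_group_tables(atoms, lattice, PROBE, SCOPE_CROSS)

    def test_mode1_zeroes_intra_object_contacts(self, lattice):
        crowd = make_crowding_pair()
        result = run_mode(crowd.atoms, 1, lattice)
        values = result.matrices["atom"].values
        assert values[1, 2] == 0.0 and values[2, 1] == 0.0  # B-C same object
        assert values[0, 1] > 0 and values[0, 2] > 0

    def test_mode1_bsa_is_row_sum(self, lattice):
        crowd = make_crowding_pair()
        result = run_mode(crowd.atoms, 1, lattice)
        np.testing.assert_allclose(result.bsa,
                                   result.matrices["atom"].values.sum(axis=1))

    def test_mode2_equals_aggregated_mode3(self, lattice):
        triple = make_fig1_triple()
        res2 = run_mode(triple.atoms, 2, lattice).matrices["residue"]
        atom3 = run_mode(triple.atoms, 3, lattice).matrices["atom"]
        np.testing.assert_array_equal(res2.values,
                                      aggregate_to_residues(atom3).values)
        assert res2.granularity == "residue"

    def test_mode4_recovers_buried_cavity_contacts(self, lattice):
        cage = make_buried_cage()
        mode1 = run_mode(cage.atoms, 1, lattice)
        mode4 = run_mode(cage.atoms, 4, lattice)
        # ligand (atom 0) is completely buried
        assert mode1.sasa[0] == 0.0
        # cage atoms' contact with the ligand grows when same-object
        # occluders no longer share the buried patches
        col1 = mode1.matrices["atom"].values[1:, 0].sum()
        col4 = mode4.matrices["atom"].values[1:, 0].sum()
        assert col4 > col1 > 0
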