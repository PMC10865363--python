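import numpy as np
import pytest

from bizinc.cluster import (
    CAP_BOND_LENGTH,
    CappedFragment,
    ClusterRecipe,
    Energy,
    EnergyRow,
    EnergyTable,
    build_cluster,
    count_atoms,
    interaction_energy,
    rank_conformers,
    write_cluster,
)
from bizinc.errors import RecipeError, TableError, UnitError
from bizinc.structures import read_structure, read_xyz, structure_from_atoms


def _protein():
    # glycine 10, a leucine-like residue 11 to truncate, one water, one zinc
    return structure_from_atoms(
        [
            ("N", "N", "GLY", 10, "A", (0.0, 0.0, 0.0), False),
            ("CA", "C", "GLY", 10, "A", (1.45, 0.0, 0.0), False),
            ("C", "C", "GLY", 10, "A", (2.0, 1.4, 0.0), False),
            ("O", "O", "GLY", 10, "A", (1.4, 2.4, 0.0), False),
            ("CA", "C", "LEU", 11, "A", (5.0, 0.0, 0.0), False),
            ("CB", "C", "LEU", 11, "A", (6.53, 0.0, 0.0), False),
            ("CG", "C", "LEU", 11, "A", (7.2, 1.3, 0.0), False),
            ("ZN", "Zn", "ZN", 90, "M", (0.0, 3.0, 0.0), True),
            ("O", "O", "HOH", 91, "W", (2.5, 3.5, 0.0), True),
            ("O", "O", "HOH", 92, "W", (20.0, 20.0, 20.0), True),
        ],
        "toy_protein",
    )


def test_full_residue_copied_whole():
    recipe = ClusterRecipe(full_residues=[("A", 10)], include_ligand=False,
                           include_metals=False, water_within=None)
    cluster = build_cluster(_protein(), recipe)
    assert count_atoms(cluster) == 4
    assert count_atoms(cluster, heavy_only=True) == 4  # deposited models have no H
    assert cluster.inventory() == {"residue": 4}


def test_capping_geometry_and_counts():
    recipe = ClusterRecipe(
        capped_residues=[CappedFragment(("A", 11), ("CB", "CG"), ("CB", "CA"))],
        include_ligand=False, include_metals=False, water_within=None,
    )
    cluster = build_cluster(_protein(), recipe)
    # kept 2 heavy atoms + 1 cap carbon
    assert cluster.heavy_atom_count == 3
    cap = [a for a in cluster.atoms if a.tag == "cap"]
    assert len(cap) == 1 and cap[0].element == "C"
    # cap sits 1.53 A from the kept atom, along the cut bond toward CA
    cb = np.array([6.53, 0.0, 0.0])
    ca = np.array([5.0, 0.0, 0.0])
    want = cb + CAP_BOND_LENGTH * (ca - cb) / np.linalg.norm(ca - cb)
    np.testing.assert_allclose(cap[0].position, want, atol=1e-12)


def test_cap_accounting_rule():
    # heavy count = kept heavy atoms + number of cut bonds
    recipe = ClusterRecipe(
        full_residues=[("A", 10)],
        capped_residues=[CappedFragment(("A", 11), ("CB", "CG"), ("CB", "CA"))],
        include_ligand=False, include_metals=True, water_within=None,
    )
    cluster = build_cluster(_protein(), recipe)
    kept = 4 + 2 + 1  # gly + fragment + zinc
    assert cluster.heavy_atom_count == kept + 1


def test_water_network_single_pass():
    recipe = ClusterRecipe(full_residues=[("A", 10)], include_ligand=False,
                           include_metals=True, water_within=3.5)
    cluster = build_cluster(_protein(), recipe)
    inv = cluster.inventory()
    assert inv.get("water", 0) == 1  # the distant water is excluded


def test_missing_residue_named_in_error():
    recipe = ClusterRecipe(full_residues=[("A", 999)])
    with pytest.raises(RecipeError, match="999"):
        build_cluster(_protein(), recipe)


def test_recipe_overlap_rejected():
    recipe = ClusterRecipe(
        full_residues=[("A", 11)],
        capped_residues=[CappedFragment(("A", 11), ("CB",), ("CB", "CA"))],
    )
    with pytest.raises(RecipeError):
        build_cluster(_protein(), recipe)


def test_cluster_determinism():
    recipe = ClusterRecipe(full_residues=[("A", 10)], include_metals=True)
    a = build_cluster(_protein(), recipe)
    b = build_cluster(_protein(), recipe)
    assert [(x.element, x.label, tuple(x.position)) for x in a.atoms] == [
        (x.element, x.label, tuple(x.position)) for x in b.atoms
    ]


def test_interaction_energy_definition():
    assert interaction_energy(Energy(0), Energy(0), Energy(0)).value == 0.0
    assert interaction_energy(Energy(-10), Energy(-4), Energy(-3)).value == pytest.approx(-3.0)


def test_interaction_energy_linearity():
    rng = np.random.default_rng(9)
    ab, a, b = rng.normal(size=3)
    base = interaction_energy(Energy(ab), Energy(a), Energy(b)).value
    for c in (2.0, -0.5, 10.0):
        scaled = interaction_energy(Energy(c * ab), Energy(c * a), Energy(c * b)).value
        assert scaled == pytest.approx(c * base)


def test_interaction_energy_unit_mismatch():
    with pytest.raises(UnitError):
        interaction_energy(Energy(1, "hartree"), Energy(0), Energy(0))
    with pytest.raises(UnitError):
        Energy(1.0, "eV")


def test_rank_single_row():
    assert rank_conformers(EnergyTable([EnergyRow("only", -512.3)])) == [("only", 0.0)]


def test_rank_shift_invariance():
    rows = [EnergyRow(lbl, e) for lbl, e in [("a", 3.0), ("b", 1.0), ("c", 2.0)]]
    base = rank_conformers(EnergyTable(rows))
    shifted = rank_conformers(
        EnergyTable([EnergyRow(r.label, r.total + 1234.5) for r in rows])
    )
    assert base == shifted
    assert base[0][1] == 0.0


def test_rank_empty_table():
    with pytest.raises(TableError):
        rank_conformers(EnergyTable([]))


def test_write_cluster_xyz_round_trip(tmp_path):
    recipe = ClusterRecipe(full_residues=[("A", 10)], include_metals=True, water_within=None)
    cluster = build_cluster(_protein(), recipe)
    p = tmp_path / "c.xyz"
    write_cluster(cluster, p, format="xyz")
    assert p.read_text().splitlines()[0] == str(len(cluster.atoms))
    back = read_xyz(p)
    for atom, (el, pos) in zip(cluster.atoms, back):
        assert atom.element == el
        np.testing.assert_allclose(pos, atom.position, atol=1e-6)


def test_write_cluster_pdb_parses(tmp_path):
    recipe = ClusterRecipe(full_residues=[("A", 10)], include_metals=True, water_within=3.5)
    cluster = build_cluster(_protein(), recipe)
    p = tmp_path / "c.pdb"
    write_cluster(cluster, p, format="pdb")
    st = read_structure(p)
    assert len(st.atoms) == len(cluster.atoms)
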