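import math

import numpy as np
import pytest

from bizinc.errors import EmptyComponentError, FormatError, ParseError, SerializationError
from bizinc.structures import (
    ANGSTROM_TO_BOHR,
    perceive_bonds,
    read_cube,
    read_structure,
    read_xyz,
    structure_from_atoms,
    write_cube,
    write_pdb,
    write_xyz,
)


def test_pdb_round_trip_preserves_atoms(canonical_site, tmp_path):
    st, _ = canonical_site
    path = tmp_path / "site.pdb"
    write_pdb(st, path)
    st2 = read_structure(path, format="pdb")
    assert len(st2.atoms) == len(st.atoms)
    assert [a.name for a in st2.atoms] == [a.name for a in st.atoms]
    assert [a.element.upper() for a in st2.atoms] == [a.element.upper() for a in st.atoms]
    np.testing.assert_allclose(st2.positions, st.positions, atol=5e-4)
    # idempotence: a second write/read cycle is exact
    path2 = tmp_path / "site2.pdb"
    write_pdb(st2, path2)
    st3 = read_structure(path2)
    np.testing.assert_array_equal(st3.positions, st2.positions)


ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.40 10.00           C
ATOM      3  N   ALA A   1       0.000   1.400   0.000  1.00 10.00           N
END
"""


def test_altloc_highest_occupancy_kept(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(ALTLOC_PDB)
    st = read_structure(p)
    assert len(st.atoms) == 2  # one CA survives
    ca = st.atoms[st.select_one(name="CA")]
    assert ca.position[0] == pytest.approx(0.0)  # the 0.60 conformer
    assert ca.occupancy == pytest.approx(0.6)


def test_altloc_tie_broken_by_letter(tmp_path):
    p = tmp_path / "tie.pdb"
    p.write_text(ALTLOC_PDB.replace("0.60", "0.50").replace("0.40", "0.50"))
    st = read_structure(p)
    ca = st.atoms[st.select_one(name="CA")]
    assert ca.alt_loc == "A"


def test_read_errors(tmp_path):
    with pytest.raises(ParseError):
        read_structure(tmp_path / "missing.pdb")
    with pytest.raises(FormatError):
        read_structure(tmp_path, format="xyzzy")


@pytest.mark.parametrize(
    "separation,expect_edge", [(1.5, True), (3.0, False)]
)
def test_bond_perception_distance_rule(separation, expect_edge):
    st = structure_from_atoms(
        [
            ("C1", "C", "LIG", 1, "L", (0, 0, 0), True),
            ("C2", "C", "LIG", 1, "L", (separation, 0, 0), True),
        ],
        "pair",
    )
    g = perceive_bonds(st, ("L", 1, "", "LIG"))
    assert g.graph.has_edge(0, 1) is expect_edge


def test_bond_perception_sulfamide_degrees(canonical_site):
    st, truth = canonical_site
    key = next(k for k in st.components if k[3] == "LIG")
    g = perceive_bonds(st, key)
    by_name = {st.atoms[i].name: i for i in st.components[key]}
    assert g.degree(by_name["S1"]) == 4
    assert g.degree(by_name["O1"]) == 1
    assert g.degree(by_name["O2"]) == 1
    assert {st.atoms[n].element for n in g.graph.neighbors(by_name["S1"])} == {"O", "N"}


def test_metals_never_covalently_bonded(canonical_site):
    st, _ = canonical_site
    zn_key = next(k for k in st.components if k[3] == "ZN")
    g = perceive_bonds(st, zn_key)
    assert g.graph.number_of_edges() == 0


def test_bond_perception_unaffected_by_far_atom(canonical_site):
    st, _ = canonical_site
    key = next(k for k in st.components if k[3] == "LIG")
    before = set(perceive_bonds(st, key).graph.edges)
    atoms = [(a.name, a.element, a.residue_name, a.residue_seq, a.chain, a.position, a.is_hetero)
             for a in st.atoms]
    atoms.append(("C99", "C", "LIG", 1, "L", (50.0, 50.0, 50.0), True))
    st2 = structure_from_atoms(atoms, "augmented")
    after = set(perceive_bonds(st2, key).graph.edges)
    assert before <= after
    assert after - before == set()


def test_empty_component_error(canonical_site):
    st, _ = canonical_site
    with pytest.raises(EmptyComponentError):
        perceive_bonds(st, ("Z", 999, "", "XXX"))


def test_cube_zeros_block(tmp_path):
    path = tmp_path / "z.cube"
    write_cube(path, (0, 0, 0), 0.5, np.zeros((2, 2, 2)))
    values = []
    for line in path.read_text().splitlines()[6:]:
        values.extend(float(v) for v in line.split())
    assert values == [0.0] * 8


def test_cube_round_trip_and_units(tmp_path):
    rng = np.random.default_rng(11)
    vals = rng.normal(size=(5, 5, 5))
    path = tmp_path / "r.cube"
    write_cube(path, (1.0, -2.0, 0.5), 0.2, vals, atoms=[("C", (0, 0, 0))])
    origin, spacing, back = read_cube(path)
    rng_span = vals.max() - vals.min()
    assert np.max(np.abs(back - vals)) <= 1e-5 * rng_span
    np.testing.assert_allclose(spacing, 0.2, atol=1e-6)
    # header spacing in Bohr: 0.2 A = 0.377945 Bohr
    header = path.read_text().splitlines()[3]
    assert math.isclose(float(header.split()[1]), 0.2 * ANGSTROM_TO_BOHR, abs_tol=5e-7)
    assert math.isclose(0.2 * ANGSTROM_TO_BOHR, 0.377945, abs_tol=1e-6)


def test_cube_rejects_non_finite(tmp_path):
    bad = np.zeros((2, 2, 2))
    bad[0, 0, 0] = np.nan
    with pytest.raises(SerializationError):
        write_cube(tmp_path / "bad.cube", (0, 0, 0), 0.5, bad)


def test_xyz_round_trip(tmp_path):
    atoms = [("C", (0.123456, -1.5, 2.0)), ("Zn", (3.0, 0.000001, -9.25))]
    p = tmp_path / "a.xyz"
    write_xyz(atoms, p, comment="two atoms")
    back = read_xyz(p)
    assert [e for e, _ in back] == ["C", "Zn"]
    for (_, want), (_, got) in zip(atoms, back):
        np.testing.assert_allclose(got, want, atol=1e-6)
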