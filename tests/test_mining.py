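import numpy as np
import pytest

from _oracles import brute_force_matches
from bizinc.mining import (
    SULFAMIDE_PATTERN,
    MiningParams,
    ZBGMatch,
    classify_nuclearity,
    element_prefilter,
    find_nearby_metals,
    match_substructure,
    mine,
)
from bizinc.structures import perceive_bonds, structure_from_atoms
from bizinc.synthetic import SiteSpec, build_decoy, build_site


def ligand_graph(structure):
    key = next(iter(structure.ligand_components()))
    return perceive_bonds(structure, key)


def test_element_prefilter(canonical_site):
    st, _ = canonical_site
    assert element_prefilter(st) is True
    no_metal, _ = build_decoy("no_metal")
    assert element_prefilter(no_metal) is False


def test_sulfamide_matches_once(canonical_site):
    st, _ = canonical_site
    assert len(match_substructure(ligand_graph(st))) == 1


def test_bis_sulfamide_matches_once():
    st, _ = build_site(SiteSpec(ligand_headgroup="sulfamide_bis"))
    assert len(match_substructure(ligand_graph(st))) == 1


def test_sulfonamide_rejected():
    st, _ = build_decoy("sulfonamide_not_sulfamide")
    assert match_substructure(ligand_graph(st)) == []


@pytest.mark.parametrize("builder", [
    lambda: build_site(SiteSpec())[0],
    lambda: build_site(SiteSpec(ligand_headgroup="sulfamide_bis"))[0],
    lambda: build_site(SiteSpec(ligand_headgroup="phosphinate"))[0],
    lambda: build_decoy("sulfonamide_not_sulfamide")[0],
])
def test_matcher_equals_brute_force_on_fixtures(builder):
    g = ligand_graph(builder())
    assert g.n_atoms <= 12
    ours = {tuple(sorted(m.items())) for m in match_substructure(g)}
    oracle = {tuple(sorted(m.items())) for m in brute_force_matches(g, SULFAMIDE_PATTERN).values()}
    assert ours == oracle


def test_matcher_equals_brute_force_on_random_graphs():
    import networkx as nx

    from bizinc.structures import MoleculeGraph

    rng = np.random.default_rng(123)
    elements = np.array(["S", "O", "N", "C"])
    for trial in range(40):
        n = int(rng.integers(4, 13))
        g = nx.Graph()
        labels = rng.choice(elements, size=n, p=[0.2, 0.3, 0.3, 0.2])
        for i in range(n):
            g.add_node(i, element=str(labels[i]))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.25:
                    g.add_edge(i, j, order="unknown")
        mg = MoleculeGraph(graph=g, source=("X", 1, "", "RND"))
        ours = {tuple(sorted(m.items())) for m in match_substructure(mg)}
        oracle = {
            tuple(sorted(m.items()))
            for m in brute_force_matches(mg, SULFAMIDE_PATTERN).values()
        }
        assert ours == oracle, f"trial {trial} diverged from brute force"


def _sulfamide_with_zn(zn_positions):
    atoms = [
        ("S1", "S", "LIG", 1, "L", (0.0, 0.0, 0.0), True),
        ("O1", "O", "LIG", 1, "L", (1.5, 0.0, 0.0), True),
        ("O2", "O", "LIG", 1, "L", (-0.48, 1.36, 0.0), True),
        ("N1", "N", "LIG", 1, "L", (-0.54, -0.76, 1.27), True),
        ("N2", "N", "LIG", 1, "L", (-0.54, -0.76, -1.27), True),
    ]
    for k, p in enumerate(zn_positions):
        atoms.append(("ZN", "Zn", "ZN", 100 + k, "M", p, True))
    return structure_from_atoms(atoms, "toy")


def test_proximity_cutoff_is_closed():
    # zinc exactly at 6.0 A from the nearest motif atom is included
    st = _sulfamide_with_zn([(7.5, 0.0, 0.0)])  # exactly 6.0 from O1, further from the rest
    g = perceive_bonds(st, ("L", 1, "", "LIG"))
    mapping = match_substructure(g)[0]
    m = find_nearby_metals(st, ZBGMatch(st.id, ("L", 1, "", "LIG"), mapping))
    assert len(m.nearby_metals) == 1
    assert m.nearby_metals[0][1] == pytest.approx(6.0, abs=1e-9)
    far = _sulfamide_with_zn([(7.6, 0.0, 0.0)])
    m2 = find_nearby_metals(far, ZBGMatch(far.id, ("L", 1, "", "LIG"), mapping))
    assert m2.nearby_metals == []


def test_two_distant_zincs_are_not_binuclear():
    # both zincs within 6 A of the ligand, but 8 A apart: no binuclear center
    st = _sulfamide_with_zn([(4.0, 0.0, 0.0), (-4.0, 0.0, 0.0)])
    g = perceive_bonds(st, ("L", 1, "", "LIG"))
    mapping = match_substructure(g)[0]
    m = find_nearby_metals(st, ZBGMatch(st.id, ("L", 1, "", "LIG"), mapping))
    assert len(m.nearby_metals) == 2
    assert classify_nuclearity(m, st) == "mononuclear"


def test_fixture_site_is_binuclear(canonical_site):
    st, _ = canonical_site
    report = mine([st])
    (match,) = report.matches[st.id]
    assert match.nuclearity == "binuclear"


def test_mine_funnel_on_mixed_set(canonical_site):
    pos, _ = canonical_site
    mono, _ = build_decoy("mononuclear")
    nometal, _ = build_decoy("no_metal")
    report = mine([pos, mono, nometal])
    assert report.funnel() == (3, 2, 2, 2, 1)


def test_mine_empty_input():
    report = mine([])
    assert report.funnel() == (0, 0, 0, 0, 0)


def test_funnel_monotone(canonical_site, reference_complexes):
    pos, _ = canonical_site
    structures = [pos] + [build_decoy(k)[0] for k in
                          ("mononuclear", "sulfonamide_not_sulfamide", "no_metal")]
    structures += list(reference_complexes.values())
    counts = mine(structures).funnel()
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_atom_order_permutation_invariance(canonical_site):
    st, _ = canonical_site
    base = mine([st])
    rng = np.random.default_rng(7)
    for _ in range(3):
        perm = rng.permutation(len(st.atoms))
        atoms = [
            (a.name, a.element, a.residue_name, a.residue_seq, a.chain, a.position, a.is_hetero)
            for a in (st.atoms[i] for i in perm)
        ]
        shuffled = structure_from_atoms(atoms, st.id)
        rep = mine([shuffled])
        assert rep.funnel() == base.funnel()
        assert rep.matches[st.id][0].nuclearity == base.matches[st.id][0].nuclearity


def test_mining_params_validation():
    with pytest.raises(Exception):
        MiningParams(proximity_cutoff=-1.0)
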