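import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from _oracles import brute_force_min_rmsd
from bizinc.errors import DegenerateGeometryError, FrameError, ParameterError
from bizinc.superpose import (
    AtomPairing,
    CoordinateEnsemble,
    backbone_pairing,
    frame_from_component,
    headgroup_rotation,
    rmsf,
    superpose,
    zinc_displacement,
)
from bizinc.synthetic import SiteSpec, build_site


def test_self_superposition_identity():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(8, 3))
    res = superpose(a, a)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)
    assert res.rmsd < 1e-12


def test_exact_transform_recovery():
    rng = np.random.default_rng(1)
    a = rng.normal(size=(10, 3))
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    t = np.array([1.0, -2.0, 3.0])
    b = a @ R.T + t
    res = superpose(a, b)
    assert res.rmsd <= 1e-9
    np.testing.assert_allclose(res.rotation, R, atol=1e-9)
    np.testing.assert_allclose(res.translation, t, atol=1e-9)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0)


def test_rmsd_symmetric():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(12, 3))
    b = rng.normal(size=(12, 3))
    assert superpose(a, b).rmsd == pytest.approx(superpose(b, a).rmsd, abs=1e-9)


def test_rmsd_equals_grid_search_minimum():
    rng = np.random.default_rng(3)
    for _ in range(3):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        ours = superpose(a, b).rmsd
        oracle = brute_force_min_rmsd(a, b)
        assert abs(ours - oracle) <= 1e-3
        assert ours <= oracle + 1e-9  # least squares is never beaten


def test_collinear_pairing_rejected():
    a = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(DegenerateGeometryError):
        superpose(a, a + 1.0)


def test_pairing_must_be_injective():
    with pytest.raises(Exception):
        AtomPairing(pairs=[(0, 1), (0, 2), (1, 3)])


def _frames(structure):
    key = next(iter(structure.ligand_components()))
    return frame_from_component(structure, key, "S1", "N2")


def test_identical_structures_zero_rotation(canonical_site):
    st, _ = canonical_site
    f = _frames(st)
    assert headgroup_rotation(st, f, st, f) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("angle,folded", [(10.0, 10.0), (25.0, 25.0), (95.0, 25.0)])
def test_designed_rotation_recovered(angle, folded):
    # the three-fold base symmetry folds the measurable range to [0, 60]
    a, _ = build_site(SiteSpec(headgroup_rotation=0.0))
    b, _ = build_site(SiteSpec(headgroup_rotation=angle))
    measured = headgroup_rotation(a, _frames(a), b, _frames(b))
    assert measured == pytest.approx(folded, abs=0.1)


def test_rotation_symmetric_in_magnitude():
    a, _ = build_site(SiteSpec(headgroup_rotation=0.0))
    b, _ = build_site(SiteSpec(headgroup_rotation=25.0))
    ab = headgroup_rotation(a, _frames(a), b, _frames(b))
    ba = headgroup_rotation(b, _frames(b), a, _frames(a))
    assert ab == pytest.approx(ba, abs=1e-6)


def test_frame_requires_three_base_atoms(canonical_site):
    st, _ = canonical_site
    key = next(iter(st.ligand_components()))
    with pytest.raises(FrameError):
        frame_from_component(st, key, "O1", "S1")  # O1 has a single neighbor


def test_zinc_displacement_zero_for_identical(canonical_site):
    from bizinc.geometry import site_report
    from bizinc.mining import mine
    from bizinc.superpose import SuperpositionResult

    st, _ = canonical_site
    (match,) = mine([st]).matches[st.id]
    rep = site_report(st, match)
    table = zinc_displacement(st, rep, st, rep, SuperpositionResult.identity())
    assert np.allclose(table["displacement"], 0.0)


def test_zinc_displacement_detects_designed_shift(canonical_site):
    from bizinc.geometry import site_report
    from bizinc.mining import mine
    from bizinc.structures import structure_from_atoms
    from bizinc.superpose import SuperpositionResult

    st, _ = canonical_site
    shift = np.array([0.4, 0.0, 0.0])
    atoms = []
    for a in st.atoms:
        pos = a.position + shift if (a.element == "Zn" and a.residue_seq == 1) else a.position
        atoms.append((a.name, a.element, a.residue_name, a.residue_seq, a.chain, pos, a.is_hetero))
    moved = structure_from_atoms(atoms, st.id)
    (ma,) = mine([st]).matches[st.id]
    (mb,) = mine([moved]).matches[st.id]
    ra = site_report(st, ma)
    rb = site_report(moved, mb)
    table = zinc_displacement(st, ra, moved, rb, SuperpositionResult.identity())
    moved_rows = table[table.label.str.startswith("zn")]
    assert sorted(round(v, 6) for v in moved_rows["displacement"]) == [0.0, 0.4]


def test_rmsf_static_ensemble_zero():
    coords = np.tile(np.random.default_rng(4).normal(size=(6, 3)), (5, 1, 1))
    assert np.allclose(rmsf(CoordinateEnsemble(coords)), 0.0)


def test_rmsf_two_frame_hand_case():
    base = np.random.default_rng(5).normal(size=(4, 3))
    moved = base.copy()
    moved[2] += np.array([0.8, 0.0, 0.0])
    values = rmsf(CoordinateEnsemble(np.stack([base, moved])), superpose_frames=False)
    assert values[2] == pytest.approx(0.4)
    assert np.allclose(np.delete(values, 2), 0.0)


def test_rmsf_invariant_under_per_frame_rigid_motion():
    rng = np.random.default_rng(6)
    base = rng.normal(size=(20, 3))
    frames = np.stack([base + rng.normal(0, 0.1, size=base.shape) for _ in range(30)])
    plain = rmsf(CoordinateEnsemble(frames), superpose_frames=True)
    moved = np.empty_like(frames)
    for t in range(frames.shape[0]):
        R = Rotation.random(random_state=np.random.RandomState(t)).as_matrix()
        moved[t] = frames[t] @ R.T + rng.normal(0, 5.0, size=3)
    realigned = rmsf(CoordinateEnsemble(moved), superpose_frames=True)
    np.testing.assert_allclose(realigned, plain, atol=1e-6)


def test_rmsf_empty_selection(canonical_site):
    with pytest.raises(ParameterError):
        rmsf(CoordinateEnsemble(np.zeros((3, 4, 3))), selection=[])


def test_backbone_pairing_on_reference_complexes(reference_complexes):
    a = reference_complexes["4W9Y"]
    b = reference_complexes["2PVW"]
    pairing = backbone_pairing(a, b)
    assert len(pairing.pairs) >= 3
    sup = superpose(a.positions, b.positions, pairing)
    assert sup.rmsd < 1e-9  # shared scaffold by construction
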