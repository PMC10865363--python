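import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bizinc.errors import DomainError, SelectionError
from bizinc.nci import (
    NCIParams,
    classify_interactions,
    compute_field,
    promolecular_density,
    reduced_density_gradient,
    signed_density,
)
from bizinc.synthetic import SiteSpec, build_site

COARSE = NCIParams(grid_spacing=0.35)


def test_density_decays_radially():
    atoms = [("C", np.zeros(3))]
    rho_near, _, _ = promolecular_density(atoms, np.array([[0.5, 0, 0]]))
    rho_far, _, _ = promolecular_density(atoms, np.array([[1.0, 0, 0]]))
    assert rho_near[0] > rho_far[0] > 0


def test_analytic_gradient_and_hessian_match_numeric():
    rng = np.random.default_rng(21)
    atoms = [("C", np.zeros(3)), ("N", np.array([1.4, 0.2, -0.3])), ("O", np.array([-1.0, 1.1, 0.8]))]
    # points away from the nuclei, where the finite difference is well behaved
    points = rng.uniform(-3.0, 3.0, size=(100, 3))
    points = points[np.all([np.linalg.norm(points - p, axis=1) > 0.4 for _, p in atoms], axis=0)]
    rho, grad, hess = promolecular_density(atoms, points)
    h = 1e-5  # angstrom
    for k in range(3):
        step = np.zeros(3)
        step[k] = h
        rp, gp, _ = promolecular_density(atoms, points + step)
        rm, gm, _ = promolecular_density(atoms, points - step)
        # gradient: d(rho)/dx_k in a.u. per bohr
        num_g = (rp - rm) / (2 * h * 1.8897259886)
        scale = np.maximum(np.abs(grad[:, k]), 1e-12)
        assert np.max(np.abs(num_g - grad[:, k]) / np.maximum(scale, np.abs(rho) * 1e-3)) < 1e-5
        num_h = (gp - gm) / (2 * h * 1.8897259886)
        hscale = np.maximum(np.abs(hess[:, k, :]), np.abs(rho)[:, None])
        assert np.max(np.abs(num_h - hess[:, k, :]) / hscale) < 1e-5


def test_homonuclear_midpoint_gradient_vanishes():
    atoms = [("N", np.array([-0.7, 0, 0])), ("N", np.array([0.7, 0, 0]))]
    _, grad, _ = promolecular_density(atoms, np.zeros((1, 3)))
    assert np.linalg.norm(grad) < 1e-12


def test_rdg_closed_form_spot_value():
    s = reduced_density_gradient(np.array([1.0]), np.array([[1.0, 0.0, 0.0]]))
    want = 1.0 / (2.0 * (3.0 * math.pi**2) ** (1.0 / 3.0))
    assert s[0] == pytest.approx(want, rel=1e-12)
    assert want == pytest.approx(0.1616, abs=5e-5)


def test_rdg_zero_gradient_and_linearity():
    assert reduced_density_gradient(np.array([0.3]), np.zeros((1, 3)))[0] == 0.0
    s1 = reduced_density_gradient(np.array([0.3]), np.array([[0.1, 0.2, -0.2]]))
    s2 = reduced_density_gradient(np.array([0.3]), np.array([[0.2, 0.4, -0.4]]))
    assert s2[0] == pytest.approx(2 * s1[0])


def test_rdg_domain_error():
    with pytest.raises(DomainError):
        reduced_density_gradient(np.array([0.0]), np.zeros((1, 3)))


def test_signed_density_middle_eigenvalue():
    h_neg = np.diag([-2.0, -1.0, 3.0])
    h_pos = np.diag([-1.0, 2.0, 3.0])
    assert signed_density(0.05, h_neg) == pytest.approx(-0.05)
    assert signed_density(0.05, h_pos) == pytest.approx(+0.05)


def test_single_atom_lambda2_negative_off_nucleus():
    atoms = [("C", np.zeros(3))]
    rho, _, hess = promolecular_density(atoms, np.array([[1.2, 0, 0]]))
    lam = np.linalg.eigvalsh(hess[0])
    assert lam[1] < 0  # curvature orthogonal to the radius is bonding-like


def test_density_invariant_under_rigid_motion():
    rng = np.random.default_rng(31)
    atoms = [("C", rng.normal(size=3)), ("O", rng.normal(size=3)), ("N", rng.normal(size=3))]
    pts = rng.normal(size=(20, 3)) * 2.0
    R = Rotation.from_rotvec([0.4, 0.9, -0.2]).as_matrix()
    t = np.array([3.0, -1.0, 2.0])
    rho_a, _, _ = promolecular_density(atoms, pts)
    moved = [(el, R @ p + t) for el, p in atoms]
    rho_b, _, _ = promolecular_density(moved, pts @ R.T + t)
    np.testing.assert_allclose(rho_b, rho_a, rtol=1e-12)


def test_field_positivity_and_mask(canonical_site):
    st, _ = canonical_site
    fields = compute_field(st, COARSE)
    assert np.all(fields.rho > 0)
    assert np.all(fields.rdg >= 0)
    # monotone masking: raising the cutoff never removes unmasked points
    tighter = fields.rho <= 0.1
    looser = fields.rho <= 0.5
    assert np.all(looser[tighter])


def test_two_atom_rdg_trough():
    from bizinc.structures import structure_from_atoms

    st = structure_from_atoms(
        [
            ("ZN", "Zn", "ZN", 1, "M", (0.0, 0.0, 0.0), True),
            ("N1", "N", "LIG", 2, "L", (2.1, 0.0, 0.0), True),
        ],
        "pair",
    )
    xs = np.linspace(0.3, 1.8, 40)
    pts = np.stack([xs, np.zeros_like(xs), np.zeros_like(xs)], axis=1)
    atoms = [("Zn", np.zeros(3)), ("N", np.array([2.1, 0, 0]))]
    rho, grad, _ = promolecular_density(atoms, pts)
    s = reduced_density_gradient(rho, grad)
    k = int(np.argmin(s))
    assert 0 < k < len(xs) - 1  # interior low-s trough between the atoms
    assert s[k] < 0.3


def test_strong_attraction_at_bridging_contact(canonical_site):
    st, _ = canonical_site
    fields = compute_field(st, COARSE)
    summary = classify_interactions(fields, COARSE, st)
    assert summary.n_analyzed > 0
    assert summary.fraction_strong_attractive > 0
    pp = summary.per_pair
    lig_zn = pp[
        (pp.atom_a.str.startswith(("LIG", "ZN")))
        & (pp.atom_b.str.startswith(("LIG", "ZN")))
        & (pp.atom_a.str[:2] != pp.atom_b.str[:2])
    ]
    assert lig_zn["strong_attractive"].sum() > 0


def test_extreme_threshold_empties_class(canonical_site):
    st, _ = canonical_site
    fields = compute_field(st, COARSE)
    params = NCIParams(grid_spacing=0.35, strong_attraction_threshold=-1e9)
    summary = classify_interactions(fields, params)
    assert summary.fraction_strong_attractive == 0.0


def test_all_zero_signed_rho_is_vdw(canonical_site):
    st, _ = canonical_site
    fields = compute_field(st, COARSE)
    fields.signed_rho = np.zeros_like(fields.signed_rho)
    summary = classify_interactions(fields, COARSE)
    assert summary.fraction_vdw == 1.0
    assert summary.fraction_strong_attractive == 0.0


def test_field_requires_metal():
    from bizinc.structures import structure_from_atoms

    st = structure_from_atoms([("C1", "C", "LIG", 1, "L", (0, 0, 0), True)], "nometal")
    with pytest.raises(SelectionError):
        compute_field(st, COARSE)


def test_headgroup_contrast_between_binding_modes(reference_complexes):
    """The bridging-amine complex shows more ligand-zinc strong attraction
    than either bisubstituted complex, where the sulfamide has retreated to
    the second shell."""
    params = NCIParams(grid_spacing=0.35)

    def ligand_zn_strong(st):
        fields = compute_field(st, params)
        pp = classify_interactions(fields, params, st).per_pair
        if pp.empty:
            return 0
        mask = (
            (pp.atom_a.str.startswith("LIG") & pp.atom_b.str.startswith("ZN"))
            | (pp.atom_b.str.startswith("LIG") & pp.atom_a.str.startswith("ZN"))
        )
        return int(pp[mask]["strong_attractive"].sum())

    mono = ligand_zn_strong(reference_complexes["4W9Y"])
    bis3 = ligand_zn_strong(reference_complexes["6SKH"])
    bis4 = ligand_zn_strong(reference_complexes["6SGP"])
    assert mono > bis3
    assert mono > bis4
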