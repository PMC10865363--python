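"""Synthetic stand-in models of the five inhibitor complexes.

These are NOT deposited coordinates. Each model is an idealized synthetic
active site constructed so that the published heavy-atom distances of the
corresponding crystallographic complex hold exactly: the two zinc ions at
the reported separation, the tetrahedral sulfamide / phosphinate headgroup
posed so its nitrogen/oxygen atoms reproduce the reported zinc and
hydrogen-bond distances, coordinating-residue mimics at dative distances,
the catalytic water where the complex retains one, and a shared backbone
scaffold so complexes can be superposed onto each other. The sulfamide
(4W9Y-like) and phosphinate (2PVW-like) headgroups are built with a designed
22 degree rotation of the tetrahedral base about the headgroup axis,
mirroring the reorientation seen between the real complexes.

The models make the whole pipeline (mining, coordination geometry,
superposition, rotation measurement, cluster extraction, NCI fields)
exercisable offline; they encode published distances as design inputs, so
recomputing those distances validates the measurement pipeline, not the
crystallography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import GenerationError
from .structures import Structure, structure_from_atoms

TETRA = math.degrees(math.acos(-1.0 / 3.0))

BOND_S_N = 1.62
BOND_S_O = 1.44
BOND_P_O = 1.50
BOND_P_C = 1.80
BOND_N_C = 1.47
DATIVE = 2.05

ENTRY_IDS = ("4W9Y", "6SKH", "6SGP", "2PVW", "3BI0")


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _perp(z):
    z = _unit(z)
    probe = np.array([0.0, 0.0, 1.0]) if abs(z[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    x = _unit(np.cross(probe, z))
    return x, np.cross(z, x)


def _solve_point(constraints, init, tol=1e-10):
    """Point satisfying |p - center_k| = radius_k for each constraint."""
    centers = np.array([c for c, _ in constraints], float)
    radii = np.array([r for _, r in constraints], float)

    def resid(p):
        base = np.linalg.norm(centers - p, axis=1) - radii
        # weak pull toward the initial guess resolves underdetermined cases
        return np.concatenate([base, 1e-4 * (p - init)])

    sol = least_squares(resid, np.asarray(init, float), xtol=1e-14, ftol=1e-14)
    err = np.max(np.abs(np.linalg.norm(centers - sol.x, axis=1) - radii))
    if err > 1e-6:
        raise GenerationError(f"distance constraints unsatisfiable (residual {err:.2e})")
    return sol.x


@dataclass
class _Builder:
    atoms: list

    def add(self, name, element, resname, seq, chain, pos, hetero):
        self.atoms.append((name, element, resname, seq, chain, np.asarray(pos, float), hetero))
        return len(self.atoms) - 1


# ---------------------------------------------------------------------------
# shared scaffold
# ---------------------------------------------------------------------------

_CENTER = np.array([1.65, 0.5, 0.0])

# residue seq -> (resname, azimuth deg in xy, z offset) for backbone markers
_SCAFFOLD_RESIDUES = [
    (377, "HIS", 15.0, 1.2),
    (387, "ASP", 265.0, -0.8),
    (424, "MET", 230.0, 1.8),
    (425, "GLU", 300.0, 1.5),
    (453, "ASP", 330.0, -1.6),
    (518, "GLY", 95.0, -1.8),
    (519, "ASN", 120.0, 1.0),
    (534, "ARG", 160.0, -0.5),
    (552, "TYR", 200.0, 0.8),
    (553, "HIS", 60.0, -1.2),
]
_SCAFFOLD_RADIUS = 6.5


def _add_scaffold(b: _Builder) -> None:
    """Backbone markers shared by all stand-ins (the superposition context)."""
    for seq, resname, az, dz in _SCAFFOLD_RESIDUES:
        a = math.radians(az)
        radial = np.array([math.cos(a), math.sin(a), 0.0])
        tang = np.array([-math.sin(a), math.cos(a), 0.0])
        ca = _CENTER + _SCAFFOLD_RADIUS * radial + np.array([0.0, 0.0, dz])
        b.add("N", "N", resname, seq, "A", ca - 1.45 * tang + np.array([0, 0, 0.3]), False)
        b.add("CA", "C", resname, seq, "A", ca, False)
        b.add("C", "C", resname, seq, "A", ca + 1.50 * tang, False)
    # methionine sulfur: keeps the element prefilter honest for the
    # phosphorus-ligand complexes (protein sulfur is ubiquitous in reality)
    met_ca = _CENTER + _SCAFFOLD_RADIUS * np.array(
        [math.cos(math.radians(230)), math.sin(math.radians(230)), 0.0]
    ) + np.array([0.0, 0.0, 1.8])
    b.add("SD", "S", "MET", 424, "A", met_ca + np.array([0.0, -1.2, 1.4]), False)


def _imidazole_ring(b: _Builder, seq: int, donor, outward) -> None:
    side = 1.37
    radius = side / (2.0 * math.sin(math.pi / 5.0))
    u = _unit(outward)
    w, _ = _perp(u)
    center = donor + radius * u
    for k, (nm, el) in enumerate(
        [("NE2", "N"), ("CE1", "C"), ("ND1", "N"), ("CG", "C"), ("CD2", "C")]
    ):
        theta = 2.0 * math.pi * k / 5.0
        b.add(nm, el, "HIS", seq, "A", center + radius * (-math.cos(theta) * u + math.sin(theta) * w), False)


def _add_donors(b: _Builder, zn1, zn2, asp453_od1=None) -> None:
    """Zinc-coordinating side-chain mimics; positions follow the zincs."""
    _imidazole_ring(b, 553, zn1 + DATIVE * _unit([-0.70, -0.35, 0.62]), [-0.70, -0.35, 0.62])
    _imidazole_ring(b, 377, zn2 + DATIVE * _unit([0.70, -0.35, 0.62]), [0.70, -0.35, 0.62])
    # bridging carboxylate (one oxygen to each zinc, on the -y face)
    od1 = zn1 + DATIVE * _unit([-0.15, -0.92, -0.36])
    od2 = zn2 + DATIVE * _unit([0.15, -0.92, -0.36])
    cg = 0.5 * (od1 + od2) + np.array([0.0, -1.05, -0.4])
    b.add("OD1", "O", "ASP", 387, "A", od1, False)
    b.add("OD2", "O", "ASP", 387, "A", od2, False)
    b.add("CG", "C", "ASP", 387, "A", cg, False)
    # monodentate carboxylates: Asp453 on the first zinc, Glu425 on the second
    if asp453_od1 is None:
        asp453_od1 = zn1 + DATIVE * _unit([-0.30, -0.25, -0.92])
    b.add("OD1", "O", "ASP", 453, "A", asp453_od1, False)
    b.add("CG", "C", "ASP", 453, "A", asp453_od1 + 1.25 * _unit([-0.4, -0.5, -0.75]), False)
    oe1 = zn2 + DATIVE * _unit([0.30, -0.25, -0.92])
    b.add("OE1", "O", "GLU", 425, "A", oe1, False)
    b.add("CD", "C", "GLU", 425, "A", oe1 + 1.25 * _unit([0.4, -0.5, -0.75]), False)


def _add_bulk_waters(b: _Builder) -> None:
    b.add("O", "O", "HOH", 901, "W", _CENTER + np.array([0.0, 9.0, 2.0]), True)
    b.add("O", "O", "HOH", 902, "W", _CENTER + np.array([-2.0, 9.5, -2.0]), True)


# ---------------------------------------------------------------------------
# headgroup poses
# ---------------------------------------------------------------------------


_TETRA_BASE_DIRS = [
    np.array(
        [
            2.0 * math.sqrt(2.0) / 3.0 * math.cos(math.radians(p)),
            2.0 * math.sqrt(2.0) / 3.0 * math.sin(math.radians(p)),
            -1.0 / 3.0,
        ]
    )
    for p in (0.0, 120.0, 240.0)
]

#: Ideal sulfamide template in local coordinates (S at the origin, the
#: linking nitrogen N2 along +z, the tetrahedral base below).
_SULFAMIDE_LOCAL = {
    "N2": BOND_S_N * np.array([0.0, 0.0, 1.0]),
    "O1": BOND_S_O * _TETRA_BASE_DIRS[0],
    "O2": BOND_S_O * _TETRA_BASE_DIRS[1],
    "N1": BOND_S_N * _TETRA_BASE_DIRS[2],
}


def _fit_headgroup_pose(
    constraints: list[tuple[str, np.ndarray, float]],
    avoid: list[tuple[np.ndarray, float]],
    seed: int = 7,
    n_trials: int = 200,
) -> dict[str, np.ndarray]:
    """Rigid-body fit of the ideal sulfamide template to distance targets.

    ``constraints`` are (atom name, anchor point, distance). A seeded
    multi-start least-squares search finds the pose; among solutions that
    satisfy every constraint to < 1e-7 angstrom and keep all template atoms
    clear of the ``avoid`` spheres, the one whose linking substituent points
    farthest out of the site (+y) is chosen — deterministic by construction.
    """
    local = _SULFAMIDE_LOCAL
    anchors = np.array([c[1] for c in constraints])
    center = anchors.mean(axis=0)
    rng = np.random.default_rng(seed)

    def atoms_at(params):
        t = params[:3]
        rot = Rotation.from_rotvec(params[3:])
        return {k: t + rot.apply(v) for k, v in local.items()}

    def resid(params):
        pos = atoms_at(params)
        return np.array(
            [np.linalg.norm(pos[name] - anchor) - dist for name, anchor, dist in constraints]
        )

    best = None
    for _ in range(n_trials):
        t0 = center + np.array([0.0, 2.0, 0.0]) + rng.normal(0.0, 1.2, 3)
        r0 = rng.normal(0.0, 1.5, 3)
        sol = least_squares(resid, np.concatenate([t0, r0]), xtol=1e-14, ftol=1e-14)
        if np.max(np.abs(resid(sol.x))) > 1e-7:
            continue
        pos = atoms_at(sol.x)
        pos["S1"] = sol.x[:3]
        clear = min(
            (np.linalg.norm(p - c) - r)
            for p in pos.values()
            for c, r in avoid
        ) if avoid else 0.0
        if clear < 0.0:
            continue
        score = float(pos["N2"][1]) + 0.2 * min(clear, 1.0)
        if best is None or score > best[0] + 1e-12:
            best = (score, pos)
    if best is None:
        raise GenerationError("no feasible headgroup pose satisfies the distance targets")
    pos = best[1]
    s = pos["S1"]
    pos["C7"] = pos["N1"] + BOND_N_C * _unit((pos["N1"] - s) + np.array([0.0, 0.3, 0.8]))
    pos["C8"] = pos["N2"] + BOND_N_C * _unit((pos["N2"] - s) + np.array([0.0, 0.35, 0.55]))
    return pos


def _sulfamide_mono_pose(zn1, zn2, n_zn1, n_zn2, o1_zn1):
    """Canonical bridging pose: the free amine N1 between the zincs."""
    pose = _fit_headgroup_pose(
        [("N1", zn1, n_zn1), ("N1", zn2, n_zn2), ("O1", zn1, o1_zn1)],
        avoid=[(zn1, 1.9), (zn2, 1.9)],
    )
    pose.pop("C7")  # monosubstituted: the bridging amine stays terminal
    return pose


def _sulfamide_bis_pose(zn1, zn2, water, o1_zn1, n1_zn2, n1_w):
    """Linker-like pose of the bisubstituted sulfamides (second shell only)."""
    return _fit_headgroup_pose(
        [("O1", zn1, o1_zn1), ("N1", zn2, n1_zn2), ("N1", water, n1_w)],
        avoid=[(zn1, 1.9), (zn2, 1.9), (water, 2.0)],
    )


def _sulfamide_pose_constrained(zn1, zn2, water, o1_zn1, o2_zn2, o2_w):
    """Rotated-by-120 pattern: the second oxygen toward water and second zinc."""
    return _fit_headgroup_pose(
        [("O1", zn1, o1_zn1), ("O2", zn2, o2_zn2), ("O2", water, o2_w)],
        avoid=[(zn1, 1.9), (zn2, 1.9), (water, 2.0)],
    )


# ---------------------------------------------------------------------------
# entry builders
# ---------------------------------------------------------------------------


def _hb_partner(target, dist, away_from, init_dir):
    """Place a hydrogen-bond partner at an exact distance, pointing outward."""
    init = target + dist * _unit(init_dir)
    return _solve_point([(target, dist)], init=init)


def _build_4w9y() -> Structure:
    zn1 = np.array([0.0, 0.0, 0.0])
    zn2 = np.array([3.3, 0.0, 0.0])
    pose = _sulfamide_mono_pose(zn1, zn2, n_zn1=2.2, n_zn2=2.1, o1_zn1=2.6)
    b = _Builder([])
    b.add("ZN", "Zn", "ZN", 501, "M", zn1, True)
    b.add("ZN", "Zn", "ZN", 502, "M", zn2, True)
    for name in ("S1", "O1", "O2", "N1", "N2", "C8"):
        el = name[0] if name[0] in "SON" else "C"
        b.add(name, el, "LIG", 601, "L", pose[name], True)
    _add_scaffold(b)
    _add_donors(b, zn1, zn2)
    site_center = 0.5 * (zn1 + zn2)
    nd2 = _hb_partner(pose["O1"], 2.9, site_center, pose["O1"] - site_center + np.array([0, 0.4, 0.9]))
    b.add("ND2", "N", "ASN", 519, "A", nd2, False)
    b.add("CG", "C", "ASN", 519, "A", nd2 + 1.33 * _unit(nd2 - site_center), False)
    oh = _hb_partner(pose["O2"], 2.6, site_center, pose["O2"] - site_center + np.array([0, 0.2, -0.9]))
    b.add("OH", "O", "TYR", 552, "A", oh, False)
    _add_bulk_waters(b)
    return structure_from_atoms(b.atoms, "4W9Y-synthetic")


def _phosphorus_variant(entry_id: str, resname: str, phosphinate: bool) -> Structure:
    """2PVW-like / 3BI0-like model: headgroup = the 4W9Y sulfamide base rotated
    by 22 degrees about the headgroup axis, with phosphorus bond lengths and
    the zinc pair widened to 3.6 angstrom about the same midpoint."""
    zn1 = np.array([-0.15, 0.0, 0.0])
    zn2 = np.array([3.45, 0.0, 0.0])
    ref = _sulfamide_mono_pose(
        np.array([0.0, 0.0, 0.0]), np.array([3.3, 0.0, 0.0]), 2.2, 2.1, 2.6
    )
    s = ref["S1"]
    axis = _unit(ref["N2"] - s)
    rot = Rotation.from_rotvec(axis * math.radians(22.0))
    base = {}
    for src in ("O1", "O2", "N1"):
        base[src] = s + rot.apply(ref[src] - s)
    b = _Builder([])
    b.add("ZN", "Zn", "ZN", 501, "M", zn1, True)
    b.add("ZN", "Zn", "ZN", 502, "M", zn2, True)
    b.add("P1", "P", resname, 601, "L", s, True)
    b.add("O1", "O", resname, 601, "L", s + BOND_P_O * _unit(base["O1"] - s), True)
    b.add("O2", "O", resname, 601, "L", s + BOND_P_O * _unit(base["O2"] - s), True)
    third = "C2" if phosphinate else "O3"
    third_len = BOND_P_C if phosphinate else BOND_P_O
    b.add(third, third[0], resname, 601, "L", s + third_len * _unit(base["N1"] - s), True)
    c1 = s + BOND_P_C * axis
    b.add("C1", "C", resname, 601, "L", c1, True)
    b.add("C8", "C", resname, 601, "L", c1 + 1.53 * _unit((c1 - s) + np.array([0.0, 0.35, 0.55])), True)
    _add_scaffold(b)
    _add_donors(b, zn1, zn2)
    _add_bulk_waters(b)
    return structure_from_atoms(b.atoms, entry_id)


def _catalytic_water(zn1, zn2) -> np.ndarray:
    """Bridging water/hydroxide oxygen ~2.0 angstrom from both zincs."""
    d = np.linalg.norm(zn2 - zn1)
    x = d / 2.0
    y = math.sqrt(max(4.0 - x * x, 0.04))
    return zn1 + x * _unit(zn2 - zn1) + y * np.array([0.0, 1.0, 0.0])


def _build_6skh() -> Structure:
    zn1 = np.array([0.0, 0.0, 0.0])
    zn2 = np.array([3.3, 0.0, 0.0])
    w = _catalytic_water(zn1, zn2)
    pose = _sulfamide_bis_pose(zn1, zn2, w, o1_zn1=2.9, n1_zn2=3.6, n1_w=2.8)
    b = _Builder([])
    b.add("ZN", "Zn", "ZN", 501, "M", zn1, True)
    b.add("ZN", "Zn", "ZN", 502, "M", zn2, True)
    for name in ("S1", "O1", "O2", "N1", "N2", "C7", "C8"):
        el = name[0] if name[0] in "SON" else "C"
        b.add(name, el, "LIG", 601, "L", pose[name], True)
    _add_scaffold(b)
    _add_donors(b, zn1, zn2)
    site_center = 0.5 * (zn1 + zn2)
    oh = _hb_partner(pose["O1"], 2.5, site_center, pose["O1"] - site_center + np.array([0, 0.2, -0.9]))
    b.add("OH", "O", "TYR", 552, "A", oh, False)
    b.add("O", "O", "HOH", 700, "W", w, True)
    _add_bulk_waters(b)
    return structure_from_atoms(b.atoms, "6SKH-synthetic")


def _build_6sgp() -> Structure:
    zn1 = np.array([0.0, 0.0, 0.0])
    zn2 = np.array([3.3, 0.0, 0.0])
    w = _catalytic_water(zn1, zn2)
    # the rotated-by-120 pattern: the first oxygen keeps the 6SKH-like
    # contact, the second oxygen takes over the water/second-zinc region
    pose = _sulfamide_pose_constrained(zn1, zn2, w, o1_zn1=2.9, o2_zn2=3.4, o2_w=2.7)
    b = _Builder([])
    b.add("ZN", "Zn", "ZN", 501, "M", zn1, True)
    b.add("ZN", "Zn", "ZN", 502, "M", zn2, True)
    for name in ("S1", "O1", "O2", "N1", "N2", "C7", "C8"):
        el = name[0] if name[0] in "SON" else "C"
        b.add(name, el, "LIG", 601, "L", pose[name], True)
    _add_scaffold(b)
    site_center = 0.5 * (zn1 + zn2)
    # Asp453 oxygen is both a first-zinc ligand and 3.2 A from the sulfamide O2
    od1 = _solve_point(
        [(zn1, DATIVE), (pose["O2"], 3.2)],
        init=zn1 + DATIVE * _unit([-0.3, -0.25, -0.92]),
    )
    _add_donors(b, zn1, zn2, asp453_od1=od1)
    oh = _hb_partner(pose["O1"], 2.5, site_center, pose["O1"] - site_center + np.array([0, 0.2, -0.9]))
    b.add("OH", "O", "TYR", 552, "A", oh, False)
    nd2 = _hb_partner(pose["O2"], 3.1, site_center, pose["O2"] - site_center + np.array([0, 0.4, 0.9]))
    b.add("ND2", "N", "ASN", 519, "A", nd2, False)
    b.add("CG", "C", "ASN", 519, "A", nd2 + 1.33 * _unit(nd2 - site_center), False)
    b.add("O", "O", "HOH", 700, "W", w, True)
    _add_bulk_waters(b)
    return structure_from_atoms(b.atoms, "6SGP-synthetic")


_BUILDERS = {
    "4W9Y": _build_4w9y,
    "6SKH": _build_6skh,
    "6SGP": _build_6sgp,
    "2PVW": lambda: _phosphorus_variant("2PVW-synthetic", "PMP", phosphinate=False),
    "3BI0": lambda: _phosphorus_variant("3BI0-synthetic", "EPE", phosphinate=True),
}


def synthetic_complex(entry_id: str) -> Structure:
    """Synthetic stand-in model for one of the five studied complexes."""
    key = entry_id.upper().replace("-SYNTHETIC", "")
    if key not in _BUILDERS:
        raise GenerationError(f"no synthetic model for {entry_id!r}; know {ENTRY_IDS}")
    return _BUILDERS[key]()


def all_synthetic_complexes() -> dict[str, Structure]:
    return {k: _BUILDERS[k]() for k in ENTRY_IDS}


#: Published heavy-atom distances (angstrom) encoded in the stand-ins.
#: Each row: (entry, label, selector_a, selector_b, value).
PUBLISHED_DISTANCES = [
    ("4W9Y", "sulfamide N - catalytic Zn", {"resname": "LIG", "name": "N1"}, {"resname": "ZN", "seq": 501}, 2.2),
    ("4W9Y", "sulfamide N - cocatalytic Zn", {"resname": "LIG", "name": "N1"}, {"resname": "ZN", "seq": 502}, 2.1),
    ("4W9Y", "sulfamide O - catalytic Zn", {"resname": "LIG", "name": "O1"}, {"resname": "ZN", "seq": 501}, 2.6),
    ("4W9Y", "Zn - Zn", {"resname": "ZN", "seq": 501}, {"resname": "ZN", "seq": 502}, 3.3),
    ("4W9Y", "sulfamide O1 - Asn519", {"resname": "LIG", "name": "O1"}, {"resname": "ASN", "seq": 519, "name": "ND2"}, 2.9),
    ("4W9Y", "sulfamide O2 - Tyr552", {"resname": "LIG", "name": "O2"}, {"resname": "TYR", "seq": 552, "name": "OH"}, 2.6),
    ("2PVW", "Zn - Zn", {"resname": "ZN", "seq": 501}, {"resname": "ZN", "seq": 502}, 3.6),
    ("6SKH", "sulfamide O1 - Tyr552", {"resname": "LIG", "name": "O1"}, {"resname": "TYR", "seq": 552, "name": "OH"}, 2.5),
    ("6SKH", "sulfamide O1 - catalytic Zn", {"resname": "LIG", "name": "O1"}, {"resname": "ZN", "seq": 501}, 2.9),
    ("6SKH", "sulfamide N - catalytic water", {"resname": "LIG", "name": "N1"}, {"resname": "HOH", "seq": 700}, 2.8),
    ("6SKH", "sulfamide N - cocatalytic Zn", {"resname": "LIG", "name": "N1"}, {"resname": "ZN", "seq": 502}, 3.6),
    ("6SGP", "sulfamide O2 - catalytic water", {"resname": "LIG", "name": "O2"}, {"resname": "HOH", "seq": 700}, 2.7),
    ("6SGP", "sulfamide O2 - Asn519", {"resname": "LIG", "name": "O2"}, {"resname": "ASN", "seq": 519, "name": "ND2"}, 3.1),
    ("6SGP", "sulfamide O2 - Asp453", {"resname": "LIG", "name": "O2"}, {"resname": "ASP", "seq": 453, "name": "OD1"}, 3.2),
    ("6SGP", "sulfamide O2 - cocatalytic Zn", {"resname": "LIG", "name": "O2"}, {"resname": "ZN", "seq": 502}, 3.4),
]


def measure_published_distances(structures: dict[str, Structure] | None = None):
    """Recompute every encoded published distance; returns a DataFrame."""
    import pandas as pd

    structures = structures or all_synthetic_complexes()
    rows = []
    for entry, label, sel_a, sel_b, expected in PUBLISHED_DISTANCES:
        st = structures[entry]
        ia = st.select_one(**sel_a)
        ib = st.select_one(**sel_b)
        d = float(np.linalg.norm(st.atoms[ia].position - st.atoms[ib].position))
        rows.append(
            {
                "entry": entry,
                "label": label,
                "computed": d,
                "computed_rounded": round(d, 1),
                "expected": expected,
                "abs_diff": abs(d - expected),
            }
        )
    return pd.DataFrame(rows)
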