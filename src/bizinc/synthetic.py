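"""Synthetic binuclear zinc sites with machine-readable ground truth.

The generator emulates the geometry of a dizinc metallopeptidase active site
bound to a tetrahedral inhibitor headgroup: two Zn ions at a parameterized
separation, protein-like coordinating groups (imidazole nitrogens,
carboxylate oxygens) placed at dative-bond distances, a sulfamide or
phosphinate headgroup whose bridging atom sits at requested distances from
the two metals, ordered waters, and optional Gaussian coordinate noise.
Ground truth (match count, nuclearity, shell assignments, hydrogen-bond
pairs, designed headgroup rotation) is recorded from the noise-free design
coordinates, so every downstream stage of the pipeline can be tested without
any external structure download.

Coordinating groups are minimal chemical mimics (a bare imidazole ring, an
acetate-like carboxylate) rather than full residues; the point is an
unambiguous, tiny fixture, not force-field realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GenerationError, ParameterError
from .structures import Structure, structure_from_atoms

TETRAHEDRAL_ANGLE = math.degrees(math.acos(-1.0 / 3.0))  # 109.47 deg

# heavy-atom bond lengths used in the idealized headgroups (angstrom)
BOND_S_N = 1.62
BOND_S_O = 1.44
BOND_P_O = 1.52
BOND_P_C = 1.80
BOND_N_C = 1.47
BOND_C_C = 1.53
DATIVE_DISTANCE = 2.05  # protein donor -> Zn

HEADGROUPS = ("sulfamide_mono", "sulfamide_bis", "phosphinate", "none")


@dataclass
class SiteSpec:
    """Design parameters of one synthetic binuclear site."""

    zn_zn_distance: float = 3.3
    ligand_headgroup: str = "sulfamide_mono"
    n_to_zn_distances: tuple[float, float] = (2.2, 2.1)
    headgroup_rotation: float = 0.0
    n_coordinating_residues: int = 4
    n_waters: int = 2
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (2.8 <= self.zn_zn_distance <= 6.0):
            raise ParameterError(f"zn_zn_distance {self.zn_zn_distance} outside [2.8, 6.0]")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.ligand_headgroup not in HEADGROUPS:
            raise ParameterError(f"unknown headgroup {self.ligand_headgroup!r}")
        if self.n_coordinating_residues < 0 or self.n_waters < 0:
            raise ParameterError("counts must be non-negative")


@dataclass
class GroundTruth:
    """Design-time truth emitted before noise is applied."""

    expected_matches: int
    nuclearity: str  # "bi", "mono" or "none"
    shell_assignments: dict[int, str]  # atom index -> first/second/none
    hbond_pairs: list[tuple[int, int]]
    rotation_angle: float
    water_count: int | None = None
    zn_indices: list[int] = field(default_factory=list)
    ligand_indices: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["shell_assignments"] = {str(k): v for k, v in d["shell_assignments"].items()}
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# geometric helpers
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GenerationError("zero-length direction vector")
    return v / n


def _perp_frame(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = _unit(z)
    probe = np.array([0.0, 0.0, 1.0]) if abs(z[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    x = _unit(np.cross(probe, z))
    y = np.cross(z, x)
    return x, y


def _rot_about(axis: np.ndarray, degrees: float) -> Rotation:
    return Rotation.from_rotvec(_unit(axis) * math.radians(degrees))


def tetrahedral_headgroup(
    central: np.ndarray,
    axis_dir: np.ndarray,
    base_azimuth: float,
    base_lengths: tuple[float, float, float],
    axis_length: float,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Idealized tetrahedral group around ``central``.

    The axis substituent lies along ``axis_dir``; the three base substituents
    sit at the tetrahedral angle from the axis at azimuths
    ``base_azimuth + {0, 120, 240}`` degrees. Returns (axis_atom, [base atoms]).
    """
    z = _unit(axis_dir)
    x, y = _perp_frame(z)
    axis_atom = central + axis_length * z
    ct = math.cos(math.radians(TETRAHEDRAL_ANGLE))
    st = math.sin(math.radians(TETRAHEDRAL_ANGLE))
    base = []
    for k, L in enumerate(base_lengths):
        phi = math.radians(base_azimuth + 120.0 * k)
        d = ct * z + st * (math.cos(phi) * x + math.sin(phi) * y)
        base.append(central + L * d)
    return axis_atom, base


def _imidazole(donor: np.ndarray, outward: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Five-membered imidazole mimic; the donor nitrogen is vertex NE2."""
    side = 1.37
    radius = side / (2.0 * math.sin(math.pi / 5.0))
    u = _unit(outward)
    w, _ = _perp_frame(u)
    center = donor + radius * u
    names = ["NE2", "CE1", "ND1", "CG", "CD2"]
    elements = ["N", "C", "N", "C", "C"]
    out = []
    for k, (nm, el) in enumerate(zip(names, elements)):
        theta = 2.0 * math.pi * k / 5.0
        pos = center + radius * (-math.cos(theta) * u + math.sin(theta) * w)
        out.append((nm, el, pos))
    return [(nm, el, p) for nm, el, p in out]


def _carboxylate(donor: np.ndarray, outward: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Acetate-like carboxylate mimic; the donor oxygen is OD1."""
    u = _unit(outward)
    w, _ = _perp_frame(u)
    cg = donor + 1.25 * u
    d2 = _unit(math.cos(math.radians(120)) * (-u) + math.sin(math.radians(120)) * w)
    od2 = cg - 1.25 * d2
    cb = cg + 1.52 * _unit(u + 0.8 * (-w))
    return [("OD1", "O", donor), ("CG", "C", cg), ("OD2", "O", od2), ("CB", "C", cb)]


# ---------------------------------------------------------------------------
# ground-truth bookkeeping (computed inline from design coordinates)
# ---------------------------------------------------------------------------

FIRST_SHELL_MAX = 2.5
SECOND_SHELL_MAX = 3.2
HBOND_MIN = 2.2
HBOND_MAX = 3.5
WATER_SHELL = 3.5
BINUCLEAR_MAX_SEP = 4.5


def _design_truth(
    atoms: list[tuple],
    zn_idx: list[int],
    ligand_idx: list[int],
    expected_matches: int,
    rotation_angle: float,
) -> GroundTruth:
    pos = np.array([a[5] for a in atoms], dtype=float)
    elements = [a[1].upper() for a in atoms]
    resnames = [a[2] for a in atoms]

    if len(zn_idx) >= 2:
        seps = [
            np.linalg.norm(pos[i] - pos[j])
            for ii, i in enumerate(zn_idx)
            for j in zn_idx[ii + 1 :]
        ]
        nuclearity = "bi" if any(s <= BINUCLEAR_MAX_SEP for s in seps) else "mono"
    elif len(zn_idx) == 1:
        nuclearity = "mono"
    else:
        nuclearity = "none"

    shells: dict[int, str] = {}
    for i, el in enumerate(elements):
        if i in zn_idx or el not in ("N", "O"):
            continue
        if zn_idx:
            dmin = min(np.linalg.norm(pos[i] - pos[z]) for z in zn_idx)
            shells[i] = (
                "first" if dmin <= FIRST_SHELL_MAX
                else "second" if dmin <= SECOND_SHELL_MAX
                else "none"
            )

    hbonds: list[tuple[int, int]] = []
    lig = set(ligand_idx)
    for i in ligand_idx:
        if elements[i] not in ("N", "O"):
            continue
        for j, el in enumerate(elements):
            if j in lig or j in zn_idx or el not in ("N", "O"):
                continue
            d = np.linalg.norm(pos[i] - pos[j])
            if HBOND_MIN <= d <= HBOND_MAX:
                hbonds.append((i, j))

    water_count = None
    if ligand_idx:
        lig_pos = pos[ligand_idx]
        count = 0
        for j, rn in enumerate(resnames):
            if rn == "HOH" and elements[j] == "O":
                if np.min(np.linalg.norm(lig_pos - pos[j], axis=1)) <= WATER_SHELL:
                    count += 1
        water_count = count

    return GroundTruth(
        expected_matches=expected_matches,
        nuclearity=nuclearity,
        shell_assignments=shells,
        hbond_pairs=sorted(hbonds),
        rotation_angle=rotation_angle,
        water_count=water_count,
        zn_indices=list(zn_idx),
        ligand_indices=list(ligand_idx),
    )


# ---------------------------------------------------------------------------
# site construction
# ---------------------------------------------------------------------------


def _build_atoms(spec: SiteSpec, n_zn: int = 2, axis_is_carbon: bool = False):
    """Assemble the design-coordinate atom list; returns (atoms, zn_idx, ligand_idx)."""
    d = spec.zn_zn_distance
    zn1 = np.array([0.0, 0.0, 0.0])
    zn2 = np.array([d, 0.0, 0.0])
    mid = 0.5 * (zn1 + zn2)

    atoms: list[tuple] = []  # (name, element, resname, seq, chain, pos, hetero)

    def add(name, element, resname, seq, chain, pos, hetero):
        atoms.append((name, element, resname, seq, chain, np.asarray(pos, float), hetero))
        return len(atoms) - 1

    zn_idx = [add("ZN", "Zn", "ZN", 1, "M", zn1, True)]
    if n_zn >= 2:
        zn_idx.append(add("ZN", "Zn", "ZN", 2, "M", zn2, True))

    # --- ligand headgroup -------------------------------------------------
    ligand_idx: list[int] = []
    expected = 0
    bridge = None
    if spec.ligand_headgroup != "none":
        n1d, n2d = spec.n_to_zn_distances
        # bridging atom in the z=0 plane, +y side of the Zn-Zn axis
        bx = (d * d + n1d * n1d - n2d * n2d) / (2.0 * d)
        byy = n1d * n1d - bx * bx
        if byy <= 0:
            raise GenerationError(
                f"bridging distances {spec.n_to_zn_distances} infeasible at Zn-Zn {d}"
            )
        bridge = np.array([bx, math.sqrt(byy), 0.0])
        u_out = _unit(bridge - mid)
        if spec.ligand_headgroup == "phosphinate":
            central_el, bridge_el, L_central = "P", "O", BOND_P_O
            base_lengths = (BOND_P_O, BOND_P_O, BOND_P_O)
            axis_el, axis_len = "C", BOND_P_C
            names = {"central": "P1", "bridge": "O3", "b1": "O1", "b2": "O2", "axis": "C1"}
        else:
            central_el, bridge_el, L_central = "S", "N", BOND_S_N
            base_lengths = (BOND_S_O, BOND_S_O, BOND_S_N)
            axis_el, axis_len = "C" if axis_is_carbon else "N", BOND_S_N
            names = {"central": "S1", "bridge": "N1", "b1": "O1", "b2": "O2", "axis": "C9" if axis_is_carbon else "N2"}
            expected = 0 if axis_is_carbon else 1
        central = bridge + L_central * u_out
        # axis direction: at the tetrahedral angle from the central->bridge vector
        e2 = np.array([0.0, 0.0, 1.0])
        v_axis = _unit(math.cos(math.radians(TETRAHEDRAL_ANGLE)) * (-u_out)
                       + math.sin(math.radians(TETRAHEDRAL_ANGLE)) * e2)
        # base azimuth such that base slot 2 coincides with the bridge direction
        z = v_axis
        x, y = _perp_frame(z)
        bdir = _unit(bridge - central)
        phi_bridge = math.degrees(math.atan2(float(bdir @ y), float(bdir @ x)))
        base_azimuth = phi_bridge - 240.0  # slot k=2 is the bridge
        axis_atom, base = tetrahedral_headgroup(
            central, v_axis, base_azimuth,
            (base_lengths[0], base_lengths[1], L_central), axis_len,
        )
        # base slot 2 must reproduce the analytically placed bridge atom
        if np.linalg.norm(base[2] - bridge) > 1e-6:
            raise GenerationError("internal headgroup construction inconsistency")
        base[2] = bridge

        # optional rigid rotation of the triangular base about central->axis
        if spec.headgroup_rotation:
            rot = _rot_about(axis_atom - central, spec.headgroup_rotation)
            base = [central + rot.apply(b - central) for b in base]

        scaffold_c = axis_atom + BOND_N_C * _unit(axis_atom - central + 0.4 * e2)
        ligand_idx.append(add(names["central"], central_el, "LIG", 1, "L", central, True))
        ligand_idx.append(add(names["b1"], "O", "LIG", 1, "L", base[0], True))
        ligand_idx.append(add(names["b2"], "O", "LIG", 1, "L", base[1], True))
        ligand_idx.append(add(names["bridge"], bridge_el, "LIG", 1, "L", base[2], True))
        ligand_idx.append(add(names["axis"], axis_el, "LIG", 1, "L", axis_atom, True))
        ligand_idx.append(add("C8", "C", "LIG", 1, "L", scaffold_c, True))
        if spec.ligand_headgroup == "sulfamide_bis":
            # substituent carbon on the bridging nitrogen as well
            c_on_bridge = base[2] + BOND_N_C * _unit(base[2] - central + np.array([0, 0.2, -0.9]))
            ligand_idx.append(add("C7", "C", "LIG", 1, "L", c_on_bridge, True))

    # --- coordinating residue mimics --------------------------------------
    donor_plan = [
        (zn1, _unit(np.array([-0.75, -0.45, 0.45])), "HIS", _imidazole),
        (zn2 if n_zn >= 2 else zn1, _unit(np.array([0.75, -0.45, 0.45])), "HIS", _imidazole),
        (zn1, _unit(np.array([-0.35, -0.35, -0.85])), "ASP", _carboxylate),
        (zn2 if n_zn >= 2 else zn1, _unit(np.array([0.35, -0.35, -0.85])), "GLU", _carboxylate),
    ]
    seq = 100
    for k in range(min(spec.n_coordinating_residues, len(donor_plan))):
        zn, direction, resname, builder = donor_plan[k]
        if n_zn < 2 and k in (1, 3):
            continue  # mononuclear variant drops the second zinc's donors
        donor = zn + DATIVE_DISTANCE * direction
        seq += 1
        for nm, el, p in builder(donor, direction):
            nm2 = nm
            if resname == "GLU":
                nm2 = nm.replace("D", "E")
            add(nm2, el, resname, seq, "A", p, False)

    # --- waters ------------------------------------------------------------
    anchor = None
    for i in ligand_idx:
        if atoms[i][1] == "O":
            anchor = atoms[i][5]
            break
    if anchor is None:
        anchor = mid + np.array([0.0, 3.0, 0.0])
    wdirs = [
        _unit(np.array([0.2, 0.9, 0.6])),
        _unit(np.array([-0.5, 0.7, -0.6])),
        _unit(np.array([0.8, 0.5, -0.4])),
        _unit(np.array([-0.2, 1.0, 0.3])),
    ]
    wseq = 200
    for k in range(spec.n_waters):
        wseq += 1
        p = anchor + 2.8 * wdirs[k % len(wdirs)] + np.array([0.0, 0.0, 0.9]) * (k // len(wdirs))
        add("O", "O", "HOH", wseq, "W", p, True)
    for k in range(2):  # distant bulk waters, always outside the shell
        wseq += 1
        add("O", "O", "HOH", wseq, "W", mid + np.array([0.0, 8.0 + 2.0 * k, 0.0]), True)

    return atoms, zn_idx, ligand_idx, expected


def _clash_check(atoms: list[tuple]) -> None:
    pos = np.array([a[5] for a in atoms])
    n = len(pos)
    for i in range(n):
        d = np.linalg.norm(pos[i + 1 :] - pos[i], axis=1)
        if np.any(d < 1.0):
            j = int(np.argmin(d)) + i + 1
            raise GenerationError(
                f"designed clash {atoms[i][0]}/{atoms[j][0]} at {d.min():.2f} angstrom"
            )


def build_site(spec: SiteSpec) -> tuple[Structure, GroundTruth]:
    """Build one synthetic site; ground truth reflects the noise-free design."""
    spec.validate()
    atoms, zn_idx, ligand_idx, expected = _build_atoms(spec)
    _clash_check(atoms)
    truth = _design_truth(atoms, zn_idx, ligand_idx, expected, spec.headgroup_rotation)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sigma, size=(len(atoms), 3))
        atoms = [
            (a[0], a[1], a[2], a[3], a[4], a[5] + noise[i], a[6])
            for i, a in enumerate(atoms)
        ]
    structure = structure_from_atoms(atoms, f"synthetic_{spec.ligand_headgroup}")
    return structure, truth


DECOY_KINDS = ("mononuclear", "sulfonamide_not_sulfamide", "no_metal")


def build_decoy(kind: str, spec: SiteSpec | None = None) -> tuple[Structure, GroundTruth]:
    """Negative controls for the mining stage."""
    if kind not in DECOY_KINDS:
        raise ParameterError(f"unknown decoy kind {kind!r}")
    spec = spec or SiteSpec()
    spec.validate()
    if kind == "mononuclear":
        atoms, zn_idx, ligand_idx, expected = _build_atoms(spec, n_zn=1)
    elif kind == "sulfonamide_not_sulfamide":
        atoms, zn_idx, ligand_idx, _ = _build_atoms(spec, axis_is_carbon=True)
        expected = 0
    else:  # no_metal
        atoms, zn_idx, ligand_idx, expected = _build_atoms(spec)
        keep = [i for i in range(len(atoms)) if i not in zn_idx]
        remap = {old: new for new, old in enumerate(keep)}
        atoms = [atoms[i] for i in keep]
        ligand_idx = [remap[i] for i in ligand_idx]
        zn_idx = []
    _clash_check(atoms)
    truth = _design_truth(atoms, zn_idx, ligand_idx, expected, spec.headgroup_rotation)
    structure = structure_from_atoms(atoms, f"decoy_{kind}")
    return structure, truth


def make_ensemble(structure: Structure, n_frames: int, sigma: float, seed: int = 0):
    """I.i.d. Gaussian-displaced coordinate ensemble (an MD stand-in)."""
    from .superpose import CoordinateEnsemble

    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    base = structure.positions
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, base.shape[0], 3))
    for t in range(n_frames):
        frames[t] = base + (rng.normal(0.0, sigma, size=base.shape) if sigma > 0 else 0.0)
    return CoordinateEnsemble(
        coords=frames, atom_names=[a.name for a in structure.atoms]
    )


def write_fixture(spec: SiteSpec, out_dir: str | Path, stem: str = "site") -> tuple[Path, Path]:
    """Write a fixture as a PDB plus a JSON sidecar with its ground truth."""
    from .structures import write_pdb

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    structure, truth = build_site(spec)
    pdb_path = out / f"{stem}.pdb"
    truth_path = out / f"{stem}.truth.json"
    write_pdb(structure, pdb_path)
    truth.to_json(truth_path)
    return pdb_path, truth_path
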