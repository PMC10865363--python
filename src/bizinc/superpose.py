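"""Rigid superposition of complexes and zinc-binding-group reorientation.

The headgroup rotation statistic operationalizes "the triangular base of the
tetrahedral headgroup is rotated": after a least-squares superposition on a
shared context (active-site backbone atoms or a shared scaffold), both
headgroups are expressed in a local frame whose origin is the central atom
(S or P) and whose z axis points from the central atom to the linking
substituent. The rotation is the circular mean of the three base-atom
azimuth offsets about z, minimized over the three cyclic base pairings, and
is reported as a magnitude in [0, 120) degrees (the tetrahedral base has a
three-fold symmetry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, FrameError, PairingError, ParameterError
from .structures import Structure


@dataclass
class AtomPairing:
    pairs: list[tuple[int, int]]
    descriptor: str = ""

    def __post_init__(self) -> None:
        a_side = [i for i, _ in self.pairs]
        b_side = [j for _, j in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise PairingError("pairing must be injective on both sides")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper orthonormal
    translation: np.ndarray  # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "SuperpositionResult":
        return cls(rotation=np.eye(3), translation=np.zeros(3), rmsd=0.0)


@dataclass
class HeadgroupFrame:
    """Central atom, linking (axis) substituent and the three base substituents."""

    central: int
    axis: int
    base: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(set((self.central, self.axis) + tuple(self.base))) != 5:
            raise FrameError("frame atoms must be five distinct atoms")


@dataclass
class CoordinateEnsemble:
    """Frames of coordinates for a fixed atom list (an MD-trajectory stand-in)."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    atom_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ParameterError("ensemble coords must have shape (n_frames, n_atoms, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# superposition (Kabsch least squares)
# ---------------------------------------------------------------------------


def superpose(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    pairing: AtomPairing | None = None,
) -> SuperpositionResult:
    """Least-squares rigid transform mapping A onto B (proper rotation only)."""
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if pairing is None:
        if coords_a.shape != coords_b.shape:
            raise PairingError("without an explicit pairing, coords must align 1:1")
        a = coords_a
        b = coords_b
    else:
        a = coords_a[[i for i, _ in pairing.pairs]]
        b = coords_b[[j for _, j in pairing.pairs]]
    if len(a) < 3:
        raise DegenerateGeometryError("need at least 3 pairs for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2:
        raise DegenerateGeometryError("pairing is collinear or degenerate")
    rot, _ = Rotation.align_vectors(b0, a0)  # proper rotation by construction
    R = rot.as_matrix()
    t = cb - R @ ca
    resid = a @ R.T + t - b
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def backbone_pairing(
    a: Structure,
    b: Structure,
    within: float = 8.0,
    atom_names: tuple[str, ...] = ("N", "CA", "C"),
    metal_element: str = "Zn",
) -> AtomPairing:
    """Pair backbone atoms of residues within ``within`` of any zinc, by identity.

    Atoms are matched across structures by (chain, residue_seq, atom name);
    this is the superposition context used for active-site comparisons.
    """

    def context(st: Structure) -> dict[tuple[str, int, str], int]:
        metals = st.metal_indices(metal_element)
        mp = st.positions[metals] if metals else np.zeros((0, 3))
        out = {}
        for i, atom in enumerate(st.atoms):
            if atom.is_hetero or atom.name not in atom_names:
                continue
            if len(mp) and np.min(np.linalg.norm(mp - atom.position, axis=1)) <= within:
                out[(atom.chain, atom.residue_seq, atom.name)] = i
        return out

    ca, cb = context(a), context(b)
    keys = sorted(set(ca) & set(cb))
    if len(keys) < 3:
        raise PairingError("fewer than 3 shared backbone atoms near the metals")
    return AtomPairing(
        pairs=[(ca[k], cb[k]) for k in keys],
        descriptor=f"backbone {'/'.join(atom_names)} within {within} A of {metal_element}",
    )


# ---------------------------------------------------------------------------
# headgroup rotation
# ---------------------------------------------------------------------------


def frame_from_component(
    structure: Structure,
    component_key,
    central_name: str,
    axis_name: str,
) -> HeadgroupFrame:
    """Build a headgroup frame from atom names inside one ligand component."""
    idx = structure.components.get(component_key)
    if not idx:
        raise FrameError(f"no component {component_key} in {structure.id}")
    names = {structure.atoms[i].name: i for i in idx}
    if central_name not in names or axis_name not in names:
        raise FrameError(f"frame atoms {central_name}/{axis_name} missing from {component_key}")
    central = names[central_name]
    cpos = structure.atoms[central].position
    # base = the three heavy atoms bonded to the central atom other than the axis
    neighbors = []
    for i in idx:
        if i in (central, names[axis_name]):
            continue
        d = float(np.linalg.norm(structure.atoms[i].position - cpos))
        if d <= 2.0:
            neighbors.append((d, i))
    neighbors.sort()
    if len(neighbors) != 3:
        raise FrameError(
            f"central atom {central_name} has {len(neighbors)} base substituents, need 3"
        )
    return HeadgroupFrame(central=central, axis=names[axis_name], base=tuple(i for _, i in neighbors))


def _wrap_deg(x: float) -> float:
    return (x + 180.0) % 360.0 - 180.0


def _circular_mean_deg(angles: list[float]) -> float:
    s = sum(math.sin(math.radians(a)) for a in angles)
    c = sum(math.cos(math.radians(a)) for a in angles)
    return math.degrees(math.atan2(s, c))


def headgroup_rotation(
    structure_a: Structure,
    frame_a: HeadgroupFrame,
    structure_b: Structure,
    frame_b: HeadgroupFrame,
    superposition: SuperpositionResult | None = None,
    return_details: bool = False,
):
    """Rotation (degrees, magnitude in [0, 120)) of headgroup B relative to A.

    Because the pairing minimizes the mean azimuth offset over the three
    cyclic base pairings, the statistic is defined modulo the three-fold
    symmetry of the tetrahedral base: a physical rotation t is measured as
    min(t mod 120, 120 - t mod 120), so reported values lie in [0, 60].
    ``superposition`` is the context fit mapping A onto B's coordinate frame
    (identity if omitted).
    """
    sup = superposition or SuperpositionResult.identity()
    pa = sup.apply(structure_a.positions)
    pb = structure_b.positions

    def local(frame: HeadgroupFrame, pos: np.ndarray):
        c = pos[frame.central]
        z = pos[frame.axis] - c
        nz = np.linalg.norm(z)
        if nz < 1e-9:
            raise FrameError("central and axis atoms coincide")
        return c, z / nz, [pos[i] - c for i in frame.base]

    ca, za, base_a = local(frame_a, pa)
    cb, zb, base_b = local(frame_b, pb)
    z = za + zb
    if np.linalg.norm(z) < 1e-6:  # anti-parallel axes: fall back to B's axis
        z = zb
    z = z / np.linalg.norm(z)
    probe = np.array([0.0, 0.0, 1.0]) if abs(z[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    x = np.cross(probe, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)

    def azimuths(vectors):
        az = []
        for v in vectors:
            az.append(math.degrees(math.atan2(float(v @ y), float(v @ x))))
        return az

    az_a = azimuths(base_a)
    az_b = azimuths(base_b)
    order_a = sorted(range(3), key=lambda k: az_a[k])
    order_b = sorted(range(3), key=lambda k: az_b[k])

    best = None
    for shift in range(3):
        offsets = [
            _wrap_deg(az_b[order_b[(k + shift) % 3]] - az_a[order_a[k]]) for k in range(3)
        ]
        mean = _circular_mean_deg(offsets)
        cand = (abs(mean), mean, shift, offsets)
        if best is None or cand[0] < best[0]:
            best = cand
    angle = abs(best[1]) % 120.0
    if return_details:
        return angle, {"pairing_shift": best[2], "offsets": best[3], "mean": best[1]}
    return angle


# ---------------------------------------------------------------------------
# zinc displacement and RMSF
# ---------------------------------------------------------------------------


def zinc_displacement(
    structure_a: Structure,
    report_a,
    structure_b: Structure,
    report_b,
    superposition: SuperpositionResult,
):
    """Per-metal displacement after superposition, plus inter-metal change.

    Metals are matched by the site-fingerprint labels of their reports.
    Returns a pandas DataFrame.
    """
    import pandas as pd

    by_label_a = {lab: m for m, lab in report_a.metal_labels.items()}
    by_label_b = {lab: m for m, lab in report_b.metal_labels.items()}
    shared = sorted(set(by_label_a) & set(by_label_b))
    if not shared:
        raise PairingError("no metals with matching labels between the two reports")
    pa = superposition.apply(structure_a.positions)
    pb = structure_b.positions
    rows = []
    for lab in shared:
        i, j = by_label_a[lab], by_label_b[lab]
        rows.append(
            {
                "label": lab,
                "displacement": float(np.linalg.norm(pa[i] - pb[j])),
            }
        )
    da = list(report_a.inter_metal_distances.values())
    db = list(report_b.inter_metal_distances.values())
    if da and db:
        rows.append(
            {"label": "inter_metal_delta", "displacement": abs(float(db[0]) - float(da[0]))}
        )
    return pd.DataFrame(rows, columns=["label", "displacement"])


def rmsf(
    ensemble: CoordinateEnsemble,
    selection: list[int] | None = None,
    superpose_frames: bool = True,
    max_iter: int = 5,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the ensemble mean position.

    With ``superpose_frames`` each frame is first least-squares fitted onto
    the running mean structure over the selected atoms (drift removal, as in
    trajectory analysis).
    """
    if selection is None:
        selection = list(range(ensemble.n_atoms))
    if not selection:
        raise ParameterError("empty selection")
    frames = ensemble.coords[:, selection, :].copy()
    if ensemble.n_frames < 2:
        return np.zeros(len(selection))
    if superpose_frames:
        mean = frames[0]
        for _ in range(max_iter):
            aligned = np.empty_like(frames)
            for t in range(frames.shape[0]):
                sup = superpose(frames[t], mean)
                aligned[t] = sup.apply(frames[t])
            new_mean = aligned.mean(axis=0)
            if np.max(np.abs(new_mean - mean)) < 1e-10:
                frames = aligned
                mean = new_mean
                break
            frames = aligned
            mean = new_mean
    mean = frames.mean(axis=0)
    dev = frames - mean
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
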