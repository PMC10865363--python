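"""Active-site cluster model extraction and energy bookkeeping.

A cluster model is assembled from a structure by a :class:`ClusterRecipe`:
whole residues copied verbatim, truncated residues cut at a named bond and
capped with a methyl carbon placed 1.53 angstrom along the cut-bond vector
(deposited models carry no hydrogens, so caps are single carbons and all
inventories are heavy-atom inventories; hydrogen addition is a
post-processing concern), plus the ligand, the metals and a hydrogen-bonded
water network selected by distance.

Electronic energies are never computed here: they enter as user-supplied
numbers with explicit units, and the module only performs the interaction
energy arithmetic E(AB) - E(A) - E(B) and relative-energy ranking of
conformers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import RecipeError, TableError, UnitError
from .structures import ComponentKey, Structure, write_pdb, write_xyz, structure_from_atoms

CAP_BOND_LENGTH = 1.53  # sp3 C-C, angstrom

ENERGY_UNITS = ("kcal/mol", "kj/mol", "hartree")


@dataclass(frozen=True)
class CappedFragment:
    """A residue truncated at ``cut`` = (kept atom name, removed atom name)."""

    residue: tuple[str, int]  # (chain, seq)
    keep_atoms: tuple[str, ...]
    cut: tuple[str, str]


@dataclass
class ClusterRecipe:
    full_residues: list[tuple[str, int]] = field(default_factory=list)
    capped_residues: list[CappedFragment] = field(default_factory=list)
    include_ligand: bool = True
    include_metals: bool = True
    water_within: float | None = 3.5  # None -> explicit list
    explicit_waters: list[tuple[str, int]] = field(default_factory=list)
    protonation_notes: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        full = set(self.full_residues)
        capped = {c.residue for c in self.capped_residues}
        overlap = full & capped
        if overlap:
            raise RecipeError(f"residues both full and capped: {sorted(overlap)}")


@dataclass
class ClusterAtom:
    element: str
    position: np.ndarray
    tag: str  # residue | cap | water | ligand | metal
    label: str  # e.g. "HIS377:NE2" or "cap(HIS377 CB-CA)"


@dataclass
class QMCluster:
    atoms: list[ClusterAtom]
    protonation_notes: dict[str, str] = field(default_factory=dict)
    net_formal_charge: int | None = None

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.element.upper() != "H")

    @property
    def total_atom_count(self) -> int:
        return len(self.atoms)

    def inventory(self) -> dict[str, int]:
        """Atom counts by provenance tag, for manual reconciliation."""
        out: dict[str, int] = {}
        for a in self.atoms:
            out[a.tag] = out.get(a.tag, 0) + 1
        return out


def _residue_atoms(structure: Structure, chain: str, seq: int) -> list[int]:
    hits = []
    for key, idx in structure.components.items():
        if key[0] == chain and key[1] == seq:
            hits.extend(idx)
    return hits


def build_cluster(structure: Structure, recipe: ClusterRecipe) -> QMCluster:
    """Extract the cluster model; deterministic atom ordering, provenance tags."""
    recipe.validate()
    atoms: list[ClusterAtom] = []

    def res_label(i: int) -> str:
        a = structure.atoms[i]
        return f"{a.residue_name}{a.residue_seq}:{a.name}"

    for chain, seq in recipe.full_residues:
        idx = _residue_atoms(structure, chain, seq)
        if not idx:
            raise RecipeError(f"full residue {chain}:{seq} not found in {structure.id}")
        for i in sorted(idx):
            a = structure.atoms[i]
            atoms.append(ClusterAtom(a.element, a.position.copy(), "residue", res_label(i)))

    for frag in recipe.capped_residues:
        chain, seq = frag.residue
        idx = _residue_atoms(structure, chain, seq)
        if not idx:
            raise RecipeError(f"capped residue {chain}:{seq} not found in {structure.id}")
        by_name = {structure.atoms[i].name: i for i in idx}
        kept_name, removed_name = frag.cut
        if kept_name not in by_name or removed_name not in by_name:
            raise RecipeError(
                f"cut bond {kept_name}-{removed_name} not present in {chain}:{seq}"
            )
        for name in frag.keep_atoms:
            if name not in by_name:
                raise RecipeError(f"kept atom {name} missing from {chain}:{seq}")
            i = by_name[name]
            a = structure.atoms[i]
            atoms.append(ClusterAtom(a.element, a.position.copy(), "residue", res_label(i)))
        kept = structure.atoms[by_name[kept_name]].position
        removed = structure.atoms[by_name[removed_name]].position
        vec = removed - kept
        norm = np.linalg.norm(vec)
        if norm < 1e-9:
            raise RecipeError(f"degenerate cut bond in {chain}:{seq}")
        cap = kept + CAP_BOND_LENGTH * vec / norm
        resname = structure.atoms[idx[0]].residue_name
        atoms.append(
            ClusterAtom("C", cap, "cap", f"cap({resname}{seq} {kept_name}-{removed_name})")
        )

    if recipe.include_ligand:
        for key, idx in structure.ligand_components().items():
            for i in sorted(idx):
                a = structure.atoms[i]
                atoms.append(ClusterAtom(a.element, a.position.copy(), "ligand", res_label(i)))

    if recipe.include_metals:
        for i in structure.metal_indices():
            a = structure.atoms[i]
            atoms.append(ClusterAtom(a.element, a.position.copy(), "metal", res_label(i)))

    # water network: one pass of O-within-distance of current cluster heavy atoms
    water_keys: list[ComponentKey] = []
    if recipe.water_within is not None and atoms:
        cluster_pos = np.array([a.position for a in atoms])
        for key, idx in structure.components.items():
            if structure.atoms[idx[0]].residue_name not in ("HOH", "WAT", "DOD", "H2O"):
                continue
            opos = [structure.atoms[i].position for i in idx if structure.atoms[i].element == "O"]
            if any(
                np.min(np.linalg.norm(cluster_pos - p, axis=1)) <= recipe.water_within
                for p in opos
            ):
                water_keys.append(key)
    for chain, seq in recipe.explicit_waters:
        for key in structure.components:
            if key[0] == chain and key[1] == seq:
                water_keys.append(key)
    for key in sorted(set(water_keys)):
        for i in sorted(structure.components[key]):
            a = structure.atoms[i]
            atoms.append(ClusterAtom(a.element, a.position.copy(), "water", res_label(i)))

    return QMCluster(atoms=atoms, protonation_notes=dict(recipe.protonation_notes))


def count_atoms(cluster: QMCluster, heavy_only: bool = False) -> int:
    return cluster.heavy_atom_count if heavy_only else cluster.total_atom_count


# ---------------------------------------------------------------------------
# energies (user-supplied numbers; never computed here)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Energy:
    value: float
    unit: str = "kcal/mol"

    def __post_init__(self) -> None:
        if self.unit not in ENERGY_UNITS:
            raise UnitError(f"unknown energy unit {self.unit!r}; expected one of {ENERGY_UNITS}")


def interaction_energy(e_complex: Energy, e_part_a: Energy, e_part_b: Energy) -> Energy:
    """E_int = E(AB) - E(A) - E(B)."""
    units = {e_complex.unit, e_part_a.unit, e_part_b.unit}
    if len(units) != 1:
        raise UnitError(f"mixed energy units {sorted(units)}")
    return Energy(e_complex.value - e_part_a.value - e_part_b.value, e_complex.unit)


@dataclass
class EnergyRow:
    label: str
    total: float
    unit: str = "kcal/mol"
    tags: dict[str, str] = field(default_factory=dict)


@dataclass
class EnergyTable:
    rows: list[EnergyRow]

    def __post_init__(self) -> None:
        if self.rows and len({r.unit for r in self.rows}) != 1:
            raise UnitError("all energy-table rows must share one unit")


def rank_conformers(table: EnergyTable) -> list[tuple[str, float]]:
    """Relative energies (total minus minimum), ascending; ties keep input order."""
    if not table.rows:
        raise TableError("energy table is empty")
    emin = min(r.total for r in table.rows)
    ranked = sorted(
        ((r.label, r.total - emin) for r in table.rows),
        key=lambda t: t[1],
    )
    return [(label, rel) for label, rel in ranked]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_cluster(cluster: QMCluster, path, format: str = "xyz") -> None:
    """Write the cluster as XYZ or PDB (provenance tags in residue names)."""
    if not cluster.atoms:
        raise RecipeError("cannot write an empty cluster")
    if format == "xyz":
        write_xyz(
            [(a.element, a.position) for a in cluster.atoms],
            path,
            comment="cluster model: " + " ".join(
                f"{k}={v}" for k, v in sorted(cluster.inventory().items())
            ),
        )
    elif format == "pdb":
        tag_res = {"residue": "RES", "cap": "CAP", "water": "HOH", "ligand": "LIG", "metal": "MET"}
        tuples = []
        for k, a in enumerate(cluster.atoms):
            name = a.label.split(":")[-1][:4] if ":" in a.label else a.element
            tuples.append((name, a.element, tag_res[a.tag], k + 1, "X", a.position, True))
        write_pdb(structure_from_atoms(tuples, "cluster"), path)
    else:
        raise UnitError(f"unknown cluster format {format!r}")


#: Residue recipes of the deposited complexes, as published: whole residues and
#: methyl-capped fragments for the monosubstituted complex and for the two
#: bisubstituted complexes. Residue numbers refer to the deposited entries;
#: usable when a user supplies those coordinate files locally.
PSMA_MONO_RECIPE = {
    "full_residues": [257, 424, 425, 426, 428, 519, 699, 700],
    "capped_residues": [209, 210, 258, 377, 381, 387, 427, 451, 453, 518, 534, 552, 553],
    "protonation_notes": {"HIS377": "HID", "HIS553": "HID"},
}

PSMA_BIS_RECIPE = {
    "full_residues": [256, 424, 425, 456, 457, 699, 700],
    "capped_residues": [209, 210, 258, 377, 381, 387, 428, 451, 453, 463, 518, 519, 534, 536, 552, 553, 559],
    "protonation_notes": {"HIS377": "HID", "HIS553": "HID"},
}
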