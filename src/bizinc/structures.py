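"""Macromolecular structure I/O and covalent-bond perception.

Structures are read with :mod:`gemmi` (PDB and mmCIF), flattened into a plain
list of :class:`AtomRecord` with a deterministic alternate-location policy
(highest occupancy wins, ties broken by alt-loc letter), first model only.
Covalent bonds inside a single chemical component are perceived from
interatomic distances against covalent-radii sums; metals never receive
covalent bonds — their contacts are treated as coordination and handled by
:mod:`bizinc.geometry`.

The module also provides the plain-text writers used across the package:
fixed-column PDB, XYZ, and Gaussian cube (values in atomic units, coordinates
in Bohr).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import networkx as nx
import numpy as np

from .errors import (
    EmptyComponentError,
    FormatError,
    ParseError,
    SelectionError,
    SerializationError,
)

#: 1 angstrom in Bohr (CODATA).
ANGSTROM_TO_BOHR = 1.8897259886

#: Residue names treated as water.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: Distance tolerance added to covalent-radii sums when perceiving bonds (angstrom).
DEFAULT_COVALENT_TOLERANCE = 0.45

# Component key: (chain, residue_seq, insertion_code, residue_name)
ComponentKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a crystallographic model (alt-locs already resolved)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    icode: str
    chain: str
    position: np.ndarray  # shape (3,), angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False
    alt_loc: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ParseError(f"atom {self.serial} {self.name}: non-finite position")
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ParseError(
                f"atom {self.serial} {self.name}: occupancy {self.occupancy} outside [0,1]"
            )
        if gemmi.Element(self.element).atomic_number == 0 and self.element != "X":
            raise ParseError(f"atom {self.serial} {self.name}: unknown element {self.element!r}")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES

    @property
    def is_metal(self) -> bool:
        return bool(gemmi.Element(self.element).is_metal)

    @property
    def component_key(self) -> ComponentKey:
        return (self.chain, self.residue_seq, self.icode, self.residue_name)


@dataclass
class Structure:
    """A parsed macromolecular model: ordered atoms plus component bookkeeping."""

    id: str
    atoms: list[AtomRecord]
    resolution: float | None = None
    _components: dict[ComponentKey, list[int]] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self._components = None

    # -- derived views ----------------------------------------------------

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def components(self) -> dict[ComponentKey, list[int]]:
        """Mapping residue key -> atom indices, in file order."""
        if self._components is None:
            comp: dict[ComponentKey, list[int]] = {}
            for i, a in enumerate(self.atoms):
                comp.setdefault(a.component_key, []).append(i)
            self._components = comp
        return self._components

    def metal_indices(self, element: str | None = None) -> list[int]:
        out = []
        for i, a in enumerate(self.atoms):
            if element is not None:
                if a.element.upper() == element.upper():
                    out.append(i)
            elif a.is_metal:
                out.append(i)
        return out

    def ligand_components(self) -> dict[ComponentKey, list[int]]:
        """Hetero components that are neither waters nor lone metals."""
        out = {}
        for key, idx in self.components.items():
            atoms = [self.atoms[i] for i in idx]
            if not atoms[0].is_hetero or atoms[0].is_water:
                continue
            if all(a.is_metal for a in atoms):
                continue
            out[key] = idx
        return out

    def element_set(self) -> set[str]:
        return {a.element.upper() for a in self.atoms}

    def select_one(
        self,
        name: str | None = None,
        resname: str | None = None,
        seq: int | None = None,
        chain: str | None = None,
    ) -> int:
        """Index of the unique atom matching all given fields; error otherwise."""
        hits = [
            i
            for i, a in enumerate(self.atoms)
            if (name is None or a.name == name)
            and (resname is None or a.residue_name == resname)
            and (seq is None or a.residue_seq == seq)
            and (chain is None or a.chain == chain)
        ]
        if len(hits) != 1:
            raise SelectionError(
                f"selection name={name} resname={resname} seq={seq} chain={chain} "
                f"matched {len(hits)} atoms in {self.id}"
            )
        return hits[0]


@dataclass
class MoleculeGraph:
    """Element-labeled connectivity graph of one chemical component.

    Nodes are atom indices of the parent :class:`Structure`; each node carries
    its element symbol and (when known) formal charge. Edges carry a bond-order
    tag, ``"unknown"`` unless supplied by a component dictionary.
    """

    graph: nx.Graph
    source: ComponentKey

    @property
    def n_atoms(self) -> int:
        return self.graph.number_of_nodes()

    def elements(self) -> dict[int, str]:
        return dict(self.graph.nodes(data="element"))

    def degree(self, node: int) -> int:
        return self.graph.degree[node]


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_FORMAT_MAP = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    First model only; waters and metals are flagged on the atom records; for
    alternate locations the highest-occupancy conformer is kept (ties broken
    by alt-loc letter order).
    """
    path = Path(path)
    if format not in _FORMAT_MAP:
        raise FormatError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMAT_MAP[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: file contains no coordinate model")
    model = st[0]

    atoms: list[AtomRecord] = []
    serial_seen: set[int] = set()
    for chain in model:
        for residue in chain:
            # group alt-locs per atom name, keep best conformer
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            for name, alts in by_name.items():
                best = min(alts, key=lambda a: (-a.occ, a.altloc or "~"))
                serial = best.serial
                if serial in serial_seen:
                    serial = (max(serial_seen) + 1) if serial_seen else 1
                serial_seen.add(serial)
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element=best.element.name,
                        residue_name=residue.name,
                        residue_seq=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        chain=chain.name,
                        position=np.array([best.pos.x, best.pos.y, best.pos.z]),
                        occupancy=min(max(best.occ, 0.0), 1.0),
                        b_factor=best.b_iso,
                        is_hetero=(residue.het_flag == "H"),
                        alt_loc=(best.altloc or "").strip("\x00"),
                    )
                )
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return Structure(id=st.name or path.stem, atoms=atoms, resolution=resolution)


# ---------------------------------------------------------------------------
# Bond perception
# ---------------------------------------------------------------------------


def covalent_radius(element: str) -> float:
    return float(gemmi.Element(element).covalent_r)


def perceive_bonds(
    structure: Structure,
    component_key: ComponentKey,
    tolerance: float = DEFAULT_COVALENT_TOLERANCE,
) -> MoleculeGraph:
    """Perceive covalent bonds for one component by covalent-radii distance.

    Two atoms are bonded iff their distance is at most the sum of covalent
    radii plus ``tolerance``. Metals never receive covalent bonds. Bond
    orders are tagged ``"unknown"``.
    """
    if component_key not in structure.components:
        raise EmptyComponentError(f"{structure.id}: no component {component_key}")
    idx = structure.components[component_key]
    if not idx:
        raise EmptyComponentError(f"{structure.id}: component {component_key} is empty")
    g = nx.Graph()
    for i in idx:
        a = structure.atoms[i]
        g.add_node(i, element=a.element.upper(), formal_charge=None, name=a.name)
    for ii, i in enumerate(idx):
        a = structure.atoms[i]
        if a.is_metal:
            continue
        for j in idx[ii + 1 :]:
            b = structure.atoms[j]
            if b.is_metal:
                continue
            cut = covalent_radius(a.element) + covalent_radius(b.element) + tolerance
            if np.linalg.norm(a.position - b.position) <= cut:
                g.add_edge(i, j, order="unknown")
    return MoleculeGraph(graph=g, source=component_key)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _pdb_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-column PDB (v3.3) records; re-readable by :func:`read_structure`."""
    lines = []
    for a in structure.atoms:
        rec = "HETATM" if a.is_hetero else "ATOM  "
        x, y, z = a.position
        lines.append(
            f"{rec}{a.serial:5d} {_pdb_atom_name(a.name, a.element)}{(a.alt_loc or ' ')[:1]}"
            f"{a.residue_name:>3s} {a.chain[:1]}{a.residue_seq:4d}{(a.icode or ' ')[:1]}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
            f"          {a.element.upper():>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(
    atoms: Sequence[tuple[str, Sequence[float]]],
    path: str | Path,
    comment: str = "",
) -> None:
    """Write an XYZ file: count line, comment, then `element x y z` in angstrom."""
    lines = [str(len(atoms)), comment.replace("\n", " ")]
    for element, pos in atoms:
        x, y, z = pos
        lines.append(f"{element:<3s} {x:14.6f} {y:14.6f} {z:14.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> list[tuple[str, np.ndarray]]:
    text = Path(path).read_text().splitlines()
    try:
        n = int(text[0].strip())
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: malformed XYZ header") from exc
    out = []
    for line in text[2 : 2 + n]:
        parts = line.split()
        out.append((parts[0], np.array([float(p) for p in parts[1:4]])))
    if len(out) != n:
        raise ParseError(f"{path}: XYZ declares {n} atoms, found {len(out)}")
    return out


def write_cube(
    path: str | Path,
    origin: Sequence[float],
    spacing: Sequence[float] | float,
    values: np.ndarray,
    atoms: Iterable[tuple[str, Sequence[float]]] = (),
    comment: str = "bizinc scalar field",
) -> None:
    """Write a Gaussian cube file.

    ``origin``/``spacing`` and atom coordinates are given in angstrom and
    converted to Bohr in the header; ``values`` is a (nx, ny, nz) array
    written in the standard z-fastest order.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise SerializationError("cube values must be a 3-D array")
    if not np.all(np.isfinite(values)):
        raise SerializationError("cube values contain non-finite entries")
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise SerializationError("cube spacing must be positive")
    atoms = list(atoms)
    nx_, ny_, nz_ = values.shape
    ob = np.asarray(origin, dtype=float) * ANGSTROM_TO_BOHR
    sb = spacing * ANGSTROM_TO_BOHR
    lines = [comment.replace("\n", " "), "scalar field written by bizinc"]
    lines.append(f"{len(atoms):5d}{ob[0]:12.6f}{ob[1]:12.6f}{ob[2]:12.6f}")
    lines.append(f"{nx_:5d}{sb[0]:12.6f}{0.0:12.6f}{0.0:12.6f}")
    lines.append(f"{ny_:5d}{0.0:12.6f}{sb[1]:12.6f}{0.0:12.6f}")
    lines.append(f"{nz_:5d}{0.0:12.6f}{0.0:12.6f}{sb[2]:12.6f}")
    for element, pos in atoms:
        z = gemmi.Element(element).atomic_number
        p = np.asarray(pos, dtype=float) * ANGSTROM_TO_BOHR
        lines.append(f"{z:5d}{float(z):12.6f}{p[0]:12.6f}{p[1]:12.6f}{p[2]:12.6f}")
    flat = values.reshape(-1)  # C order: z fastest
    for start in range(0, flat.size, 6):
        chunk = flat[start : start + 6]
        lines.append("".join(f"{v:14.6E}" for v in chunk))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a cube file back; returns (origin_ang, spacing_ang, values)."""
    lines = Path(path).read_text().splitlines()
    natoms = int(lines[2].split()[0])
    origin = np.array([float(v) for v in lines[2].split()[1:4]]) / ANGSTROM_TO_BOHR
    shape = []
    spacing = []
    for k in range(3):
        parts = lines[3 + k].split()
        shape.append(int(parts[0]))
        spacing.append(float(parts[1 + k]) / ANGSTROM_TO_BOHR)
    vals = []
    for line in lines[6 + natoms :]:
        vals.extend(float(v) for v in line.split())
    values = np.array(vals, dtype=float).reshape(shape)
    return origin, np.array(spacing), values


def structure_from_atoms(
    atoms: Sequence[tuple[str, str, str, int, str, Sequence[float], bool]],
    structure_id: str,
) -> Structure:
    """Build a :class:`Structure` from simple tuples.

    Each tuple is (atom_name, element, residue_name, residue_seq, chain,
    position, is_hetero). Serial numbers are assigned sequentially.
    """
    records = []
    for i, (name, element, resname, seq, chain, pos, het) in enumerate(atoms, start=1):
        records.append(
            AtomRecord(
                serial=i,
                name=name,
                element=element,
                residue_name=resname,
                residue_seq=seq,
                icode="",
                chain=chain,
                position=np.asarray(pos, dtype=float),
                is_hetero=het,
            )
        )
    return Structure(id=structure_id, atoms=records)
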