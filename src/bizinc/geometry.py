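"""Coordination-sphere geometry of binuclear zinc sites.

All criteria are heavy-atom distances: deposited crystal structures carry no
hydrogens, so dative bonds, coordination shells and hydrogen bonds are
defined on N/O (and metal) positions only. The first coordination shell
(default <= 2.5 angstrom) brackets typical ~2.0 angstrom dative bonds; the
second shell (2.5, 3.2] captures the "> 2.8 angstrom" outer contacts;
hydrogen bonds are N/O--N/O pairs inside a [2.2, 3.5] angstrom window with
donor/acceptor roles reported as candidates only (no angle term is possible
without hydrogens).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ParameterError
from .mining import ZBGMatch
from .structures import Structure


@dataclass
class GeometryParams:
    first_shell_max: float = 2.5
    second_shell_max: float = 3.2
    hbond_max: float = 3.5
    hbond_min: float = 2.2
    water_shell: float = 3.5
    rounding: int = 1

    def __post_init__(self) -> None:
        if not self.first_shell_max < self.second_shell_max:
            raise ParameterError("first_shell_max must be < second_shell_max")
        if not self.hbond_min < self.hbond_max:
            raise ParameterError("hbond_min must be < hbond_max")


@dataclass
class CoordinationShell:
    metal_index: int
    first_shell: list[tuple[int, float]]
    second_shell: list[tuple[int, float]]


@dataclass
class HBond:
    atom_a: int
    atom_b: int
    distance: float
    context_a: str
    context_b: str


@dataclass
class MetalSiteReport:
    structure_id: str
    metals: list[int]
    metal_labels: dict[int, str]
    inter_metal_distances: dict[tuple[int, int], float]
    shells: dict[int, CoordinationShell]
    hbonds: list[HBond]
    water_count: int
    nuclearity: str
    params: GeometryParams = field(default_factory=GeometryParams)


def distance(structure: Structure, i: int, j: int) -> float:
    """Euclidean distance between two atoms, in angstrom (full precision)."""
    return float(np.linalg.norm(structure.atoms[i].position - structure.atoms[j].position))


def interzinc_distance(
    structure: Structure, metal_pair: tuple[int, int], params: GeometryParams | None = None
) -> float:
    """Distance between a metal pair, rounded at the configured precision."""
    params = params or GeometryParams()
    i, j = metal_pair
    if i == j:
        raise ParameterError("metal pair must be two distinct atoms")
    for k in (i, j):
        if not structure.atoms[k].is_metal:
            raise ParameterError(f"atom {k} ({structure.atoms[k].name}) is not a metal")
    return round(distance(structure, i, j), params.rounding)


def assign_shells(
    structure: Structure,
    metal: int,
    candidates: list[int] | None = None,
    params: GeometryParams | None = None,
) -> CoordinationShell:
    """Partition candidate N/O atoms into first/second coordination shells."""
    params = params or GeometryParams()
    if candidates is None:
        candidates = [
            i
            for i, a in enumerate(structure.atoms)
            if i != metal and not a.is_metal and a.element.upper() in ("N", "O")
        ]
    first, second = [], []
    for i in candidates:
        d = distance(structure, metal, i)
        if d <= params.first_shell_max:
            first.append((i, d))
        elif d <= params.second_shell_max:
            second.append((i, d))
    first.sort(key=lambda t: (t[1], t[0]))
    second.sort(key=lambda t: (t[1], t[0]))
    return CoordinationShell(metal_index=metal, first_shell=first, second_shell=second)


def detect_hbonds(
    structure: Structure,
    ligand_selection: list[int],
    params: GeometryParams | None = None,
) -> list[HBond]:
    """All ligand-N/O x environment-N/O pairs within the distance window."""
    params = params or GeometryParams()
    if not ligand_selection:
        raise ParameterError("ligand selection is empty")
    lig = set(ligand_selection)
    out = []
    for i in sorted(lig):
        a = structure.atoms[i]
        if a.element.upper() not in ("N", "O"):
            continue
        for j, b in enumerate(structure.atoms):
            if j in lig or b.is_metal or b.element.upper() not in ("N", "O"):
                continue
            d = distance(structure, i, j)
            if params.hbond_min <= d <= params.hbond_max:
                out.append(
                    HBond(
                        atom_a=i,
                        atom_b=j,
                        distance=d,
                        context_a=f"{a.residue_name}{a.residue_seq}:{a.name}",
                        context_b=f"{b.residue_name}{b.residue_seq}:{b.name}",
                    )
                )
    out.sort(key=lambda h: (h.atom_a, h.distance, h.atom_b))
    return out


def count_waters_within(
    structure: Structure,
    ligand_selection: list[int],
    params: GeometryParams | None = None,
) -> int:
    """Distinct waters (component name) with O within the shell of the ligand."""
    params = params or GeometryParams()
    if not ligand_selection:
        return 0
    lig_pos = structure.positions[ligand_selection]
    waters = set()
    for j, b in enumerate(structure.atoms):
        if not b.is_water or b.element.upper() != "O":
            continue
        dmin = float(np.min(np.linalg.norm(lig_pos - b.position, axis=1)))
        if dmin <= params.water_shell:
            waters.add(b.component_key)
    return len(waters)


def metal_fingerprint(
    structure: Structure, metal: int, params: GeometryParams | None = None
) -> str:
    """Residue-contact fingerprint of a metal: sorted first-shell protein contacts.

    Used to give metals stable labels across related complexes without
    asserting catalytic roles.
    """
    params = params or GeometryParams()
    shell = assign_shells(structure, metal, params=params)
    names = sorted(
        {
            f"{structure.atoms[i].residue_name}{structure.atoms[i].residue_seq}"
            for i, _ in shell.first_shell
            if not structure.atoms[i].is_hetero
        }
    )
    return "+".join(names)


def label_metals(
    structure: Structure, metals: list[int], params: GeometryParams | None = None
) -> dict[int, str]:
    ordered = sorted(metals, key=lambda m: (metal_fingerprint(structure, m, params), m))
    return {m: f"zn{k + 1}" for k, m in enumerate(ordered)}


def site_report(
    structure: Structure,
    match: ZBGMatch,
    params: GeometryParams | None = None,
) -> MetalSiteReport:
    """Assemble the full geometric characterization of one matched site."""
    params = params or GeometryParams()
    metals = [m for m, _ in match.nearby_metals]
    labels = label_metals(structure, metals, params)
    inter = {
        (i, j): distance(structure, i, j) for i, j in combinations(sorted(metals), 2)
    }
    ligand_idx = sorted(structure.components[match.component_key])
    shells = {m: assign_shells(structure, m, params=params) for m in metals}
    hbonds = detect_hbonds(structure, ligand_idx, params)
    waters = count_waters_within(structure, ligand_idx, params)
    return MetalSiteReport(
        structure_id=structure.id,
        metals=sorted(metals),
        metal_labels=labels,
        inter_metal_distances=inter,
        shells=shells,
        hbonds=hbonds,
        water_count=waters,
        nuclearity=match.nuclearity,
        params=params,
    )


def report_table(structure: Structure, report: MetalSiteReport) -> pd.DataFrame:
    """One row per measured pair (shell memberships and hydrogen bonds)."""
    rows = []

    def atom_label(i: int) -> str:
        a = structure.atoms[i]
        return f"{a.residue_name}{a.residue_seq}:{a.name}"

    for m, shell in report.shells.items():
        for cls, entries in (("first_shell", shell.first_shell), ("second_shell", shell.second_shell)):
            for i, d in entries:
                rows.append(
                    {
                        "atom_a": f"{atom_label(m)}[{report.metal_labels[m]}]",
                        "atom_b": atom_label(i),
                        "distance": round(d, report.params.rounding),
                        "classification": cls,
                    }
                )
    for (i, j), d in report.inter_metal_distances.items():
        rows.append(
            {
                "atom_a": f"{atom_label(i)}[{report.metal_labels[i]}]",
                "atom_b": f"{atom_label(j)}[{report.metal_labels[j]}]",
                "distance": round(d, report.params.rounding),
                "classification": "inter_metal",
            }
        )
    for h in report.hbonds:
        rows.append(
            {
                "atom_a": h.context_a,
                "atom_b": h.context_b,
                "distance": round(h.distance, report.params.rounding),
                "classification": "hbond_candidate",
            }
        )
    rows.append(
        {
            "atom_a": "ligand",
            "atom_b": "waters<=%.1fA" % report.params.water_shell,
            "distance": float(report.water_count),
            "classification": "water_count",
        }
    )
    return pd.DataFrame(rows, columns=["atom_a", "atom_b", "distance", "classification"])
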