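"""Structure mining for zinc-bound sulfamide zinc-binding groups.

The pipeline applies four stages in order, each gating the next:

1. element prefilter — the structure must contain every required element
   (default S, O, N and Zn);
2. substructure match — the sulfamide pattern ``S(O)(O)(N)N`` is searched in
   the element-labeled connectivity graph of every non-water ligand
   component (bond orders ignored; the central sulfur must have exactly the
   four pattern neighbors among heavy atoms);
3. metal proximity — a match survives if any atom of the mapped motif lies
   within the proximity cutoff (default 6 angstrom, closed) of a zinc;
4. nuclearity — a surviving site is binuclear when at least two nearby
   zincs are mutually within the binuclear separation limit (default 4.5
   angstrom), mononuclear when exactly served by isolated zincs.

Counts of structures surviving each stage form a monotone funnel recorded in
the :class:`MiningReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism

from .errors import ParameterError
from .structures import ComponentKey, MoleculeGraph, Structure, perceive_bonds


@dataclass
class SubstructurePattern:
    """A tiny element-labeled pattern graph with named slots."""

    name: str
    # nodes: slot label -> element; edges between slot labels
    nodes: dict[str, str]
    edges: list[tuple[str, str]]
    #: slots whose heavy-atom degree in the target must equal the pattern degree
    exact_degree: tuple[str, ...] = ()

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for slot, el in self.nodes.items():
            g.add_node(slot, element=el)
        g.add_edges_from(self.edges)
        return g


#: The sulfamide motif: tetravalent S bonded to two O and two N.
SULFAMIDE_PATTERN = SubstructurePattern(
    name="sulfamide",
    nodes={"S": "S", "O1": "O", "O2": "O", "N1": "N", "N2": "N"},
    edges=[("S", "O1"), ("S", "O2"), ("S", "N1"), ("S", "N2")],
    exact_degree=("S",),
)

PATTERNS = {"sulfamide": SULFAMIDE_PATTERN}


@dataclass
class MiningParams:
    required_elements: frozenset[str] = frozenset({"S", "O", "N", "ZN"})
    pattern: SubstructurePattern = field(default_factory=lambda: SULFAMIDE_PATTERN)
    metal_element: str = "Zn"
    proximity_cutoff: float = 6.0
    binuclear_max_separation: float = 4.5

    def __post_init__(self) -> None:
        self.required_elements = frozenset(e.upper() for e in self.required_elements)
        if self.proximity_cutoff <= 0 or self.binuclear_max_separation <= 0:
            raise ParameterError("cutoffs must be positive")


@dataclass
class ZBGMatch:
    """One matched motif with the zincs found near it."""

    structure_id: str
    component_key: ComponentKey
    mapping: dict[str, int]  # pattern slot -> atom index
    nearby_metals: list[tuple[int, float]] = field(default_factory=list)
    nuclearity: str = "unclassified"

    @property
    def atom_indices(self) -> tuple[int, ...]:
        return tuple(self.mapping[k] for k in sorted(self.mapping))


@dataclass
class MiningReport:
    n_scanned: int = 0
    n_element_pass: int = 0
    n_pattern_pass: int = 0
    n_proximity_pass: int = 0
    n_binuclear: int = 0
    matches: dict[str, list[ZBGMatch]] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def funnel(self) -> tuple[int, int, int, int, int]:
        return (
            self.n_scanned,
            self.n_element_pass,
            self.n_pattern_pass,
            self.n_proximity_pass,
            self.n_binuclear,
        )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def element_prefilter(structure: Structure, params: MiningParams | None = None) -> bool:
    """True iff every required element occurs at least once in the structure."""
    params = params or MiningParams()
    return params.required_elements.issubset(structure.element_set())


def _canonical(mapping: dict[str, int], pattern: SubstructurePattern) -> tuple:
    """Collapse symmetric slot swaps (O1/O2, N1/N2 ...) to one canonical key."""
    by_element: dict[str, list[int]] = {}
    for slot, el in pattern.nodes.items():
        by_element.setdefault(el, []).append(mapping[slot])
    return tuple((el, tuple(sorted(idx))) for el, idx in sorted(by_element.items()))


def match_substructure(
    graph: MoleculeGraph, pattern: SubstructurePattern | None = None
) -> list[dict[str, int]]:
    """All subgraph-isomorphic embeddings of the pattern, symmetry-deduplicated.

    Element labels and adjacency are respected; bond orders are ignored.
    Slots listed in ``pattern.exact_degree`` additionally require the target
    atom's heavy-atom degree to equal the pattern degree (this excludes e.g.
    higher-coordinate sulfur).
    """
    pattern = pattern or SULFAMIDE_PATTERN
    pg = pattern.to_graph()
    matcher = isomorphism.GraphMatcher(
        graph.graph,
        pg,
        node_match=lambda t, p: t["element"] == p["element"],
    )
    seen = {}
    # monomorphisms: pattern edges must exist in the target, extra target
    # edges among mapped atoms are allowed (SMARTS-like substructure search)
    for iso in matcher.subgraph_monomorphisms_iter():
        mapping = {slot: idx for idx, slot in iso.items()}
        ok = True
        for slot in pattern.exact_degree:
            if graph.graph.degree[mapping[slot]] != pg.degree[slot]:
                ok = False
                break
        if not ok:
            continue
        key = _canonical(mapping, pattern)
        if key not in seen:
            seen[key] = mapping
    return [seen[k] for k in sorted(seen)]


def find_nearby_metals(
    structure: Structure, match: ZBGMatch, params: MiningParams | None = None
) -> ZBGMatch:
    """Attach all metals within the (closed) proximity cutoff of any motif atom."""
    params = params or MiningParams()
    pos = structure.positions
    motif = np.array([pos[i] for i in match.mapping.values()])
    nearby = []
    for m in structure.metal_indices(params.metal_element):
        dmin = float(np.min(np.linalg.norm(motif - pos[m], axis=1)))
        if dmin <= params.proximity_cutoff:
            nearby.append((m, dmin))
    match.nearby_metals = sorted(nearby, key=lambda t: (t[1], t[0]))
    return match


def classify_nuclearity(
    match: ZBGMatch, structure: Structure, params: MiningParams | None = None
) -> str:
    """Label the matched site none / mononuclear / binuclear."""
    params = params or MiningParams()
    metals = [m for m, _ in match.nearby_metals]
    if not metals:
        match.nuclearity = "none"
    else:
        pos = structure.positions
        binuclear = any(
            np.linalg.norm(pos[i] - pos[j]) <= params.binuclear_max_separation
            for i, j in combinations(metals, 2)
        )
        match.nuclearity = "binuclear" if binuclear else "mononuclear"
    return match.nuclearity


def mine_structure(
    structure: Structure, params: MiningParams | None = None
) -> list[ZBGMatch]:
    """Run pattern + proximity + nuclearity on one structure (prefilter passed)."""
    params = params or MiningParams()
    matches: list[ZBGMatch] = []
    for key in structure.ligand_components():
        graph = perceive_bonds(structure, key)
        for mapping in match_substructure(graph, params.pattern):
            m = ZBGMatch(structure.id, key, mapping)
            find_nearby_metals(structure, m, params)
            classify_nuclearity(m, structure, params)
            matches.append(m)
    return matches


def mine(structures, params: MiningParams | None = None) -> MiningReport:
    """Full funnel over an iterable of structures (or (id, exception) pairs)."""
    params = params or MiningParams()
    report = MiningReport()
    for item in structures:
        if isinstance(item, tuple) and isinstance(item[1], Exception):
            report.n_scanned += 1
            report.failures[str(item[0])] = str(item[1])
            continue
        structure: Structure = item
        report.n_scanned += 1
        if not element_prefilter(structure, params):
            continue
        report.n_element_pass += 1
        matches = mine_structure(structure, params)
        if not matches:
            continue
        report.n_pattern_pass += 1
        report.matches[structure.id] = matches
        if any(m.nearby_metals for m in matches):
            report.n_proximity_pass += 1
        if any(m.nuclearity == "binuclear" for m in matches):
            report.n_binuclear += 1
    return report


def report_table(report: MiningReport):
    """Tidy per-match table (pandas DataFrame) for TSV export."""
    import pandas as pd

    rows = []
    for sid, matches in report.matches.items():
        for m in matches:
            rows.append(
                {
                    "structure_id": sid,
                    "component": ":".join(str(p) for p in m.component_key),
                    "match_atoms": ",".join(f"{s}={i}" for s, i in sorted(m.mapping.items())),
                    "n_metals": len(m.nearby_metals),
                    "min_dist": min((d for _, d in m.nearby_metals), default=float("nan")),
                    "nuclearity": m.nuclearity,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["structure_id", "component", "match_atoms", "n_metals", "min_dist", "nuclearity"],
    )
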