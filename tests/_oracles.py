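"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check.
"""

from itertools import permutations

import numpy as np


def brute_force_matches(graph, pattern):
    """All canonical embeddings of the pattern by exhaustive enumeration.

    Enumerates every injective mapping of pattern slots onto graph nodes,
    keeping those where element labels agree, every pattern edge is present
    in the target, and exact-degree slots have matching heavy-atom degree.
    Symmetric duplicates are collapsed by the sorted per-element atom sets.
    Exponential; only usable on graphs of a dozen atoms.
    """
    g = graph.graph
    nodes = list(g.nodes)
    slots = list(pattern.nodes)
    found = {}
    for perm in permutations(nodes, len(slots)):
        mapping = dict(zip(slots, perm))
        if any(g.nodes[mapping[s]]["element"] != pattern.nodes[s] for s in slots):
            continue
        if any(not g.has_edge(mapping[a], mapping[b]) for a, b in pattern.edges):
            continue
        pattern_degree = {s: 0 for s in slots}
        for a, b in pattern.edges:
            pattern_degree[a] += 1
            pattern_degree[b] += 1
        if any(g.degree[mapping[s]] != pattern_degree[s] for s in pattern.exact_degree):
            continue
        by_el = {}
        for s in slots:
            by_el.setdefault(pattern.nodes[s], []).append(mapping[s])
        key = tuple((el, tuple(sorted(ix))) for el, ix in sorted(by_el.items()))
        found.setdefault(key, mapping)
    return found


def brute_force_min_rmsd(a, b, coarse_step_deg=15.0):
    """Minimum RMSD over rotations by dense sampling plus local refinement."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(np.mean(np.sum((a @ R.T - b) ** 2, axis=1))))

    best = (np.inf, None)
    grid = np.arange(0.0, 360.0, coarse_step_deg)
    half = np.arange(-90.0, 90.1, coarse_step_deg)
    for e1 in grid:
        for e2 in half:
            for e3 in grid:
                rv = Rotation.from_euler("zyz", [e1, e2, e3], degrees=True).as_rotvec()
                v = rmsd_of(rv)
                if v < best[0]:
                    best = (v, rv)
    res = minimize(rmsd_of, best[1], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14})
    return min(best[0], float(res.fun))
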