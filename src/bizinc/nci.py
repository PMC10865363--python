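"""Promolecular noncovalent-interaction (NCI) fields over a bimetallic site.

The promolecular density is the sum of spherically averaged free-atom
densities, each represented as a fitted sum of exponentials
``rho_elem(r) = sum_i c_i exp(-r / zeta_i)`` (atomic units; one term for H
and He, two for the first row, three for the second row). The reduced
density gradient

    s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3))

is small where noncovalent interactions occur, and the density signed by the
middle eigenvalue of its Hessian, sign(lambda2) * rho, separates attractive
(negative), van der Waals (near zero) and repulsive (positive) regions.
Gradient and Hessian are analytic from the same exponentials.

Elements beyond the fitted table (including zinc) fall back to the nearest
parameterized atomic number with a logged warning; a promolecular density is
an approximation for any element, and this keeps the field well defined over
the metal site.

All density math is in atomic units internally; interfaces take angstrom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .errors import DomainError, SelectionError
from .structures import ANGSTROM_TO_BOHR, Structure, write_cube

logger = logging.getLogger(__name__)

# Fitted free-atom density parameters, atomic units: Z -> [(c_i, zeta_i), ...].
# Single exponential for H/He, two for Li-Ne, three for Na-Ar.
PROMOLECULAR_PARAMS: dict[int, list[tuple[float, float]]] = {
    1: [(0.2815, 0.5288)],
    2: [(2.437, 0.3379)],
    3: [(11.84, 0.1912), (0.06332, 1.0256)],
    4: [(31.34, 0.1390), (0.3694, 0.6945)],
    5: [(67.82, 0.1059), (0.8527, 0.5300)],
    6: [(120.2, 0.0884), (1.172, 0.4168)],
    7: [(190.9, 0.0767), (2.247, 0.3460)],
    8: [(289.5, 0.0669), (2.879, 0.3051)],
    9: [(406.3, 0.0608), (3.049, 0.2754)],
    10: [(561.3, 0.0549), (6.984, 0.2439)],
    11: [(760.8, 0.0507), (22.42, 0.2433), (0.06358, 1.3064)],
    12: [(1016.0, 0.0468), (37.17, 0.2278), (0.3331, 0.9966)],
    13: [(1319.0, 0.0435), (57.95, 0.2125), (0.8878, 0.8038)],
    14: [(1658.0, 0.0407), (87.16, 0.1985), (0.7888, 0.7185)],
    15: [(2042.0, 0.0382), (115.7, 0.1878), (1.465, 0.6550)],
    16: [(2501.0, 0.0358), (158.0, 0.1773), (2.170, 0.6084)],
    17: [(3024.0, 0.0337), (205.5, 0.1687), (3.369, 0.5565)],
    18: [(3625.0, 0.0318), (260.0, 0.1610), (5.211, 0.5231)],
}

_RDG_PREFACTOR = 2.0 * (3.0 * math.pi**2) ** (1.0 / 3.0)

_warned_elements: set[str] = set()


def _params_for(element: str) -> list[tuple[float, float]]:
    z = gemmi.Element(element).atomic_number
    if z in PROMOLECULAR_PARAMS:
        return PROMOLECULAR_PARAMS[z]
    nearest = min(PROMOLECULAR_PARAMS, key=lambda k: abs(k - z))
    if element not in _warned_elements:
        _warned_elements.add(element)
        logger.warning(
            "no promolecular fit for %s (Z=%d); using nearest parameterized Z=%d",
            element, z, nearest,
        )
    return PROMOLECULAR_PARAMS[nearest]


@dataclass
class NCIParams:
    selection_radius: float = 3.5  # angstrom around the metals
    grid_spacing: float = 0.15  # angstrom
    grid_padding: float = 2.0  # angstrom
    density_cutoff: float = 0.3  # a.u.; masks covalent/core regions
    rdg_isovalue: float = 0.5
    strong_attraction_threshold: float = -0.02  # a.u. on sign(lambda2)*rho
    vdw_band: float = 0.01
    metal_element: str = "Zn"
    buffer: float = 2.0  # extra ring of density-only atoms, angstrom

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0 or self.density_cutoff <= 0:
            raise DomainError("grid spacing and density cutoff must be positive")


@dataclass
class ScalarFieldSet:
    origin: np.ndarray  # angstrom
    spacing: float  # angstrom, isotropic
    shape: tuple[int, int, int]
    rho: np.ndarray
    rdg: np.ndarray
    signed_rho: np.ndarray
    mask: np.ndarray  # True where rho <= density_cutoff (analysis region)
    selection_atoms: list[int]
    buffer_atoms: list[int]

    def grid_points(self) -> np.ndarray:
        nx, ny, nz = self.shape
        ax = [self.origin[k] + self.spacing * np.arange(n) for k, n in enumerate((nx, ny, nz))]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)


@dataclass
class NCISummary:
    n_analyzed: int
    fraction_strong_attractive: float
    fraction_vdw: float
    fraction_repulsive: float
    per_pair: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# density, gradient, Hessian
# ---------------------------------------------------------------------------


def promolecular_density(
    atoms: list[tuple[str, np.ndarray]],
    points: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Density, gradient and Hessian of the promolecular density.

    ``atoms`` are (element, position) with positions in angstrom; ``points``
    is (n, 3) in angstrom. Returns rho (n,), grad (n, 3), hessian (n, 3, 3),
    all in atomic units.
    """
    if not atoms:
        raise SelectionError("promolecular density needs at least one atom")
    pts = np.atleast_2d(np.asarray(points, dtype=float)) * ANGSTROM_TO_BOHR
    if not np.all(np.isfinite(pts)):
        raise DomainError("non-finite evaluation point")
    n = pts.shape[0]
    rho = np.zeros(n)
    grad = np.zeros((n, 3))
    hess = np.zeros((n, 3, 3))
    eye = np.eye(3)
    for element, pos in atoms:
        params = _params_for(element)
        d = pts - np.asarray(pos, dtype=float) * ANGSTROM_TO_BOHR
        r = np.linalg.norm(d, axis=1)
        r_safe = np.maximum(r, 1e-10)
        u = d / r_safe[:, None]
        f = np.zeros(n)
        fp = np.zeros(n)
        fpp = np.zeros(n)
        for c, zeta in params:
            e = c * np.exp(-r / zeta)
            f += e
            fp += -e / zeta
            fpp += e / zeta**2
        rho += f
        grad += fp[:, None] * u
        uu = u[:, :, None] * u[:, None, :]
        hess += fpp[:, None, None] * uu + (fp / r_safe)[:, None, None] * (eye[None] - uu)
    return rho, grad, hess


def reduced_density_gradient(rho: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3)), atomic units."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise DomainError("reduced density gradient requires rho > 0")
    gnorm = np.linalg.norm(np.atleast_2d(grad), axis=-1).reshape(rho.shape)
    return gnorm / (_RDG_PREFACTOR * rho ** (4.0 / 3.0))


def signed_density(rho: np.ndarray, hessian: np.ndarray) -> np.ndarray:
    """rho carrying the sign of the middle Hessian eigenvalue (lambda2)."""
    h = np.asarray(hessian, dtype=float)
    single = h.ndim == 2
    if single:
        h = h[None]
    eigvals = np.linalg.eigvalsh(h)  # ascending
    lam2 = eigvals[:, 1]
    sign = np.where(lam2 < 0, -1.0, 1.0)
    out = sign * np.asarray(rho, dtype=float).reshape(-1)
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# field over a structure
# ---------------------------------------------------------------------------


def compute_field(structure: Structure, params: NCIParams | None = None) -> ScalarFieldSet:
    """Evaluate rho, s and sign(lambda2)rho over the metal-site neighborhood.

    The atom set is the metals plus every atom within ``selection_radius`` of
    any metal; a further ring of atoms within ``selection_radius + buffer``
    contributes density only (suppresses edge artifacts but is excluded from
    per-atom tallies). The grid spans the selection bounding box plus
    padding. Points with rho above ``density_cutoff`` are masked out of the
    analysis region (covalent/core exclusion).
    """
    params = params or NCIParams()
    metals = structure.metal_indices(params.metal_element)
    if not metals:
        raise SelectionError(f"no {params.metal_element} atoms in {structure.id}")
    pos = structure.positions
    mp = pos[metals]
    dist_to_metal = np.min(
        np.linalg.norm(pos[:, None, :] - mp[None, :, :], axis=2), axis=1
    )
    selection = sorted(set(metals) | {int(i) for i in np.flatnonzero(dist_to_metal <= params.selection_radius)})
    buffer_atoms = [
        int(i)
        for i in np.flatnonzero(
            (dist_to_metal > params.selection_radius)
            & (dist_to_metal <= params.selection_radius + params.buffer)
        )
    ]
    sel_pos = pos[selection]
    lo = sel_pos.min(axis=0) - params.grid_padding
    hi = sel_pos.max(axis=0) + params.grid_padding
    shape = tuple(int(math.floor((hi[k] - lo[k]) / params.grid_spacing)) + 1 for k in range(3))
    axes = [lo[k] + params.grid_spacing * np.arange(shape[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    contributing = [
        (structure.atoms[i].element, pos[i]) for i in selection + buffer_atoms
    ]
    rho = np.zeros(points.shape[0])
    grad = np.zeros((points.shape[0], 3))
    hess = np.zeros((points.shape[0], 3, 3))
    chunk = 20000
    for start in range(0, points.shape[0], chunk):
        sl = slice(start, start + chunk)
        r, g, h = promolecular_density(contributing, points[sl])
        rho[sl], grad[sl], hess[sl] = r, g, h

    rdg = reduced_density_gradient(rho, grad)
    srho = signed_density(rho, hess)
    mask = rho <= params.density_cutoff
    return ScalarFieldSet(
        origin=lo,
        spacing=params.grid_spacing,
        shape=shape,
        rho=rho.reshape(shape),
        rdg=rdg.reshape(shape),
        signed_rho=np.asarray(srho).reshape(shape),
        mask=mask.reshape(shape),
        selection_atoms=selection,
        buffer_atoms=buffer_atoms,
    )


def classify_interactions(
    fields: ScalarFieldSet,
    params: NCIParams | None = None,
    structure: Structure | None = None,
) -> NCISummary:
    """Tally interaction classes on the low-s, low-rho analysis region.

    Strong attractive: sign(lambda2)rho <= strong_attraction_threshold;
    van der Waals: |sign(lambda2)rho| <= vdw_band; repulsive:
    sign(lambda2)rho >= |strong_attraction_threshold|. When a structure is
    given, qualifying points are also tallied per nearest selection-atom pair.
    """
    params = params or NCIParams()
    region = fields.mask & (fields.rdg <= params.rdg_isovalue)
    n = int(region.sum())
    if n == 0:
        return NCISummary(0, 0.0, 0.0, 0.0)
    sr = fields.signed_rho[region]
    strong = sr <= params.strong_attraction_threshold
    vdw = np.abs(sr) <= params.vdw_band
    repulsive = sr >= abs(params.strong_attraction_threshold)

    per_pair = pd.DataFrame()
    if structure is not None and fields.selection_atoms:
        pts = fields.grid_points().reshape(*fields.shape, 3)[region]
        sel = fields.selection_atoms
        sel_pos = structure.positions[sel]
        d = np.linalg.norm(pts[:, None, :] - sel_pos[None, :, :], axis=2)
        nearest2 = np.argsort(d, axis=1)[:, :2]
        rows: dict[tuple[str, str], dict[str, int]] = {}
        for k in range(pts.shape[0]):
            i, j = sorted(int(x) for x in nearest2[k])
            ai, aj = structure.atoms[sel[i]], structure.atoms[sel[j]]
            key = (
                f"{ai.residue_name}{ai.residue_seq}:{ai.name}",
                f"{aj.residue_name}{aj.residue_seq}:{aj.name}",
            )
            rec = rows.setdefault(key, {"strong_attractive": 0, "vdw": 0, "repulsive": 0, "total": 0})
            rec["total"] += 1
            if strong[k]:
                rec["strong_attractive"] += 1
            if vdw[k]:
                rec["vdw"] += 1
            if repulsive[k]:
                rec["repulsive"] += 1
        per_pair = pd.DataFrame(
            [
                {"atom_a": a, "atom_b": b, **counts}
                for (a, b), counts in sorted(rows.items())
            ]
        )
    return NCISummary(
        n_analyzed=n,
        fraction_strong_attractive=float(strong.mean()),
        fraction_vdw=float(vdw.mean()),
        fraction_repulsive=float(repulsive.mean()),
        per_pair=per_pair,
    )


def export_cubes(fields: ScalarFieldSet, structure: Structure, out_dir, stem: str = "nci") -> list:
    """Write rho / rdg / signed-rho cube files for external viewers."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atoms = [
        (structure.atoms[i].element, structure.atoms[i].position)
        for i in fields.selection_atoms
    ]
    paths = []
    for name, values in (("rho", fields.rho), ("rdg", fields.rdg), ("signed_rho", fields.signed_rho)):
        p = out / f"{stem}_{name}.cube"
        write_cube(p, fields.origin, fields.spacing, values, atoms, comment=f"bizinc {name}")
        paths.append(p)
    return paths
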