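"""Desk-scale voxel-based linear-elastic micro-FE compression model.

Every foreground voxel becomes one 8-node trilinear hexahedral element with
identical isotropic tissue properties, so the global stiffness is assembled
from a single element matrix scaled by E*h. Compression is displacement
driven and frictionless: the axial displacement of the proximal surface
nodes under the plunger footprint is prescribed, the distal surface is fixed
axially, lateral motion is free except for minimal rigid-body pinning.
Von Mises stress is evaluated at element centers; the apparent modulus is
engineering stress over engineering strain using the nominal plunger area.

Units: lengths mm, moduli GPa, forces kN (GPa * mm^2), stresses MPa in the
reported von Mises field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import cg

from .decompose import ElementMap
from .prgraph import LoadCase
from .volume import BinaryVolume

__all__ = [
    "FEParams",
    "FESystem",
    "FEResult",
    "hex_stiffness",
    "assemble",
    "solve_compression",
    "von_mises",
    "apparent_modulus",
    "element_stress_table",
]

#: desk-scale cap on element count (large-scale solvers are out of scope)
MAX_ELEMENTS = 300_000

_CORNERS = np.array(list(product((0, 1), repeat=3)), np.int64)  # local node offsets
_STRUCT26 = np.ones((3, 3, 3), bool)


@dataclass
class FEParams:
    """Tissue material and loading parameters."""

    youngs_modulus: float = 15.0  # GPa
    poisson: float = 0.3
    strain: float = 0.01  # applied axial strain (LoadCase.strain takes precedence)
    rtol: float = 1e-8
    maxiter: int = 20000

    def __post_init__(self) -> None:
        if not (self.youngs_modulus > 0):
            raise ValueError("E must be > 0")
        if not (0 <= self.poisson < 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5)")
        if not (self.strain > 0):
            raise ValueError("strain must be > 0")


def _elastic_matrix(E: float, nu: float) -> np.ndarray:
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


def _b_matrix(xi: np.ndarray, h: float) -> np.ndarray:
    """Strain-displacement matrix at local point xi (in [-1,1]^3), edge h."""
    loc = 2.0 * _CORNERS - 1.0  # (8, 3) local corner signs
    dN = np.empty((8, 3))
    for a in range(8):
        sa = loc[a]
        dN[a, 0] = sa[0] * (1 + xi[1] * sa[1]) * (1 + xi[2] * sa[2]) / 8.0
        dN[a, 1] = sa[1] * (1 + xi[0] * sa[0]) * (1 + xi[2] * sa[2]) / 8.0
        dN[a, 2] = sa[2] * (1 + xi[0] * sa[0]) * (1 + xi[1] * sa[1]) / 8.0
    dN *= 2.0 / h  # jacobian of the cube element is (h/2) I
    B = np.zeros((6, 24))
    for a in range(8):
        bx, by, bz = dN[a]
        c = 3 * a
        B[0, c] = bx
        B[1, c + 1] = by
        B[2, c + 2] = bz
        B[3, c] = by
        B[3, c + 1] = bx
        B[4, c + 1] = bz
        B[4, c + 2] = by
        B[5, c] = bz
        B[5, c + 2] = bx
    return B


def hex_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """24x24 stiffness of a cube trilinear hexahedron (2-point Gauss rule).

    Symmetric positive semidefinite with exactly six zero-energy (rigid-body)
    modes; scales linearly in E and in the edge length h.
    """
    D = _elastic_matrix(E, nu)
    g = 1.0 / np.sqrt(3.0)
    ke = np.zeros((24, 24))
    detJ = (h / 2.0) ** 3
    for gx, gy, gz in product((-g, g), repeat=3):
        B = _b_matrix(np.array([gx, gy, gz]), h)
        ke += B.T @ D @ B * detJ
    return (ke + ke.T) / 2.0


@dataclass
class FESystem:
    """Assembled voxel FE system (stiffness, mesh bookkeeping)."""

    K: csr_matrix
    node_ijk: np.ndarray  # (n_nodes, 3) lattice coordinates
    edofs: np.ndarray  # (n_elements, 24) global dof indices
    voxels: np.ndarray  # (n_elements, 3) voxel coordinates
    spacing: float  # um
    shape: tuple[int, int, int]
    params: FEParams
    excluded_voxels: int = 0

    @property
    def h_mm(self) -> float:
        return self.spacing / 1000.0

    @property
    def n_nodes(self) -> int:
        return len(self.node_ijk)


@dataclass
class FEResult:
    """Solution fields and reactions of a compression solve."""

    system: FESystem
    u: np.ndarray  # (n_nodes, 3) displacements, mm
    reaction_prox: float  # kN, axial, on the loaded footprint
    reaction_dist: float  # kN, axial, on the supported face
    strain: float
    load_case: LoadCase
    prescribed_dofs: np.ndarray
    residual: float

    @property
    def reaction_N(self) -> float:
        return abs(self.reaction_prox) * 1000.0


def assemble(b: BinaryVolume, p: FEParams | None = None) -> FESystem:
    """One hexahedral element per foreground voxel; shared corner nodes.

    Foreground components not 26-connected to both loading faces cannot
    transmit load and would make the system singular; they are excluded and
    reported via a warning.
    """
    p = p or FEParams()
    fg = b.data
    if not fg.any():
        raise ValueError("empty foreground: nothing to assemble")
    zs = np.where(fg.any(axis=(0, 1)))[0]
    z_min, z_max = int(zs[0]), int(zs[-1])
    lab, ncomp = ndimage.label(fg, structure=_STRUCT26)
    keep_ids = [
        i
        for i in range(1, ncomp + 1)
        if (lab[:, :, z_min] == i).any() and (lab[:, :, z_max] == i).any()
    ]
    kept = np.isin(lab, keep_ids)
    excluded = int(fg.sum() - kept.sum())
    if excluded:
        warnings.warn(
            f"assemble: excluded {excluded} foreground voxels not connected "
            "to both loading faces"
        )
    if not kept.any():
        raise ValueError("no foreground connects the two loading faces")
    voxels = np.argwhere(kept)
    ne = len(voxels)
    if ne > MAX_ELEMENTS:
        raise ValueError(f"{ne} elements exceeds the desk-scale cap {MAX_ELEMENTS}")
    nx, ny, nz = fg.shape
    # global lattice node ids, then compress to the used subset
    stride = np.array([(ny + 1) * (nz + 1), nz + 1, 1], np.int64)
    enodes = np.empty((ne, 8), np.int64)
    for a, off in enumerate(_CORNERS):
        enodes[:, a] = (voxels + off) @ stride
    used, inv = np.unique(enodes, return_inverse=True)
    enodes_c = inv.reshape(ne, 8)
    node_ijk = np.stack(
        [used // ((ny + 1) * (nz + 1)), (used // (nz + 1)) % (ny + 1), used % (nz + 1)],
        axis=1,
    )
    edofs = (3 * enodes_c[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 24)
    ke = hex_stiffness(p.youngs_modulus, p.poisson, b.spacing / 1000.0)
    ndof = 3 * len(used)
    rows = np.repeat(edofs, 24, axis=1).ravel()
    cols = np.tile(edofs, (1, 24)).ravel()
    data = np.tile(ke.ravel(), ne)
    K = coo_matrix((data, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return FESystem(K, node_ijk, edofs, voxels, b.spacing, fg.shape, p, excluded)


def _node_footprint(sys: FESystem, diameter: float | None) -> np.ndarray:
    """Boolean mask over nodes: in-plane position inside the plunger disc."""
    if diameter is None:
        return np.ones(sys.n_nodes, bool)
    nx, ny, _ = sys.shape
    r = diameter * 1000.0 / sys.spacing / 2.0
    cx, cy = nx / 2.0, ny / 2.0
    xy = sys.node_ijk[:, :2].astype(float)
    return (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2 <= r**2


def solve_compression(
    sys: FESystem, lc: LoadCase, p: FEParams | None = None
) -> FEResult:
    """Displacement-driven frictionless uniaxial compression.

    Axial displacement strain*L is prescribed on the proximal-face nodes
    inside the plunger footprint, the distal face is fixed axially, lateral
    translations are unconstrained apart from minimal per-component pinning
    of the rigid-body modes. Solved with Jacobi-preconditioned CG.
    """
    p = p or sys.params
    strain = lc.strain
    h = sys.h_mm
    zn = sys.node_ijk[:, 2]
    z_lo, z_hi = int(zn.min()), int(zn.max())
    L = (z_hi - z_lo) * h
    fp = _node_footprint(sys, lc.plunger_diameter)
    prox_nodes = np.where((zn == z_lo) & fp)[0]
    dist_nodes = np.where(zn == z_hi)[0]
    if len(prox_nodes) == 0:
        raise ValueError("plunger footprint touches no proximal node")
    ndof = sys.K.shape[0]
    u = np.zeros(ndof)
    fixed = np.zeros(ndof, bool)
    u[3 * prox_nodes + 2] = strain * L  # pushed toward the distal face
    fixed[3 * prox_nodes + 2] = True
    fixed[3 * dist_nodes + 2] = True
    # minimal rigid-body pinning, per connected node set (lateral modes only)
    for comp_nodes in _node_components(sys):
        pn = np.intersect1d(comp_nodes, prox_nodes)
        anchor_pool = pn if len(pn) else comp_nodes
        cx, cy = sys.node_ijk[anchor_pool, 0].mean(), sys.node_ijk[anchor_pool, 1].mean()
        d2 = (sys.node_ijk[anchor_pool, 0] - cx) ** 2 + (
            sys.node_ijk[anchor_pool, 1] - cy
        ) ** 2
        a0 = int(anchor_pool[np.argmin(d2)])
        fixed[3 * a0] = True
        fixed[3 * a0 + 1] = True
        far = int(anchor_pool[np.argmax(d2)])
        if far != a0:
            dx = abs(sys.node_ijk[far, 0] - sys.node_ijk[a0, 0])
            dy = abs(sys.node_ijk[far, 1] - sys.node_ijk[a0, 1])
            fixed[3 * far + (1 if dx >= dy else 0)] = True
    free = ~fixed
    K = sys.K
    rhs = -K[:, fixed] @ u[fixed]
    Kff = K[free][:, free]
    d = Kff.diagonal()
    d[d == 0] = 1.0
    from scipy.sparse import diags

    M = diags(1.0 / d)
    x, info = cg(Kff, rhs[free], rtol=p.rtol, atol=0.0, maxiter=p.maxiter, M=M)
    if info != 0:
        res = np.linalg.norm(Kff @ x - rhs[free]) / max(np.linalg.norm(rhs[free]), 1e-30)
        raise RuntimeError(f"CG did not converge (info={info}, rel residual {res:.2e})")
    u[free] = x
    f_all = K @ u
    resid = np.linalg.norm(f_all[free]) / max(np.linalg.norm(f_all[fixed]), 1e-30)
    r_prox = float(f_all[3 * prox_nodes + 2].sum())
    r_dist = float(f_all[3 * dist_nodes + 2].sum())
    pres = np.where(fixed)[0]
    return FEResult(sys, u.reshape(-1, 3), r_prox, r_dist, strain, lc, pres, resid)


def _node_components(sys: FESystem) -> list[np.ndarray]:
    """Node index sets of the 26-connected voxel components (share no nodes)."""
    vol = np.zeros(sys.shape, bool)
    vol[tuple(sys.voxels.T)] = True
    lab, n = ndimage.label(vol, structure=_STRUCT26)
    if n == 1:
        return [np.arange(sys.n_nodes)]
    comp_of_elem = lab[tuple(sys.voxels.T)]
    out = []
    node_comp = np.zeros(sys.n_nodes, np.int64)
    enodes = sys.edofs[:, ::3] // 3
    for c in range(1, n + 1):
        nodes = np.unique(enodes[comp_of_elem == c])
        out.append(nodes)
    return out


def von_mises(fr: FEResult) -> np.ndarray:
    """Per-voxel von Mises stress (MPa) at element centers; background is 0."""
    sys = fr.system
    p = sys.params
    B0 = _b_matrix(np.zeros(3), sys.h_mm)
    D = _elastic_matrix(p.youngs_modulus, p.poisson)
    ue = fr.u.reshape(-1)[sys.edofs]  # (ne, 24)
    eps = ue @ B0.T  # (ne, 6)
    sig = eps @ D.T  # GPa
    sx, sy, sz, txy, tyz, tzx = sig.T
    vm = np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )
    field = np.zeros(sys.shape)
    field[tuple(sys.voxels.T)] = vm * 1000.0  # GPa -> MPa
    return field


def apparent_modulus(fr: FEResult, lc: LoadCase | None = None) -> float:
    """(reaction / nominal plunger area) / applied strain, in GPa.

    The nominal area is the plunger disc if a diameter is set, otherwise the
    cross-section of the foreground bounding box (the "original specimen
    dimensions" convention).
    """
    lc = lc or fr.load_case
    sys = fr.system
    h = sys.h_mm
    if lc.plunger_diameter is not None:
        d_mm = lc.plunger_diameter
        area = np.pi * (d_mm / 2.0) ** 2
    else:
        ext = sys.voxels.max(axis=0) - sys.voxels.min(axis=0) + 1
        area = float(ext[0] * ext[1]) * h * h
    if area <= 0:
        raise ValueError("zero footprint area")
    stress = fr.reaction_N / 1000.0 / area  # kN / mm^2 = GPa
    return abs(stress) / fr.strain


def element_stress_table(fr: FEResult, em: ElementMap):
    """Per-element summary (mean/median/max) of the von Mises field."""
    import pandas as pd

    field = von_mises(fr)
    solved = np.zeros(fr.system.shape, bool)
    solved[tuple(fr.system.voxels.T)] = True
    rows = []
    for i in em.ids:
        vox = em.labels == i
        vals = field[vox & solved]
        if vals.size == 0:
            rows.append(
                {"id": i, "mean": 0.0, "median": 0.0, "max": 0.0, "excluded": True}
            )
        else:
            rows.append(
                {
                    "id": i,
                    "mean": float(vals.mean()),
                    "median": float(np.median(vals)),
                    "max": float(vals.max()),
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows, columns=["id", "mean", "median", "max", "excluded"])
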