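"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately avoid the package's own code
paths (no numba kernels, no shared helpers): neighborhood topology is
recomputed with scipy.ndimage.label on extracted 3x3x3 blocks, distances
and counts by direct enumeration.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from prnet import BinaryVolume, DensityVolume


# ---------------------------------------------------------------------------
# shape zoo (solid test objects for thinning / topology)
# ---------------------------------------------------------------------------


def solid_rod(radius=3.0, length=20, pad=3):
    n = int(2 * radius) + 2 * pad + 1
    c = n // 2
    x, y = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    disc = x**2 + y**2 <= radius**2
    a = np.zeros((n, n, length + 2 * pad), bool)
    a[:, :, pad : pad + length] = disc[:, :, None]
    return a


def square_rod(width=3, length=20, pad=3):
    n = width + 2 * pad
    a = np.zeros((n, n, length + 2 * pad), bool)
    a[pad : pad + width, pad : pad + width, pad : pad + length] = True
    return a


def solid_plate(nx=15, ny=15, thickness=3, pad=3):
    a = np.zeros((nx + 2 * pad, ny + 2 * pad, thickness + 2 * pad), bool)
    a[pad : pad + nx, pad : pad + ny, pad : pad + thickness] = True
    return a


def hollow_shell(outer=7, pad=2):
    n = outer + 2 * pad
    a = np.zeros((n, n, n), bool)
    s = slice(pad, pad + outer)
    a[s, s, s] = True
    inner = slice(pad + 1, pad + outer - 1)
    a[inner, inner, inner] = False
    return a


def solid_torus(R=6.0, r=2.2, pad=2):
    n = int(2 * (R + r)) + 2 * pad + 1
    c = n // 2
    x, y, z = np.meshgrid(
        np.arange(n) - c, np.arange(n) - c, np.arange(2 * int(r) + 2 * pad + 1) - (int(r) + pad),
        indexing="ij",
    )
    a = (np.sqrt(x**2 + y**2) - R) ** 2 + z**2 <= r**2
    return a


def small_lattice():
    from prnet import phantom as ph

    spec = ph.vertical_lattice(
        n_columns=2, n_decks=2, rod_radius=2.2, grid=(26, 26, 26), spacing=200.0, seed=4
    )
    from prnet import preprocess

    vol, mask, truth = ph.generate(spec)
    return preprocess(vol).data


def shape_suite() -> list[tuple[str, np.ndarray]]:
    """Ten solid shapes: rods, plates, torus, shell, lattice, blobs."""
    return [
        ("rod_r3", solid_rod(3.0, 20)),
        ("rod_r2", solid_rod(2.0, 16)),
        ("square_rod3", square_rod(3, 18)),
        ("square_rod5", square_rod(5, 14)),
        ("plate_t3", solid_plate(15, 15, 3)),
        ("plate_t2", solid_plate(12, 10, 2)),
        ("shell", hollow_shell(7)),
        ("torus", solid_torus()),
        ("cube", square_rod(7, 7)),
        ("lattice", small_lattice()),
    ]


@pytest.fixture(scope="session")
def shapes():
    return shape_suite()


# ---------------------------------------------------------------------------
# independent classification oracle (scipy-based, no package internals)
# ---------------------------------------------------------------------------

_S6 = ndimage.generate_binary_structure(3, 1)
_S26 = np.ones((3, 3, 3), bool)


def _neighborhood(vol: np.ndarray, p) -> np.ndarray:
    x, y, z = p
    return vol[x - 1 : x + 2, y - 1 : y + 2, z - 1 : z + 2].copy()


def oracle_features(vol: np.ndarray, p) -> tuple[int, int, int]:
    """(n, xi6, eta) for a padded boolean volume at point p, via scipy."""
    nb = _neighborhood(vol, p)
    center = nb[1, 1, 1]
    assert center
    nb[1, 1, 1] = False
    n = int(nb.sum())
    _, xi6 = ndimage.label(nb, structure=_S6)
    # eta: 6-components of background within N18 that touch a face neighbor
    man = np.zeros((3, 3, 3), int)
    for dx in range(3):
        for dy in range(3):
            for dz in range(3):
                man[dx, dy, dz] = abs(dx - 1) + abs(dy - 1) + abs(dz - 1)
    bg18 = (~nb) & (man >= 1) & (man <= 2)
    lab, k = ndimage.label(bg18, structure=_S6)
    eta = 0
    faces = man == 1
    for i in range(1, k + 1):
        if ((lab == i) & faces).any():
            eta += 1
    return n, int(xi6), eta


def oracle_base_class(n: int, xi6: int, eta: int) -> int:
    """Same decision table as the implementation, evaluated independently."""
    from prnet.skeleton import VoxelClass as V

    if n == 0:
        return int(V.ISOLATED)
    if n == 1:
        return int(V.ARC_END)
    if xi6 >= 3:
        return int(V.ARC_ARC)
    if eta >= 3:
        return int(V.SURFACE_SURFACE)
    if eta == 2:
        return int(V.SURFACE)
    if xi6 == 2:
        return int(V.ARC)
    return int(V.SURFACE_END)


def oracle_classify(skel: np.ndarray) -> np.ndarray:
    """Full oracle: base table + the arc/surface family adjacency pass."""
    from prnet.skeleton import VoxelClass as V

    vol = np.pad(skel, 1)
    out = np.zeros(vol.shape, np.int8)
    for p in np.argwhere(vol):
        out[tuple(p)] = oracle_base_class(*oracle_features(vol, tuple(p)))
    surf_any = np.isin(
        out, (int(V.SURFACE), int(V.SURFACE_END), int(V.SURFACE_SURFACE))
    )
    arcish = np.isin(out, (int(V.ARC), int(V.ARC_END)))
    # only arc branches of >= 3 voxels count as the arc side of a junction
    lab, ncomp = ndimage.label(arcish, structure=_S26)
    branch = np.zeros_like(arcish)
    for i in range(1, ncomp + 1):
        comp = lab == i
        if comp.sum() >= 3:
            branch |= comp
    surfish = np.isin(out, (int(V.SURFACE), int(V.SURFACE_END)))
    near_arc = ndimage.binary_dilation(branch, _S26)
    near_surf = ndimage.binary_dilation(surf_any, _S26)
    res = out.copy()
    res[surfish & near_arc] = int(V.ARC_SURFACE)
    res[branch & near_surf] = int(V.ARC_SURFACE)
    return res[1:-1, 1:-1, 1:-1]


# ---------------------------------------------------------------------------
# exhaustive min-cut oracle
# ---------------------------------------------------------------------------


def min_cut_exhaustive(g) -> float:
    """Minimum s-t cut by enumerating all vertex bipartitions (<= 12 nodes)."""
    import itertools

    nodes = [n for n in g if n not in ("s", "t")]
    best = np.inf
    for r in range(len(nodes) + 1):
        for side in itertools.combinations(nodes, r):
            s_side = set(side) | {"s"}
            cut = 0.0
            for u, v, d in g.edges(data=True):
                if (u in s_side) != (v in s_side):
                    cut += d.get("capacity", np.inf)
            best = min(best, cut)
    return best


# ---------------------------------------------------------------------------
# misc fixtures
# ---------------------------------------------------------------------------


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def ibeam():
    """I-beam phantom: two decks joined by one column (density chain)."""
    from prnet import LoadCase, phantom as ph
    from prnet.pipeline import run_pr_network

    spec = ph.vertical_lattice(
        n_columns=1, n_decks=2, rod_radius=2.2, grid=(30, 30, 30), spacing=200.0, seed=1
    )
    vol, mask, truth = ph.generate(spec)
    return run_pr_network(vol, mask, LoadCase(strain=0.01))
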