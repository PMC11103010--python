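"""Low-level digital-topology kernels (numba).

All kernels operate on uint8 volumes padded with one background layer, so
3x3x3 neighborhoods never leave the array. Conventions: 26-connectivity for
foreground, 6-connectivity for background (the standard Jordan pair).

A voxel is *simple* iff removing it preserves topology, characterized by the
two topological numbers being 1: the number of 26-components of the
foreground punctured neighborhood, and the number of 6-components of the
background within the 18-neighborhood that are face-adjacent to the voxel.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def _build_tables():
    off = np.array(
        [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ],
        dtype=np.int8,
    )
    adj26 = np.zeros((26, 26), np.bool_)
    adj6 = np.zeros((26, 26), np.bool_)
    for i in range(26):
        for j in range(26):
            if i == j:
                continue
            d = np.abs(off[i] - off[j])
            if d.max() <= 1:
                adj26[i, j] = True
            if d.sum() == 1:
                adj6[i, j] = True
    man = np.abs(off).sum(axis=1)
    return off, adj26, adj6, (man <= 2), (man == 1)


OFF26, ADJ26, ADJ6, IS18, ISFACE = _build_tables()


@njit(cache=True)
def _components(mask, adj, comp):
    """Label connected components among True entries of a 26-slot mask."""
    for i in range(26):
        comp[i] = -1
    ncomp = 0
    stack = np.empty(26, np.int64)
    for s in range(26):
        if mask[s] and comp[s] < 0:
            comp[s] = ncomp
            top = 1
            stack[0] = s
            while top > 0:
                top -= 1
                u = stack[top]
                for v in range(26):
                    if mask[v] and comp[v] < 0 and adj[u, v]:
                        comp[v] = ncomp
                        stack[top] = v
                        top += 1
            ncomp += 1
    return ncomp


@njit(cache=True)
def _gather(vol, x, y, z, fg):
    n = 0
    for i in range(26):
        v = vol[x + OFF26[i, 0], y + OFF26[i, 1], z + OFF26[i, 2]] != 0
        fg[i] = v
        if v:
            n += 1
    return n


@njit(cache=True)
def _t6_background(fg, comp):
    """6-components of background within N18 that touch a face neighbor."""
    bg18 = np.zeros(26, np.bool_)
    for i in range(26):
        bg18[i] = (not fg[i]) and IS18[i]
    ncomp = _components(bg18, ADJ6, comp)
    cnt = 0
    for c in range(ncomp):
        hit = False
        for i in range(26):
            if bg18[i] and ISFACE[i] and comp[i] == c:
                hit = True
        if hit:
            cnt += 1
    return cnt


@njit(cache=True)
def _is_simple(vol, x, y, z, fg, comp):
    n = _gather(vol, x, y, z, fg)
    if n == 0:
        return False
    t26 = _components(fg, ADJ26, comp)
    if t26 != 1:
        return False
    return _t6_background(fg, comp) == 1


@njit(cache=True)
def _thin_sheet(vol, x, y, z):
    """Locally one-voxel-thick along some axis (both face neighbors background).

    Evaluated against the frozen pre-sub-iteration state: sheets and 1-wide
    ribbons present when a peel starts are retained, while thin configurations
    that only appear transiently during the sequential sweep are not, which
    prevents fin artifacts from freezing on thick rods.
    """
    if vol[x - 1, y, z] == 0 and vol[x + 1, y, z] == 0:
        return True
    if vol[x, y - 1, z] == 0 and vol[x, y + 1, z] == 0:
        return True
    if vol[x, y, z - 1] == 0 and vol[x, y, z + 1] == 0:
        return True
    return False


@njit(cache=True)
def _thin_pass(vol, pre, cand):
    """Sequentially delete still-simple, unprotected candidates (lex order).

    ``pre`` is the frozen pre-sub-iteration state used for the sheet
    retention rule; curve ends and simplicity are judged on the live state.
    """
    fg = np.zeros(26, np.bool_)
    comp = np.empty(26, np.int64)
    removed = 0
    for i in range(cand.shape[0]):
        x, y, z = cand[i, 0], cand[i, 1], cand[i, 2]
        if vol[x, y, z] == 0:
            continue
        if _thin_sheet(pre, x, y, z):
            continue
        n = _gather(vol, x, y, z, fg)
        if n <= 1:  # isolated (non-simple) or protected curve end
            continue
        if _components(fg, ADJ26, comp) != 1:
            continue
        if _t6_background(fg, comp) != 1:
            continue
        vol[x, y, z] = 0
        removed += 1
    return removed


@njit(cache=True)
def _relaxed_pass(vol, protected, cand):
    """Peel with sheet retention restricted to a frozen protected mask.

    Used for the slender-plane reduction: ``protected`` marks sheet-interior
    voxels (eta >= 2) on the iteration-start state, so ribbons and fins
    collapse onto curves while wide sheets lose at most one rim ring per
    iteration. Curve ends are kept; only simple points are deleted.
    """
    fg = np.zeros(26, np.bool_)
    comp = np.empty(26, np.int64)
    removed = 0
    for i in range(cand.shape[0]):
        x, y, z = cand[i, 0], cand[i, 1], cand[i, 2]
        if vol[x, y, z] == 0 or protected[x, y, z]:
            continue
        n = _gather(vol, x, y, z, fg)
        if n <= 1:
            continue
        if _components(fg, ADJ26, comp) != 1:
            continue
        if _t6_background(fg, comp) != 1:
            continue
        vol[x, y, z] = 0
        removed += 1
    return removed


@njit(cache=True)
def _curve_pass(vol, cand):
    """Curve-style peel: only curve ends retained (no sheet protection).

    Used to collapse slender surface components onto their center curves; the
    candidate list restricts removal to those components, the rest of the
    skeleton is frozen by omission.
    """
    fg = np.zeros(26, np.bool_)
    comp = np.empty(26, np.int64)
    removed = 0
    for i in range(cand.shape[0]):
        x, y, z = cand[i, 0], cand[i, 1], cand[i, 2]
        if vol[x, y, z] == 0:
            continue
        n = _gather(vol, x, y, z, fg)
        if n <= 1:
            continue
        if _components(fg, ADJ26, comp) != 1:
            continue
        if _t6_background(fg, comp) != 1:
            continue
        vol[x, y, z] = 0
        removed += 1
    return removed


@njit(cache=True)
def _features(vol, coords, out):
    """Per-voxel (n, xi6, eta): neighbor count, 6-components of the foreground
    punctured neighborhood (branch count), background topological number."""
    fg = np.zeros(26, np.bool_)
    comp = np.empty(26, np.int64)
    for i in range(coords.shape[0]):
        x, y, z = coords[i, 0], coords[i, 1], coords[i, 2]
        n = _gather(vol, x, y, z, fg)
        out[i, 0] = n
        out[i, 1] = _components(fg, ADJ6, comp)
        out[i, 2] = _t6_background(fg, comp)


@njit(cache=True)
def _simple_flags(vol, coords, out):
    fg = np.zeros(26, np.bool_)
    comp = np.empty(26, np.int64)
    for i in range(coords.shape[0]):
        out[i] = _is_simple(vol, coords[i, 0], coords[i, 1], coords[i, 2], fg, comp)
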