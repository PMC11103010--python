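"""Decomposition of a classified skeleton into labeled plate and rod elements.

Pipeline (after thinning + classification): slender surface components are
reclassified to rods within a fixed erosion budget, short arcs are pruned,
junction neighborhoods are removed to separate individual elements, the
surviving components are labeled (rods odd, plates even), and the labels are
grown back over the original foreground geometry by constrained dilation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .skeleton import (
    ClassifiedSkeleton,
    VoxelClass,
    classify,
)
from .volume import BinaryVolume

__all__ = [
    "DecomposeParams",
    "LabeledSkeleton",
    "ElementMap",
    "reduce_slender_plates",
    "prune_short_rods",
    "split_and_label",
    "remap",
    "decompose",
]

_STRUCT26 = np.ones((3, 3, 3), bool)
_BIG = np.iinfo(np.int32).max


@dataclass
class DecomposeParams:
    """Plate-rod decomposition parameters (all in voxels)."""

    slender_plate_iterations: int = 2
    min_rod_length: int = 4
    junction_radius: float = 2.0

    def __post_init__(self) -> None:
        if min(self.slender_plate_iterations, self.min_rod_length) < 0:
            raise ValueError("parameters must be >= 0")
        if self.junction_radius < 0:
            raise ValueError("junction_radius must be >= 0")


@dataclass
class LabeledSkeleton:
    """Skeleton split at junctions, one positive label per element candidate."""

    labels: np.ndarray  # int32; 0 = background
    kinds: dict[int, str]  # label -> "rod" | "plate"
    spacing: float


@dataclass
class ElementMap:
    """Element labels over the original foreground plus the element table.

    Rods carry odd ids and plates even ids; labels partition the assigned
    foreground. ``unassigned`` counts foreground voxels unreachable from any
    skeleton label.
    """

    labels: np.ndarray  # int32 over the original grid
    table: pd.DataFrame  # id, type, voxels, skeleton_voxels, touches_proximal/distal
    spacing: float
    unassigned: int = 0

    @property
    def ids(self) -> list[int]:
        return [int(i) for i in self.table["id"]]

    def kind(self, label: int) -> str:
        return "rod" if label % 2 == 1 else "plate"

    def voxels_of(self, label: int) -> int:
        row = self.table.loc[self.table["id"] == label]
        return int(row["voxels"].iloc[0])


def _surface_interior_count(mask: np.ndarray) -> np.ndarray:
    """Boolean mask of voxels with a locally two-sided background (eta == 2),
    i.e. sheet-interior voxels of ``mask`` viewed in isolation."""
    from . import _topo

    coords = np.argwhere(mask)
    if coords.size == 0:
        return np.zeros_like(mask)
    vol = np.pad(mask.astype(np.uint8), 1)
    feats = np.empty((coords.shape[0], 3), np.int64)
    _topo._features(vol, coords + 1, feats)
    out = np.zeros_like(mask)
    out[tuple(coords[feats[:, 2] == 2].T)] = True
    return out


def reduce_slender_plates(cs: ClassifiedSkeleton, p: DecomposeParams) -> ClassifiedSkeleton:
    """Reduce slender surface components (ribbons, fins) to rods.

    Runs ``slender_plate_iterations`` relaxed thinning iterations in which
    only sheet-interior voxels (eta >= 2, frozen at the iteration start) and
    curve ends are retained; only simple points are deleted, so topology is
    preserved. Ribbons and fin pairs up to roughly 2x the budget in width
    collapse onto their center curves and classify as arcs; wide plates
    lose at most one rim ring per iteration and keep their surface class.
    """
    if p.slender_plate_iterations == 0:
        return cs
    from . import _topo

    vol = np.pad(cs.skeleton.data.astype(np.uint8), 1)
    dirs = [(0, 0, -1), (0, 0, 1), (0, -1, 0), (0, 1, 0), (-1, 0, 0), (1, 0, 0)]
    for _ in range(p.slender_plate_iterations):
        protected = np.pad(_surface_interior_count(vol[1:-1, 1:-1, 1:-1] > 0), 1)
        removed = 0
        for dx, dy, dz in dirs:
            border = (vol == 1) & (np.roll(vol, (-dx, -dy, -dz), (0, 1, 2)) == 0)
            cand = np.argwhere(border)
            if cand.size:
                removed += _topo._relaxed_pass(vol, protected, cand)
        if removed == 0:
            break
    new_skel = BinaryVolume(vol[1:-1, 1:-1, 1:-1].astype(bool), cs.skeleton.spacing)
    forced = cs.forced_arc
    if forced is not None:
        forced = forced & new_skel.data
    return classify(new_skel, forced_arc=forced)


def prune_short_rods(cs: ClassifiedSkeleton, p: DecomposeParams) -> ClassifiedSkeleton:
    """Delete maximal arc segments shorter than ``min_rod_length`` voxels.

    A maximal segment is a 26-component of arc/arc-end voxels (junction and
    surface voxels delimit segments and are untouched). Deletion can
    disconnect structures; that is observable downstream in the graph.
    """
    seg = cs.mask(VoxelClass.ARC, VoxelClass.ARC_END)
    lab, n = ndimage.label(seg, structure=_STRUCT26)
    if n == 0:
        return cs
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    kill = np.isin(lab, np.where(sizes < p.min_rod_length)[0] + 1)
    if not kill.any():
        return cs
    new_skel = BinaryVolume(cs.skeleton.data & ~kill, cs.skeleton.spacing)
    forced = cs.forced_arc
    if forced is not None:
        forced = forced & new_skel.data
    return classify(new_skel, forced_arc=forced)


def split_and_label(cs: ClassifiedSkeleton, p: DecomposeParams) -> LabeledSkeleton:
    """Separate elements by removing junction neighborhoods, then label.

    All skeleton voxels within Euclidean distance ``junction_radius`` of an
    intersection-class voxel are removed; the surviving 26-components are
    labeled in deterministic scan order — arc-majority components get the
    next odd id (rod), surface-majority the next even id (plate), ties type
    as rod.
    """
    skel = cs.skeleton.data
    inter = cs.intersections
    if inter.any():
        dist = ndimage.distance_transform_edt(~inter)
        keep = skel & (dist > p.junction_radius)
    else:
        keep = skel.copy()
    comp, n = ndimage.label(keep, structure=_STRUCT26)
    arcish = cs.mask(VoxelClass.ARC, VoxelClass.ARC_END, VoxelClass.ISOLATED)
    labels = np.zeros(skel.shape, np.int32)
    kinds: dict[int, str] = {}
    next_odd, next_even = 1, 2
    # ndimage.label ids are already assigned in scan order
    arc_counts = ndimage.sum_labels(arcish, comp, index=np.arange(1, n + 1))
    tot_counts = ndimage.sum_labels(keep, comp, index=np.arange(1, n + 1))
    for i in range(1, n + 1):
        if tot_counts[i - 1] < p.min_rod_length:
            # junction-region debris, not a credible element; left unlabeled
            # so the remap absorbs its volume into the neighboring elements
            continue
        a = arc_counts[i - 1]
        s = tot_counts[i - 1] - a
        if a >= s:  # tie types as rod
            new_id = next_odd
            next_odd += 2
            kinds[new_id] = "rod"
        else:
            new_id = next_even
            next_even += 2
            kinds[new_id] = "plate"
        labels[comp == i] = new_id
    return LabeledSkeleton(labels, kinds, cs.skeleton.spacing)


def _shifted(a: np.ndarray, off: tuple[int, int, int], fill=0) -> np.ndarray:
    """a shifted so that out[p] = a[p + off], zero-filled at the boundary."""
    out = np.full_like(a, fill)
    src = []
    dst = []
    for o, n in zip(off, a.shape):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _offset_groups():
    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    faces = [o for o in offs if sum(map(abs, o)) == 1]
    edges = [o for o in offs if sum(map(abs, o)) == 2]
    corners = [o for o in offs if sum(map(abs, o)) == 3]
    return faces, edges, corners


_GROUPS = _offset_groups()


def remap(ls: LabeledSkeleton, original: BinaryVolume) -> ElementMap:
    """Grow skeleton labels back over the original foreground geometry.

    Iterative constrained dilation: each round, every unlabeled foreground
    voxel 26-adjacent to a labeled voxel takes the label of its nearest
    labeled voxel. The nearest labeled voxel of a frontier voxel is always
    one of its 26-neighbors (any non-neighbor is at distance >= 2 > sqrt(3)),
    so the rule reduces to: nearest labeled neighbor, face before edge before
    corner, ties broken toward the smallest label id. Rounds repeat until no
    voxel changes; foreground unreachable from any label stays 0.
    """
    if np.any((ls.labels > 0) & ~original.data):
        raise ValueError("labeled skeleton must be a subset of the original foreground")
    fg = original.data
    lab = ls.labels.astype(np.int32).copy()
    if not (lab > 0).any():
        if fg.any():
            warnings.warn("remap: no labels to grow; returning all-zero map")
        return _element_map(lab, ls, original, unassigned=int(fg.sum()))
    while True:
        base = lab.copy()
        claimed = np.zeros(lab.shape, bool)
        changed = False
        for group in _GROUPS:
            cand = np.full(lab.shape, _BIG, np.int64)
            for off in group:
                s = _shifted(base, off)
                cand = np.minimum(cand, np.where(s > 0, s, _BIG))
            sel = (lab == 0) & fg & ~claimed & (cand < _BIG)
            if sel.any():
                lab[sel] = cand[sel]
                claimed |= sel
                changed = True
        if not changed:
            break
    unassigned = int(np.count_nonzero(fg & (lab == 0)))
    return _element_map(lab, ls, original, unassigned)


def _element_map(
    lab: np.ndarray, ls: LabeledSkeleton, original: BinaryVolume, unassigned: int
) -> ElementMap:
    zs = np.where(original.data.any(axis=(0, 1)))[0]
    z_min, z_max = (int(zs[0]), int(zs[-1])) if len(zs) else (0, 0)
    rows = []
    for i in sorted(ls.kinds):
        vox = lab == i
        count = int(vox.sum())
        if count == 0:
            continue
        rows.append(
            {
                "id": i,
                "type": ls.kinds[i],
                "voxels": count,
                "skeleton_voxels": int((ls.labels == i).sum()),
                "touches_proximal": bool(vox[:, :, z_min].any()),
                "touches_distal": bool(vox[:, :, z_max].any()),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "id",
            "type",
            "voxels",
            "skeleton_voxels",
            "touches_proximal",
            "touches_distal",
        ],
    )
    return ElementMap(lab, table, original.spacing, unassigned)


def decompose(
    b: BinaryVolume, params: DecomposeParams | None = None
) -> tuple[ElementMap, ClassifiedSkeleton]:
    """Full decomposition chain from a binary volume to an ElementMap."""
    from .skeleton import thin

    params = params or DecomposeParams()
    cs = classify(thin(b))
    cs = reduce_slender_plates(cs, params)
    cs = prune_short_rods(cs, params)
    ls = split_and_label(cs, params)
    return remap(ls, b), cs
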