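"""Synthetic trabecular specimens built from parametric plates and rods.

The generator produces structurally controllable test objects — horizontal
plate "decks" connected by vertical rod "columns", optionally braced by
oblique rods — together with per-primitive ground-truth labels. A step-wise
reduction (concentric re-coring, distal cutting) emulates specimen
preparation of excised cylinders: primitives crossing the new boundary are
truncated, which is the mechanism that introduces side artifacts (peripheral
elements losing their network connections at the cut interface).

These phantoms are test objects, not statistically realistic bone: they have
controllable connectivity, not realistic fabric or thickness distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .volume import BinaryVolume, DensityVolume, SpecimenMask, cylinder_mask, full_mask

__all__ = [
    "Rod",
    "Plate",
    "PhantomSpec",
    "ReductionStep",
    "GroundTruth",
    "generate",
    "vertical_lattice",
    "reduce",
]

#: density assigned inside primitives / background, mg HA/cm^3.
#: 1200 clears the 800 segmentation threshold with a wide margin so the
#: phantom exercises the real preprocessing chain.
FOREGROUND_DENSITY = 1200.0
BACKGROUND_DENSITY = 0.0


@dataclass
class Rod:
    """Cylindrical strut between two points (voxel coordinates), radius in voxels."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius < 1.0:
            raise ValueError("rod radius must be >= 1 voxel")


@dataclass
class Plate:
    """Axis-aligned slab: thin along ``normal``, extended in-plane.

    In-plane extent is either a disc of ``radius`` voxels or a rectangle of
    ``half_extents`` voxels around ``center``.
    """

    center: tuple[float, float, float]
    thickness: float  # voxels, along the normal
    normal: int = 2
    radius: float | None = None
    half_extents: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.thickness < 1.0:
            raise ValueError("plate thickness must be >= 1 voxel")
        if self.normal not in (0, 1, 2):
            raise ValueError("normal must be an axis index")
        if (self.radius is None) == (self.half_extents is None):
            raise ValueError("give exactly one of radius / half_extents")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int]
    spacing: float  # um
    primitives: list = field(default_factory=list)
    noise_sd: float = 0.0  # density units
    seed: int = 0
    specimen_diameter: float | None = None  # mm; None -> rectangular TV mask
    specimen_length: float | None = None  # mm

    def to_json(self) -> str:
        def enc(p):
            if isinstance(p, Rod):
                return {"kind": "rod", "p0": list(p.p0), "p1": list(p.p1), "radius": p.radius}
            return {
                "kind": "plate",
                "center": list(p.center),
                "thickness": p.thickness,
                "normal": p.normal,
                "radius": p.radius,
                "half_extents": list(p.half_extents) if p.half_extents else None,
            }

        return json.dumps(
            {
                "shape": list(self.shape),
                "spacing_um": self.spacing,
                "primitives": [enc(p) for p in self.primitives],
                "noise_sd": self.noise_sd,
                "seed": self.seed,
                "specimen_diameter_mm": self.specimen_diameter,
                "specimen_length_mm": self.specimen_length,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        prims = []
        for p in d["primitives"]:
            if p["kind"] == "rod":
                prims.append(Rod(tuple(p["p0"]), tuple(p["p1"]), p["radius"]))
            else:
                he = tuple(p["half_extents"]) if p.get("half_extents") else None
                prims.append(
                    Plate(tuple(p["center"]), p["thickness"], p["normal"], p.get("radius"), he)
                )
        return cls(
            tuple(d["shape"]),
            d["spacing_um"],
            prims,
            d.get("noise_sd", 0.0),
            d.get("seed", 0),
            d.get("specimen_diameter_mm"),
            d.get("specimen_length_mm"),
        )


@dataclass
class ReductionStep:
    """One step of specimen reduction: re-core to a smaller diameter or cut length."""

    kind: str  # "core" | "cut"
    new_diameter: float | None = None  # mm
    new_length: float | None = None  # mm

    def __post_init__(self) -> None:
        if self.kind not in ("core", "cut"):
            raise ValueError("kind must be 'core' or 'cut'")
        if self.kind == "core" and self.new_diameter is None:
            raise ValueError("core step needs new_diameter")
        if self.kind == "cut" and self.new_length is None:
            raise ValueError("cut step needs new_length")


@dataclass
class GroundTruth:
    """Per-primitive voxel labels (1-based, in primitive order).

    Overlapping voxels carry the lower primitive id; ``overlaps`` lists the
    (id_a, id_b, voxel_count) of every merged pair so tests can exclude them.
    """

    labels: np.ndarray
    kinds: dict[int, str]  # id -> "rod" | "plate"
    overlaps: list[tuple[int, int, int]]

    @property
    def n_primitives(self) -> int:
        return len(self.kinds)

    def ids_of_kind(self, kind: str) -> list[int]:
        return [i for i, k in self.kinds.items() if k == kind]


def _rasterize(prim, shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = shape
    xi = np.arange(nx, dtype=np.float64)
    yi = np.arange(ny, dtype=np.float64)
    zi = np.arange(nz, dtype=np.float64)
    if isinstance(prim, Rod):
        p0 = np.asarray(prim.p0, float)
        p1 = np.asarray(prim.p1, float)
        d = p1 - p0
        L2 = float(d @ d)
        X, Y, Z = np.meshgrid(xi, yi, zi, indexing="ij")
        P = np.stack([X, Y, Z], axis=-1) - p0
        if L2 == 0:
            dist2 = np.sum(P**2, axis=-1)
        else:
            t = np.clip(P @ d / L2, 0.0, 1.0)
            dist2 = np.sum((P - t[..., None] * d) ** 2, axis=-1)
        return dist2 <= prim.radius**2
    # plate
    ax = prim.normal
    axes = [0, 1, 2]
    axes.remove(ax)
    coords = [xi, yi, zi]
    slab = np.abs(coords[ax] - prim.center[ax]) <= prim.thickness / 2.0
    u = coords[axes[0]] - prim.center[axes[0]]
    v = coords[axes[1]] - prim.center[axes[1]]
    if prim.radius is not None:
        inplane = u[:, None] ** 2 + v[None, :] ** 2 <= prim.radius**2
    else:
        a, b = prim.half_extents
        inplane = (np.abs(u)[:, None] <= a) & (np.abs(v)[None, :] <= b)
    # broadcast the slab along its normal and the in-plane mask across it
    full = np.einsum(
        "i,jk->ijk" if ax == 0 else ("j,ik->ijk" if ax == 1 else "k,ij->ijk"),
        slab.astype(bool),
        inplane.astype(bool),
    )
    return full.astype(bool)


def generate(spec: PhantomSpec) -> tuple[DensityVolume, SpecimenMask, GroundTruth]:
    """Rasterize a phantom: density volume, TV mask and ground-truth labels.

    Deterministic under a fixed seed; changing only the seed changes only the
    additive noise, never the geometry.
    """
    for p in spec.primitives:
        _check_inside(p, spec.shape)
    labels = np.zeros(spec.shape, np.int32)
    kinds: dict[int, str] = {}
    overlap_counts: dict[tuple[int, int], int] = {}
    for pid, prim in enumerate(spec.primitives, start=1):
        mask = _rasterize(prim, spec.shape)
        kinds[pid] = "rod" if isinstance(prim, Rod) else "plate"
        taken = labels > 0
        both = mask & taken
        if both.any():
            for other in np.unique(labels[both]):
                key = (int(other), pid)
                overlap_counts[key] = overlap_counts.get(key, 0) + int(
                    np.count_nonzero(both & (labels == other))
                )
        labels[mask & ~taken] = pid  # lower id wins on overlap
    density = np.where(labels > 0, FOREGROUND_DENSITY, BACKGROUND_DENSITY)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        density = density + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vol = DensityVolume(density, spec.spacing)
    if spec.specimen_diameter is not None:
        length = spec.specimen_length
        if length is None:
            length = spec.shape[2] * spec.spacing / 1000.0
        mask = cylinder_mask(spec.shape, spec.spacing, spec.specimen_diameter, length)
    else:
        mask = full_mask(spec.shape, spec.spacing)
    truth = GroundTruth(
        labels, kinds, [(a, b, n) for (a, b), n in sorted(overlap_counts.items())]
    )
    return vol, mask, truth


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 3D segments."""
    p0, p1, q0, q1 = (np.asarray(v, float) for v in (p0, p1, q0, q1))
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # refine s for the clamped t
    if a > 1e-12:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    return float(np.linalg.norm(p0 + s * u - (q0 + t * v)))


def _check_inside(prim, shape) -> None:
    lo = np.zeros(3)
    hi = np.asarray(shape, float) - 1
    if isinstance(prim, Rod):
        # endpoints must lie in the grid; the radius may clip at the border
        pts = np.asarray([prim.p0, prim.p1], float)
        if np.any(pts < lo - 0.5) or np.any(pts > hi + 0.5):
            raise ValueError("rod extends outside the grid")
    else:
        c = np.asarray(prim.center, float)
        if np.any(c < lo) or np.any(c > hi):
            raise ValueError("plate center outside the grid")


def vertical_lattice(
    n_columns: int,
    n_decks: int,
    rod_radius: float = 2.2,
    plate_thickness: float = 3.0,
    grid: tuple[int, int, int] = (48, 48, 48),
    spacing: float = 200.0,
    seed: int = 0,
    *,
    n_braces: int = 0,
    n_dangling: int = 0,
    specimen_diameter: float | None = None,
    z_margin: float = 3.0,
    protrude: float = 0.0,
) -> PhantomSpec:
    """Canonical test structure: horizontal plate decks joined by vertical columns.

    Produces ``n_decks`` plates and ``n_columns * (n_decks - 1)`` rods. Columns
    sit on a fixed angular grid spanning the cross-section, including
    peripheral positions, so that re-coring severs a predictable subset.
    Optional oblique ``n_braces`` rods per deck gap run from an interior point
    on one deck to a peripheral point on the next; coring truncates them
    mid-span, leaving dangling stubs (the side-artifact mechanism).

    ``n_dangling`` adds per deck gap that many rods attached to one deck
    only (terminating mid-gap): weakly connected elements that contribute
    bone volume but carry no load, as trabeculae with disrupted connectivity
    do. ``protrude`` extends the columns past the outer decks by that many
    voxels, so the loading surfaces expose individual column tips (like the
    cut faces of an excised specimen) instead of a monolithic deck — only
    tips under the plunger footprint then act as flow sources.
    """
    if n_columns < 1 or n_decks < 2:
        raise ValueError("need n_columns >= 1 and n_decks >= 2")
    nx, ny, nz = grid
    rng = np.random.default_rng(seed)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    if specimen_diameter is not None:
        R = specimen_diameter * 1000.0 / spacing / 2.0
    else:
        R = min(nx, ny) / 2.0 - 1.0
    deck_r = R - 1.0
    z_lo, z_hi = z_margin, nz - 1 - z_margin
    deck_z = np.linspace(z_lo, z_hi, n_decks)
    gap = (deck_z[1] - deck_z[0]) - plate_thickness
    if gap < 6:
        raise ValueError("deck gap too small for distinct rods; enlarge grid or reduce decks")
    prims: list = []
    for z in deck_z:
        prims.append(Plate((cx, cy, float(z)), plate_thickness, normal=2, radius=deck_r))
    # columns: fixed angular grid, radii spread over the cross-section
    # (peripheral positions included); global rotation is the only seeded part.
    rot = rng.uniform(0, 2 * np.pi)
    margin = rod_radius + 1.0
    col_xy = []
    for k in range(n_columns):
        # one column on the axis, the rest on a peripheral ring. The ring
        # leaves clear annular windows inside and outside it, so a re-coring
        # circle can remove the ring wholly instead of slicing columns into
        # slivers, and the junction holes punched into the decks can never
        # surround and isolate a deck region.
        if n_columns == 1 or k > 0:
            r = 0.68 * (deck_r - margin)
            n_ring = max(n_columns - 1, 1)
            ang = rot + 2 * np.pi * (k - (n_columns > 1)) / n_ring
        else:
            r = 0.0
            ang = 0.0
        x, y = cx + r * np.cos(ang), cy + r * np.sin(ang)
        col_xy.append((x, y))
        for d in range(n_decks - 1):
            z0 = float(deck_z[d]) - (protrude if d == 0 else 0.0)
            z1 = float(deck_z[d + 1]) + (protrude if d == n_decks - 2 else 0.0)
            prims.append(Rod((x, y, z0), (x, y, z1), rod_radius))
    # Anchored extras (brace roots, dangling rods) attach to the deck nearest
    # the specimen middle, so a severed remnant can never reach a loading
    # surface through an outer deck. Around every strut-deck attachment the
    # label regrowth claims a cone roughly junction_radius + strut radius
    # wide; anchor points closer than that to another attachment end up in
    # sub-scale contact with it, so anchors keep a lateral root clearance.
    root_clearance = 2 * rod_radius + 4.1
    mid_idx = (n_decks - 1) / 2.0
    roots = list(col_xy)

    def root_clear(x: float, y: float) -> bool:
        return all(np.hypot(x - rx, y - ry) >= root_clearance for rx, ry in roots)

    for d in range(n_decks - 1):
        inner = d if abs(d - mid_idx) <= abs(d + 1 - mid_idx) else d + 1
        outer = d + 1 if inner == d else d
        for _ in range(n_braces):
            # oblique strut from a mid-radius anchor on the inner deck to the
            # periphery of the outer deck; re-coring severs it there, and the
            # clearances make the remnant a genuine dangling stub
            for _try in range(60):
                a0 = rng.uniform(0, 2 * np.pi)
                # radial band clear of the axial column; the angular windows
                # between ring columns provide the rest of the clearance
                r0 = rng.uniform(0.64, 0.74) * (deck_r - margin)
                x0, y0 = cx + r0 * np.cos(a0), cy + r0 * np.sin(a0)
                if not root_clear(x0, y0):
                    continue
                a1 = a0 + rng.uniform(-0.5, 0.5)
                r1 = deck_r - margin  # peripheral attachment, severed by coring
                p0 = (x0, y0, float(deck_z[inner]))
                p1 = (cx + r1 * np.cos(a1), cy + r1 * np.sin(a1), float(deck_z[outer]))
                cand = Rod(p0, p1, rod_radius)
                if all(
                    not isinstance(o, Rod)
                    or _segment_distance(cand.p0, cand.p1, o.p0, o.p1)
                    >= cand.radius + o.radius + 3.0
                    for o in prims
                ):
                    prims.append(cand)
                    roots.append((x0, y0))
                    break
        for _ in range(n_dangling):
            # dangling rod: hangs from the inner deck into the gap, free end
            # mid-gap — bone volume with no load path (a broken trabecula);
            # long enough to survive junction removal and short-rod pruning
            for _try in range(120):
                a = rng.uniform(0, 2 * np.pi)
                r = rng.uniform(0.40, 0.80) * (deck_r - margin)
                x, y = cx + r * np.cos(a), cy + r * np.sin(a)
                if not root_clear(x, y):
                    continue
                frac = rng.uniform(0.55, 0.70)
                gapz = deck_z[d + 1] - deck_z[d]
                if inner == d:
                    z0, z1 = float(deck_z[d]), float(deck_z[d] + frac * gapz)
                else:
                    z0, z1 = float(deck_z[d + 1] - frac * gapz), float(deck_z[d + 1])
                cand = Rod((x, y, z0), (x, y, z1), rod_radius)
                if all(
                    not isinstance(o, Rod)
                    or _segment_distance(cand.p0, cand.p1, o.p0, o.p1)
                    >= cand.radius + o.radius + 3.0
                    for o in prims
                ):
                    prims.append(cand)
                    roots.append((x, y))
                    break
    return PhantomSpec(
        shape=grid,
        spacing=spacing,
        primitives=prims,
        seed=seed,
        specimen_diameter=specimen_diameter
        if specimen_diameter is not None
        else 2 * R * spacing / 1000.0,
    )


def reduce(
    v: DensityVolume | BinaryVolume,
    mask: SpecimenMask,
    step: ReductionStep,
    truth: GroundTruth | None = None,
):
    """Apply one reduction step; material outside the new boundary is removed.

    Re-coring to the full current diameter is the identity; enlarging is an
    error. Elements crossing the new boundary are truncated, which severs
    their network connections at the interface.
    """
    spacing = v.spacing
    shape = v.data.shape
    zs = np.where(mask.data.any(axis=(0, 1)))[0]
    if len(zs) == 0:
        raise ValueError("mask is empty")
    z0 = int(zs[0])
    cur_len = mask.length
    if cur_len is None:
        cur_len = (zs[-1] - zs[0] + 1) * spacing / 1000.0
    if step.kind == "core":
        cur_d = mask.diameter
        if cur_d is not None and step.new_diameter > cur_d + 1e-9:
            raise ValueError("core step must not enlarge the specimen")
        new_mask = cylinder_mask(
            shape, spacing, step.new_diameter, cur_len, proximal_offset=z0
        )
    else:
        if step.new_length > cur_len + 1e-9:
            raise ValueError("cut step must not lengthen the specimen")
        keep = np.zeros(shape, bool)
        n_keep = int(round(step.new_length * 1000.0 / spacing))
        keep[:, :, z0 : z0 + n_keep] = True
        new_data = mask.data & keep
        new_mask = SpecimenMask(new_data, spacing, mask.diameter, step.new_length)
    kept = new_mask.data
    if isinstance(v, BinaryVolume):
        out = BinaryVolume(v.data & kept, spacing)
    else:
        out = DensityVolume(np.where(kept, v.data, BACKGROUND_DENSITY), spacing)
    if truth is not None:
        labels = np.where(kept, truth.labels, 0).astype(truth.labels.dtype)
        truth = GroundTruth(labels, dict(truth.kinds), list(truth.overlaps))
        return out, new_mask, truth
    return out, new_mask
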