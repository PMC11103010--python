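# Methods

`prnet` decomposes a binary trabecular-bone volume into individually labeled
plate and rod elements, models their connectivity as a graph, identifies the
subset of elements that participate in load transfer between the loading
surfaces, and summarizes that subset as a connectivity-weighted bone volume
fraction. A desk-scale voxel finite-element model provides the mechanical
reference against which the network metric is evaluated on synthetic
phantoms. This note records the model, its assumptions, the parameters that
matter, and the places where the design was genuinely open.

## Pipeline

1. **Preprocessing** — Gaussian filtering (sigma 1.2 voxels, reflect
   boundary) of the density-calibrated grayscale volume, then inclusive
   thresholding at 800 mg HA/cm^3. The threshold tie rule (`>=`) is a
   convention; densities are continuous so it is observable only on
   constructed fixtures.
2. **Thinning** — iterative, topology-preserving peeling to a one-voxel
   surface/curve skeleton (below).
3. **Classification** — each skeleton voxel gets one of eight topological
   classes (surface, surface-end, arc, arc-end, arc-arc, arc-surface,
   surface-surface intersection, isolated).
4. **Decomposition** — slender surfaces are reduced to rods, arcs shorter
   than 4 voxels are removed, junction neighborhoods (Euclidean radius 2 of
   intersection voxels) are cut out, the remaining components are labeled
   (rods odd, plates even) and grown back over the original foreground.
5. **Network analysis** — elements are graph nodes; every touching pair
   (voxels 26-adjacent across labels, a two-voxel-thick junction surface)
   is an edge. Super-nodes s/t collect the elements on the proximal surface
   inside the plunger footprint and on the distal surface; maximum s-t flow
   and s-t path membership identify load-bearing elements; their volume
   over the mask volume is the weighted BV/TV.
6. **Micro-FE** — one trilinear hexahedral element per voxel, linear
   elastic, displacement-driven frictionless compression; von Mises stress
   at element centers and an apparent modulus from the reaction force.

## Digital topology

Foreground connectivity is 26, background 6 (the standard Jordan pair). A
voxel is *simple* iff both topological numbers are 1: one 26-component of
the punctured foreground neighborhood, and one 6-component of the
background within the 18-neighborhood touching a face neighbor. Thinning
deletes candidates sequentially (lexicographic order, re-checked at visit),
so the 26-component count and the Euler characteristic — computed
exactly on the cubical complex as vertices − edges + faces − cells — are
preserved by construction. The per-voxel kernels are numba-compiled; the
test suite recomputes the same quantities independently with
`scipy.ndimage` on extracted 3×3×3 neighborhoods.

**Retention rules.** Deleting every simple point yields a curve skeleton
and destroys plates, so two retentions make the result shape-preserving:
curve ends (exactly one neighbor) are kept, and voxels that are locally one
voxel thick along a grid axis (both face neighbors background) are kept.
The thickness rule is evaluated against the frozen pre-sub-iteration state:
evaluated live, transient one-voxel configurations arising mid-sweep freeze
into fin artifacts on thick rods; evaluated pre-state, sheets and existing
ribbons survive while fins erode. One iteration peels each of the six face
directions in turn.

**Slender-plane reduction.** Surface skeletons represent rods of
near-isotropic cross-section as narrow ribbons or fin pairs rather than
curves. Following the decomposition literature, two additional *relaxed*
thinning iterations run in which only sheet-interior voxels (background
topological number >= 2, frozen per iteration) and curve ends are retained.
Ribbons up to about five voxels wide collapse onto their center curves
within the budget; wide plates lose at most one rim ring per iteration and
keep their interior. A 9×9 one-voxel plane therefore remains
surface-classified, while a 3-voxel-wide ribbon becomes a rod.

**Classification.** Per voxel we use the neighbor count n, the number of
6-connected components of the punctured foreground neighborhood (the branch
count xi6), and the background topological number eta:

| rule (first match) | class |
|---|---|
| n = 0 | isolated |
| n = 1 | arc end |
| xi6 >= 3 | arc-arc intersection |
| eta >= 3 | surface-surface intersection |
| eta = 2 | surface |
| xi6 = 2 | arc |
| otherwise | surface end |

Branch counting deliberately uses 6-connectivity: under 26-adjacency the
arms of two crossing digital curves merge through diagonals and every
junction would be invisible. Arc-surface intersections cannot be read from
(xi6, eta) in a 3×3×3 neighborhood at all (the rod tail 26-merges with the
sheet), so they are found by a family-adjacency pass: where an arc branch
meets surface-family voxels, both sides become arc-surface intersections.
Only arc branches of at least 3 voxels count as the arc side — isolated
arc-classified voxels inside imperfectly thinned sheet regions would
otherwise convert whole deck patches into junctions and fragment plates.

## Decomposition details

* Rod length is the voxel count of a maximal arc segment (a 26-component of
  arc/arc-end voxels); segments shorter than 4 voxels are deleted, which can
  disconnect structure — deliberately observable in the graph stage.
* Junction removal deletes skeleton voxels within Euclidean distance 2 of
  any intersection voxel (Euclidean for isotropy; Chebyshev would remove
  more).
* Post-split components are typed by majority class (tie → rod) and labeled
  in scan order, rods odd / plates even. Components smaller than the
  4-voxel rod minimum are junction debris and stay unlabeled; the remap
  absorbs their volume into the neighboring elements.
* The remap grows labels over the original foreground in rounds. The
  nearest labeled voxel of any frontier voxel is necessarily one of its 26
  neighbors (everything else is at distance >= 2 > sqrt(3)), so the rule
  "take the label of the nearest labeled voxel, ties to the smallest id"
  reduces to a local comparison ordered face < edge < corner. This makes
  the remap deterministic and fully vectorizable. Foreground unreachable
  from any label stays 0 and is reported.

## Network model

Elements are nodes; this is the only reading under which a sparse adjacency
matrix of junctions and super-node attachment are coherent. Edges carry
unit capacity by default (the "unweighted" reading of the graph);
`capacity="area"` uses the junction voxel count for sensitivity studies.
Terminal edges get capacity one more than the total finite capacity —
never a bottleneck, hence effectively unbounded, but the flow value stays
finite even when one element spans both platens. Any max-flow algorithm is
acceptable; the implementation uses networkx and the tests pin the value to
exhaustive min-cut enumeration on small graphs.

Two load-bearing notions are exposed. `mode="flow"` flags elements with
positive throughput in the computed maximum flow; under unit capacities a
maximum flow may legitimately route around genuinely connected parallel
elements, so this set depends on the routing. `mode="reach"` flags elements
lying on at least one simple s-t path, computed exactly as membership in
the biconnected component of the graph-plus-st-edge that contains both
terminals (mere connected-component membership would count dangling
elements). The pipeline weights BV/TV with `reach`, because a volume
fraction should not depend on flow routing; `flow` remains the default of
`max_flow()` itself for path analysis.

Junction surfaces smaller than `min_contact` voxels (pipeline default 8,
about the cross-section of the thinnest resolvable strut) are dropped:
label regrowth around removed junction neighborhoods can bring two elements
into sub-strut-scale contact that the geometry does not support.

## Micro-FE model

Linear elastic, tissue modulus 15 GPa, Poisson 0.3, one 8-node trilinear
hexahedron per voxel (2×2×2 Gauss rule; the element matrix is symmetric
positive semidefinite with exactly six rigid modes and scales as E·h).
Compression is displacement driven: the axial displacement of proximal
surface nodes under the plunger footprint is prescribed to strain × length
(default 1%), the distal face is fixed axially, lateral motion is free
except minimal per-component pinning of the lateral rigid-body modes
(frictionless platens). Foreground components not 26-connected to both
loading faces cannot carry load and are removed before assembly (reported
via a warning). The system is assembled as a scipy CSR matrix and solved
with Jacobi-preconditioned conjugate gradients to a relative residual of
1e-8; at the desk scales the package targets (grids up to ~64^3,
≤ 300 000 elements) this is simpler than a matrix-free operator and fast.
Units: mm, GPa, kN internally; von Mises stress is reported in MPa.

The apparent modulus is (reaction force / nominal plunger area) / applied
strain. Note a consequence of the displacement-driven boundary conditions:
a plunger smaller than a *solid* specimen reads a **higher** apparent
modulus (flat-punch behavior — the surrounding material shears along with
the indented column), not a lower one. The familiar softening from
under-sized plungers is a property of porous structures losing peripheral
load paths, not of the continuum model.

## Synthetic phantoms

The generator rasterizes parametric primitives (capsule rods, axis-aligned
disc/rect plates) into density volumes (foreground 1200, background 0
mg HA/cm^3, optional Gaussian noise) with per-primitive ground-truth labels
(overlaps keep the lower id and are listed). Geometry is deterministic
given the seed; the seed changes only the noise and the randomized
placements.

The canonical test object is a deck-and-column lattice: horizontal plate
decks joined by vertical columns — one on the axis, the rest on a
peripheral ring. The ring layout is deliberate: junction removal punches
holes a few voxels wide into the deck sheets at every attachment, and
column positions must keep those holes from merging into cuts that isolate
deck regions; the ring also leaves clear annular windows so a re-coring
circle removes columns whole instead of slicing them into slivers.
Optional structures model disrupted connectivity: oblique *braces* from a
mid-radius anchor to the deck periphery (severed mid-span by re-coring,
leaving stubs attached at one end only) and *dangling rods* hanging from a
deck into a gap (bone volume with no load path from the start). Anchored
extras attach to the deck nearest the specimen middle and keep a lateral
root clearance of about twice the strut radius plus four voxels from every
other attachment, because label-regrowth cones around junctions put closer
attachments into spurious contact. Columns may protrude past the outer
decks so the loading surfaces expose individual tips, as the cut faces of
an excised specimen do.

The reduction protocol re-cores to a concentric smaller cylinder and/or
cuts distal slices; primitives crossing the new boundary are truncated,
which is the side-artifact mechanism under study.

What the phantoms do **not** emulate: realistic trabecular fabric,
thickness and spacing distributions, curvature, marrow-equivalent
background density, or imaging noise spectra. Passing tests show that the
pipeline's stages behave correctly on controllable geometry, not that its
outputs are accurate on scanned bone.

## The side-artifact experiment

Twenty randomized lattices (3 decks; 2–3 ring columns plus the axial one;
1–2 braces and up to 7 dangling rods per gap; 44^3 grid at 200 um — sizes
chosen so a full ensemble runs in minutes on one CPU) are each taken
through three nested stages: the full specimen, a re-coring to 69% of the
diameter that truncates the braces, and a deep re-coring to 28% that also
removes the column ring; the plunger always matches the current diameter.
For every stage the pipeline computes plain and weighted BV/TV and the FE
model the apparent modulus; both predictors are regressed on the modulus
pooled across all phantoms and stages. Dangling structure inflates plain
BV/TV but neither the weighted BV/TV nor the stiffness, so the weighted
fraction is the better predictor — the reported comparison is this
directional statement, plus the strict exclusion of interface-severed
elements from the load-bearing set. Stages of one phantom are pooled, so
the samples are not independent; the report flags this.

The voxel spacing of 200 um (rather than a scanner-like 30 um) keeps the
structures a few voxels wide, which is the regime in which decomposition
parameters (4-voxel rod minimum, radius-2 junctions) are meaningful at
desk-scale grid sizes.

## Numerical choices and degenerate inputs

* Thresholding is inclusive; smoothing with sigma 0 is the identity.
* Thinning of an empty volume is empty; a single voxel is kept (not
  simple); thinning is idempotent because every surviving voxel is either
  non-simple or retained by a rule evaluated on the stable state.
* ROC requires both classes; regression requires n >= 3 and a non-constant
  predictor; BV/TV requires a non-empty mask; FE requires non-empty
  foreground connecting both faces. Each is an explicit error.
* Flow with no sources or sinks is 0 with an empty load-bearing set.
* Zero applied strain is a valid degenerate compression (zero fields).

## Known limitations

* The eight-class characterization is an operational reconstruction from
  the cited digital-topology framework; junction classes on strongly bent
  or stair-cased sheets are heuristic, and the family-adjacency rule can
  over-mark junction neighborhoods on rough surfaces.
* Element identity is not tracked across reduction stages; stage-wise
  comparisons use ground-truth overlap instead.
* The FE model is linear, small-strain, single-material, and desk-scale
  only; no failure, no contact, no friction.
* The weighted BV/TV depends on decomposition quality; over-segmented
  junction regions can shift a few percent of volume between neighboring
  elements (they stay inside the load-bearing set, so the fraction is
  affected far less than the element table).
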