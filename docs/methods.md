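# Methods

This note documents the models, algorithms and numerical choices behind
`hepaq3d`, the assumptions built into its synthetic phantoms, and what the
passing test suite does and does not demonstrate about real tissue data.

## Data model and geometry

Volumes are 8-bit `(z, y, x)` grids with per-axis voxel spacing in μm;
every user-facing triple (spacing, kernel extents, crop bounds, seed
points) is `(x, y, z)`, with conversion centralized in `hepaq3d.core`.
Masks and label volumes share their source geometry. Morphological kernels
are per-axis voxel radii (`2k+1` voxels across); a radius-0 kernel is the
identity, which is how optional opening steps are skipped.

Kernel rescaling between acquisition set-ups follows the feature-relative
convention: `extent' = round(extent × new_spacing / ref_spacing)` per axis,
so a (2, 2, 1) kernel at 0.207 μm lateral spacing becomes (4, 4, 1) at
0.414 μm. Note this scales the kernel's *physical* size with the voxel
size — it keeps the kernel matched to how many voxels a feature spans, not
to an absolute physical extent, and is only appropriate while feature
appearance is comparable between set-ups.

## Pre-processing

CLAHE is fully volumetric: cuboidal windows are sampled every `step`
voxels per axis (plus the final index), each window yields a
clipped-histogram (256-bin) equalization mapping, and voxels blend the
mappings of the surrounding sample centres trilinearly, clamping to the
nearest mapping beyond the outer centres. The clip level is the fraction
of the window's voxel count used as the per-bin ceiling, with the clipped
excess redistributed uniformly; `clip = 1` disables clipping and reduces to
plain adaptive histogram equalization (verified against an independent
loop-based implementation to ±1 grey level). Whether mappings should be
blended or tiled is an open choice; blending was chosen for smoothness and
is part of this package's definition of the operation.

## Thresholding

The global Otsu threshold maximizes between-class variance over the 256-bin
histogram with the convention *voxel ≥ threshold ⇒ foreground*. The
variance is flat across empty histogram gaps; ties resolve to the middle of
the maximizing plateau, so a clean bimodal image thresholds mid-gap rather
than at the gap's lower edge.

The adaptive variant places `n_samples` cuboidal sample regions on a
uniform grid (per-axis jitter, seeded), computes a local Otsu value per
region, assigns it to the region centre and interpolates per-voxel
thresholds trilinearly (nearest beyond the outermost centres). A single
whole-volume sample region reduces exactly to the global threshold.
Caveat observed on the phantoms: sample regions that contain no stained
structure make Otsu split pure background noise and flood the candidate
mask. The defaults therefore use a whole-stack sample region for the small
(26 μm) phantom field; real, larger stacks with structure everywhere are
the intended use case for genuinely local sampling, and a manual threshold
is the documented fallback.

## Voting and cavity filling

The single-pass voting filter uses a box neighbourhood of per-axis radius
`r` (N = neighbourhood minus centre). Direct mode converts a background
voxel when its foreground neighbours number at least `⌈N/2⌉ + majority`;
inverse mode removes foreground symmetrically. Majorities are restricted
to 0–10; smaller values act more aggressively (at 0–1 they also shave
boundary voxels of large objects, matching the documented behaviour).
Direct voting never removes foreground; inverse voting never creates it.

Cavity filling is a *surround-coverage* rule: a background voxel is filled
when at least `min_foreground_fraction` of the 26 lattice directions
contain a foreground voxel within the per-axis radius, and the sweep
iterates to a fixpoint so an enclosed cavity floods outward from its
most-surrounded voxels. This realizes the operation's documented
phenomenology: a completely enclosed cavity fills at fractions up to 1,
while cavities open on one side (a tube lumen open along its axis, a hole
next to an unsegmented patch) need a lower fraction — ~0.7 fills sinusoid
lumina without bridging between nearby vessels. A voxel-volume-fraction
rule cannot reproduce this (the solid fraction around a hollow core's
centre never approaches 0.9), which is why coverage semantics was chosen.
The accelerated variant bounds rays by the box of the radius (cheapest,
slightly longer diagonal reach); the precise variant bounds them by the
inscribed ellipsoid and needs a slightly larger radius to bridge the same
lattice-diagonal gap.

Binary morphology uses ellipsoidal structuring elements in voxel units.
Border policy: erosion, dilation and opening treat the outside of the
stack as background (border-touching structures shrink under erosion);
the erosion half of a *closing* treats the outside as foreground so closing
never eats the stack faces. Objects are 26-connected, background and
cavities 6-connected.

## Structure pipelines

**Necrotic region** (DMs channel; DPPIV only for visualization):
threshold → erosion/dilation pair (noise removal and small-cavity closing,
dilation ≈ 2× erosion) → a second erosion slightly larger than the
sinusoid radius (erases the vessel network) with matching dilation →
volume filter. Interior holes are tolerated; only the boundary feeds the
distance measures.

**Veins**: the lumen is unstained, so candidates are voxels *below* the
per-channel thresholds in every provided channel (AND), opened (to detach
narrower dark vessels) and closed (to absorb intraluminal cells). Each
user seed selects its 26-connected component; components are merged per
label into central/portal masks, and a component claimed by both labels is
flagged. Nothing unseeded ever appears in the output.

**Sinusoids** (60×, mouse): a voxel must pass the threshold in both DPPIV
and DMs. Then inverse voting (salt noise), cavity filling (radius slightly
above the lumen radius, fraction 0.7), closing equal to the largest
remaining cavity, optional opening, volume filter, and optional exclusion
of a necrotic mask. The result must be free of enclosed cavities or the
network statistics would be distorted (asserted in the tests via
background-component labelling).

**Bile canaliculi**: median + greyscale opening (radii ≤ 2), a threshold
that may differ from the sinusoid step, direct voting to close sub-voxel
gaps (radius ≤ 2, majority < 4), optional opening, inverse voting, volume
filter. Because mouse DPPIV stains both networks, the sinusoid mask —
dilated by a small margin (default 3, 3, 1 voxels) so the wall's blurred
halo goes with it — is subtracted at the end; the two masks are disjoint by
construction. The margin subtraction is this package's realization of the
otherwise unspecified disambiguation between the two DPPIV-positive
structures.

**Nuclei**: median + greyscale opening, threshold, inverse voting, cavity
filling, closing, opening, then separation by watershed on the negated
anisotropic distance transform. All regional maxima seed the watershed and
adjacent basins merge while `min(peak_a, peak_b) − saddle < alpha` (μm),
iterated to a fixpoint. `alpha` is therefore a true merge level: label
count is monotone non-increasing in it, an isolated nucleus is never split
regardless of `alpha`, and flat anisotropic distance ridges (elongated
nuclei) do not over-split the way threshold-based maxima detection does.

Classification uses the equivalent spherical diameter: below the smallest
non-hepatocyte diameter → dropped; within exactly one class range → that
class; in the overlap (or gap) of the ranges → hepatic iff roundness ≥ the
cutoff (hepatocyte nuclei are large and round; endothelial and other
non-parenchymal nuclei are smaller and elongated); beyond both ranges →
dropped as an unresolvable agglomerate. The class diameter ranges have no
defaults and must be supplied explicitly. Roundness is the isoperimetric
quotient `36πV²/A³` (the cube of sphericity): exactly 1 for a sphere from
closed-form volume and area, 0.20 for a 10:1:1 prolate spheroid, tending
to 0 with elongation. For voxel objects the surface area comes from
marching cubes on a lightly Gaussian-smoothed (σ = 0.8 voxel) binary, which
suppresses the staircase over-estimate. BrdU positivity is mean intensity
over the nucleus's voxels ≥ cutoff.

## Network graphs

Skeletonization resamples the mask to cubic voxels first (nearest
neighbour): thinning treats voxels as cubes, so on a 0.207 × 0.54 μm grid a
round horizontal vessel looks like a flat ribbon and thins into
ladder/ring artifacts. The cubic pitch defaults to the finest spacing; for
wide vessels a pitch near a quarter of the vessel diameter (0.54 μm for
~4.6 μm sinusoids) additionally suppresses the surface-detail spurs that
over-resolved thinning produces. The skeleton keeps the resampled grid's
spacing; all downstream coordinates are physical (μm).

The voxel graph has one vertex per skeleton voxel, edges between
26-adjacent voxels, and per-vertex radii sampled from the anisotropic
distance transform of the source mask. Four filters clean it, applied in
the fixed order resampling → dead-end removal → intersection collapse →
geometric pruning; each is the identity at its neutral parameter
(1, 0, 0, 0):

1. *Resampling* keeps `⌈factor × m⌉` evenly spaced interior vertices per
   branch (branch = maximal degree-2 path), always keeping endpoints;
   total length never increases.
2. *Dead-end removal* deletes dead-end branches (leaf to first
   intersection node) shorter than the threshold, in a single pass over
   the input graph's degrees — dead-ends newly exposed by a removal
   survive, so whole trees are never silently cascaded away. Isolated
   paths have no anchoring intersection and are untouched.
3. *Collapse* merges intersection nodes (degree > 2) whose pairwise
   distance is below the threshold, transitively, placing the merged
   vertex at the group centroid. Remnant vertices whose entire
   neighbourhood leads back into the merged node (one-vertex pendants and
   tiny enclosed loops created by the merge) are absorbed as well — they
   carry no network structure, and leaving them would fabricate sub-voxel
   dead-end branches after the dead-end filter has already run.
4. *Geometric pruning* deletes degree-2 vertices deviating from a straight
   line by less than the angle, reconnecting their neighbours directly,
   sweeping in vertex-id order until a fixpoint. Confluence is validated
   against an all-orders enumeration oracle on small chains rather than
   assumed.

Branch statistics follow the standard taxonomy. After conceptually
stripping dead-end branches, junction-to-junction connections whose
interiors pass only through dead-end anchor points count once, as
second-order; connections with no dead-end in between are first-order. A
path from a junction back to itself is a cycle, not a branch "connecting
two intersection nodes", and is excluded from both counts. Branch lengths
are polyline lengths; the volume fraction is mask voxels × voxel volume
over domain volume.

Graphs are written per connected component to versioned plain-text files
(`<prefix>_graph<i>.txt`: header, `V id x y z radius`, `E id id`),
round-tripping losslessly to six decimals.

## Hepatocyte shapes

Hepatocyte boundaries are unstained; shapes are approximated by a
watershed seeded at the hepatic nuclei over the convex blend
`(1 − w)·d_nuc + w·(max(d_str) − d_str)`, where `d_nuc` is distance to the
nearest nucleus and `d_str` distance to the sinusoid+bile scaffold — the
second term peaks *on* the structures, which act as ridges. `w = 0` is
voxel-identical to a pure nucleus-distance watershed; `w = 1` puts full
emphasis on the structures. The blend realizing the balance is this
package's choice; any field agreeing at the two endpoints is admissible.
Cells cannot claim structure, vein or necrotic voxels (masked before the
watershed); basins merge at saddle depth < `alpha` as in nucleus
separation; labels below the minimal cell diameter are discarded (seeded
basins always contain their nucleus). Per cell: volume, equivalent
diameter, and contact fractions over surface voxels (≥ 1 six-neighbour
outside the cell), classified by the neighbours' membership with fixed
priority sinusoid > bile > neighbouring cell; the remainder is an
unassigned residue, so the three fractions sum to ≤ 100%. Cells touching
the stack border are flagged and excluded from all summary statistics.

## Distance fields and profiles

Distance fields are anisotropy-aware Euclidean distance transforms to the
reference mask surface (0 inside), satisfying the per-axis 1-Lipschitz
property and matching brute force on small grids exactly. BrdU profiles
bin nuclei by the field value at their centroid (nearest voxel) into
contiguous bins of fixed width; counts are conserved. The summary table
emits one row per parameter (counts, volumes, diameters, contact
fractions, per-network branch counts by order, lengths, radii, volume
fractions) with mean, SD and n, always including zero-count rows for
missing networks so downstream tables keep a fixed shape.

## Synthetic phantoms

The generator emulates the 60× mouse acquisition in a 128 × 128 × 64 voxel
stack at 0.207 × 0.207 × 0.54 μm (≈ 26 × 26 × 35 μm — a deliberately small
desk-scale field). One seeded RNG drives everything; output is bitwise
reproducible.

Geometry: a dark-lumen central vein (radius 3.5 μm) through the stack
centre and quarter-cylinder portal veins (2.5 μm) at the corners; a
branching sinusoid tree (lumen radius 1.6 μm, stained wall 0.7 μm,
segments 7–11 μm, bifurcation 40–65° off the parent with siblings ≥ 95°
apart, non-adjacent centrelines ≥ 7.5 μm apart — sinusoids in tissue are
separated by cell-scale gaps); a solid-stained bile tree (radius 0.8 μm)
kept ≥ 1.5 μm clear of sinusoid surfaces; ellipsoidal nuclei of two
classes (hepatocyte 6.5–8 μm diameter, near-spherical; non-hepatocyte
4–5.2 μm, axis ratio 1.4–1.8) placed clear of all structures, with a 30%
BrdU-positive rate (the regime of a proliferating, toxin-injured liver);
a GS shell two cell layers (~9 μm) around the central vein; an optional
necrotic blob in DMs. Terminal tree branches are extended by up to 5 μm
where space allows so that planted dead-end branches stay well above the
3 μm artifact-removal threshold after skeleton tip retraction (≈ the tube
radius) and junction-zone absorption. Channels are rendered with a
0.25 μm partial-volume edge ramp, blurred anisotropically
(σ = 0.2, 0.2, 0.35 μm), then corrupted with Gaussian noise (σ = 6 grey
levels) and 0.1% salt-and-pepper noise.

Ground truth is emitted in the exact containers the pipelines consume:
binary masks, the generating trees as spatial graphs (analysed by the same
branch-definition code the pipeline uses), a nucleus label volume and
records.

What the phantom does *not* emulate: depth-dependent attenuation and
scattering, a real confocal PSF (the blur is a small Gaussian), stain
heterogeneity and cross-talk, anastomosing (cyclic) vessel topology,
deformable/touching nuclei in dense sheets, and field sizes beyond a
single lobule fragment. Passing tests therefore demonstrate correctness of
the algorithms under controlled, known-truth conditions — not segmentation
accuracy on real stacks, which the interactive parameter-tuning workflow
must establish per dataset.

## Default parameters and problem sizes

`hepaq3d.presets` holds the parameterization calibrated for the default
phantom geometry (whole-stack adaptive Otsu; cavity fill radius (9, 9, 4)
voxels at fraction 0.7; closing (4, 4, 2); bile threshold at ~the
half-maximum between parenchymal background and the canalicular stain
after median filtering; nucleus class ranges 3–5.8 μm and 6.1–10 μm with
roundness cutoff 0.5; graph filters 0.5 / 3 μm / 2 μm / 5°; sinusoid
thinning pitch 0.54 μm). Validation runs use the default phantom
(seed 0) plus a zero-noise variant of the same geometry; the whole suite
runs in well under a minute on one CPU.

## Known limitations

* Exact topological recovery of the sinusoid graph (junction, dead-end and
  branch-order counts all exact) holds for the default phantom and about
  half of other random geometries; the failure mode is junction splitting —
  in fat bifurcation wedges the medial axis can place two degree-3
  vertices more than the 2 μm collapse distance apart, adding one
  intersection node. Bile-network recovery is exact across all tested
  geometries. Real analyses tune the collapse distance per dataset.
* The directional cavity fill is iterative and costs a few array sweeps
  per pass; for very large radii on big stacks it is the slowest primitive.
* The 20× acquisition variant (solidly stained sinusoids) is not
  parameterized here, though all primitives it needs are available.
* Nucleus separation assumes blob-like nuclei; near-spherical agglomerates
  with deep mutual overlap may stay merged, as with any distance-transform
  watershed.
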