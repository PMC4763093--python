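# Methods

## Geometric primitives

Surface area is the sum of half cross-product magnitudes over triangles,
optionally restricted to faces of given label classes. Degenerate
(zero-area) faces are counted and warned about but never fatal:
structure-from-motion exports routinely contain slivers, and a hard error
would make every real mesh unusable.

Enclosed volume uses the divergence theorem: each triangle contributes the
signed tetrahedron volume `det(v0, v1, v2)/6`, and the sum over a closed,
consistently wound surface is origin-independent (vertices are centred
first purely for floating-point conditioning). Consistent winding is
restored by flood fill across shared edges starting from the largest face;
a surface where that fails is non-orientable and volume is refused. The
absolute value absorbs the global inward/outward choice. Volume on a mesh
with boundary edges is refused outright rather than estimated — in real
digitisation work some growth forms (tabular, foliose) simply do not
reconstruct as coherent solids, and "not computable" is the honest,
reportable outcome. Callers repair first if repair is meaningful.

Hole filling closes each boundary loop by a fan from the loop centroid.
Break surfaces left by physically sampling a colony are close to planar,
so the centroid fan reproduces the "flat" fill of interactive mesh tools
while remaining well defined for non-planar loops; a three-vertex loop
gets a single triangle. Fill faces are reported so callers can label them
as non-living contact surface. The operation is idempotent and leaves
original faces untouched.

The OBJ dialect: 1-based and negative (end-relative) indices, polygon
fan-triangulation on read, material/normal statements ignored, per-vertex
resolution of texture coordinates, fixed 9-decimal output formatting so
identical meshes serialize to identical bytes. Face labels serialize as a
two-column CSV (`face_index,class`, 0-based) — there is no established
format for per-face segmentation masks, and a diffable CSV is the
simplest thing that survives version control.

## Calibration and alignment

The model-to-centimetre factor is the mean of `known_length /
model_distance` over landmark pairs. The mean-ratio estimator (rather
than a total-least-squares fit) mirrors the field procedure of measuring
the same reference object repeatedly, and keeps a single bad landmark
visible through the coefficient of variation, which is returned and
warned about above 5% (default) instead of silently absorbed.

Alignment is point-to-point ICP: nearest-neighbour correspondences from a
deterministic stride subsample, closed-form orthogonal-Procrustes update,
stop on RMS improvement below tolerance. Initialization is a centroid
shift plus a principal-axes pre-rotation, trying the four proper sign
combinations (and the plain centroid shift, which wins when the shape is
near-axisymmetric and its principal axes are ill-determined) and keeping
the lowest-residual candidate — deterministic, no random restarts.
Unsampled/sampled pairs of the same colony are near-aligned already, so
this basin is sufficient; ICP's monotone non-increasing residual then
holds per iteration. Exhausting the iteration budget above a caller-set
RMS ceiling flags the result instead of raising: a bad alignment is a
data outcome. Note that near-axisymmetric colonies (an ideal hemisphere)
make the rotation about the symmetry axis unidentifiable in principle;
recovery tests therefore use the branched form.

## Derived metrics

All derived quantities are signed differences or non-negative relative
errors, computed at full precision and rounded only at serialization
(2 decimals). The error conventions are `100·|ThSA − ESA_tissue| /
ESA_tissue`, `100·|ThV − TV_tissue| / TV_tissue`, and `100·|TV_skeleton −
TV_water| / TV_water`; the denominators (tissue measurement, water
volume) were confirmed numerically as the only convention reproducing the
published reference table bundled with the package. ThSA and its volume
counterpart stay signed — negative values are physically meaningful
(a sampled reconstruction can come out larger than the unsampled one) —
while the error metrics wrap the difference in an absolute value.

Missing raw measurements propagate: any derived value with an absent
operand is absent, never zero, matching how non-watertight volumes are
reported. The bundled reference table reproduces every published derived
cell within max(0.02 absolute, 0.1% relative); the slack absorbs the
original authors' rounding of intermediates (e.g. a Biomass printed as
3.39 where the printed raw columns give 3.40).

## Frame selection

Sharpness is the variance of the Laplacian of the grayscale frame — the
standard focus measure; the criterion used in the original manual frame
culling was never formalised, so this is declared as this package's
choice. Selection is greedy sharpest-first under two constraints: a count
cap (default 70, the reconstruction service's per-model image limit) and
a minimum ordinal spacing, which keeps the selection spread along the
circling trajectory instead of clustering at the sharpest moment. Ties
break toward the lower frame id, making selection fully deterministic.

## Synthetic colonies

The generator produces parametric stand-ins for the gross growth forms,
chosen for analytic tractability rather than realism:

- **massive** — a UV hemisphere of radius *r* closed by a base disc
  (SA `3πr²`, V `2πr³/3`); cap faces are *living*, the disc is
  *non-living contact*.
- **branched** — a trunk and four branch frusta standing clear of each
  other, so the smooth closed-form SA/V sums are exact per primitive;
  geometric attachment would add intersection area with no testing value.
- **tabular** — a thin circular plate hovering over a stalk frustum.
- **foliose** — an open spherical-cap shell with no basal closure,
  intentionally non-watertight to exercise the volume-refusal path, with
  its lowest face band labelled as the basal contact ring.

Every colony sits over a disjoint seafloor annulus labelled *background*
so segmentation is exercised on each fixture. Default size 5 cm and
resolution 4 (64 azimuthal × 32 polar segments) keep discretization error
below 0.5% of the smooth closed forms while meshes stay small enough for
sub-second geometry operations.

**Sampling** grows a connected patch of the requested living-area
fraction by breadth-first traversal over edge-adjacent living faces from
a seed face drawn from the spec's RNG (deterministic per seed), detaches
it, and flat-fills both resulting break surfaces with the
*non-living contact* label. Because the two fills triangulate the same
loop with opposite orientation, fragment and remaining-colony volumes sum
exactly to the original — a conservation identity the tests assert.

**Bleaching** erodes the living surface inward by the tissue thickness
along area-weighted vertex normals. Vertices touching any non-living face
(basal rim, break surface) stay fixed, mimicking tissue ending where bare
substrate begins; this leaves a one-ring collar at label boundaries, which
is why shell-volume recovery is asserted at 5% rather than exactly. A
local guard halves the offset wherever a face would invert, warning when
it engages.

**Measurement protocol.** The synthetic underwater protocol measures the
unsampled colony's surface over *living* faces only: the base disc exists
to make the digital volume well defined, but it stands in for the reef
attachment, which is invisible to underwater imaging and absent from a
community-segmented model. Under this protocol the underwater differencing
identity is exact on noiseless synthetic data (ThSA equals the removed
patch area, ThV the fragment volume), which is precisely what makes the
synthetic recovery tests sharp. Water-displacement volume is a physical
bench measurement with no digital counterpart, so the generator leaves it
absent. What passing these tests shows is that the measurement chain is
self-consistent and correctly implemented; it says nothing about
reconstruction noise, occlusion, misalignment or scale error in real
imagery, which dominate the error budget in the field.

## Numerical choices

- Watertightness = every undirected edge borders exactly two faces;
  edges with three or more incident faces are a structural error, not
  repaired.
- ICP defaults: 60 iterations, RMS-improvement tolerance 1e-8 cm,
  stride 1 (subsampling is an opt-in speed knob; meshes here are small).
- Scale-fit CV threshold 5% — a warning, never an error, since a noisy
  reference can still be usable.
- Voxel-oracle tests compare the divergence-theorem volume against a
  vertical-ray-casting voxelization at edge h = 0.2 cm with a 3·h·SA
  band, the standard surface-layer bound for voxel volume error.
- Test problem sizes (resolution 3–4 colonies, icosphere subdivision 5,
  200 synthetic frames) were chosen so the whole suite completes in
  seconds while staying inside the asymptotic-convergence regimes the
  assertions rely on.

## Known limitations

- No non-rigid registration; reconstruction distortion between repeat
  models is not modelled or corrected.
- Hole filling assumes near-planar loops; deeply folded boundary loops
  would fill with self-intersecting fans (detected only insofar as
  downstream volume repair fails).
- The branched generator's disjoint-component construction means
  connectivity-based analyses (not part of this package) would see five
  components, not one colony.
- Per-frame sharpness ignores exposure and motion-blur anisotropy; it is
  a focus proxy, not an image-quality model.
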