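# Methods

This note documents the models, estimators and numerical choices behind
`cochleamorph`, and what the phantom-based validation does and does not show
about real micro-CT data.

## The phantom model

The synthetic cochlea stands in for a specimen scan.  Its centreline is a
logarithmic spiral with axial pitch,

    r(θ) = r0 · e^(g·θ),    z(θ) = pitch · θ / 2π,    θ ∈ [0, 2π·turns],

with conventional human-scale defaults (2.5 turns, r0 = 1.6 mm, g = 0.045,
pitch = 1.3 mm/turn).  These are configuration, not measured anatomy: no
published spiral parameters exist for the kind of specimen this emulates, and
every value is exposed on `PhantomSpec`.  The osseous spiral lamina is a
ribbon around this centreline: two parallel plates (tympanic below the
mid-surface, vestibular above; default thickness 0.30 mm, gap 0.15 mm) whose
radial width tapers linearly in unwrapped angle from 1.34 mm at the base to
0.28 mm at the apex — the reported range of the human OSL, used here as
phantom parameters so the measurement task spans the realistic dynamic range.
Plate thickness is exaggerated relative to the real lamina (tens of µm) so
that plates remain several voxels thick at the 30 µm default voxel; the
geometry is a measurement test-bed, not an anatomical model.

Intensities are bone 180, soft tissue 80, background 0, with additive
Gaussian noise σ = 10 applied last.  At the default threshold of 130 both
tissue classes sit 5σ from the decision boundary, so segmentation is
essentially exact; this deliberately isolates geometric measurement error
from segmentation error.  Real scans have partial-volume gradients, beam
hardening and texture that this phantom does not emulate — passing phantom
tests therefore validates the measurement chain given a good segmentation,
not robustness to difficult image quality.

### Pores and exact porosity truth

Pores are unions of discrete Euclidean balls (radius 2–3 voxels by default)
carved into each plate.  Candidate centres are restricted to voxels whose
chessboard distance to the plate surface exceeds r + 1; since chessboard
distance lower-bounds Euclidean distance, every pore keeps at least a
one-voxel bony shell and the void never reaches the plate surface.  The
ground-truth porosity is the carved-voxel count over the pristine plate
count — exact by construction, whatever the pore overlap.

Pores are *allowed to overlap* by default.  Non-overlapping equal spheres jam
near ~38% volume fraction under rejection sampling, well below the 50–65%
porosity regime of interest; overlapping unions reach any target fraction
while keeping the voxel-count truth exact and every cavity strictly interior.
A strict non-overlap mode exists (`allow_overlapping_pores=False`) and raises
a generation error naming the achieved fraction when the target is
unreachable within the 10⁵-attempt budget.

One consequence of uniform sampling over the *eligible interior*: where the
ribbon narrows (apex), the eligible band shrinks faster than the plate
volume, so local porosity falls below the whole-plate target (e.g. ~44% at
the apex for a 53% global target).  This is a property of the phantom, not a
measurement bias — per-segment validation therefore compares against
per-segment voxel-count truth, and whole-plate porosity recovers the global
target almost exactly.

## Width measurement

All geometry is computed in a cylindrical frame built from three landmarks
(cochlear centre, helicotrema, a basal point), matching the manual
axis-setting workflow; automatic landmark detection is out of scope.  Mask
voxels are binned into angular half-planes (default 90 steps/turn, i.e. 4°),
and the turns crossing each half-plane are separated by gap clustering along
the axial, then radial, coordinate (threshold 0.5 mm — above the inter-plate
gap, below the inter-turn clearance).  Turn indices count from the basal turn
upward, which unwraps the angle past 360°.  Planar multi-turn spirals whose
turns overlap radially cannot be separated this way; with any realistic
axial pitch the limitation is immaterial.

“Width along the reference axis” is interpreted as the radial-section
measurement: within each half-plane, width is the 3-D Euclidean distance
between the inner (modiolar) and outer (lateral) wall point of that section.
This mid-modiolar radial construction is the standard one and the only
interpretation consistent with a banded tonotopic width map; the alternative
(projection onto the plane ⊥ axis) cannot be distinguished without the
original specimen.

### Sub-voxel wall localization

A wall point must be located to a fraction of a voxel for a 5% width error at
an 8-voxel-wide apex.  The estimator works per radial sampling column: the
cluster's one-voxel-thick extreme shell is reduced to one voxel per lattice
column (indexed by the two lattice axes transverse to the local radial
direction).  Each column's extreme voxel centre lies inside the solid at a
depth quasi-uniform in [0, c·v), where v is the voxel size and c the cosine
between the radial direction and the dominant lattice axis; the mean of the
per-column extremes shifted outward by c·v/2 is then an (approximately)
unbiased edge estimate with sub-voxel scatter.  Simpler estimators fail
quietly: the global extreme voxel is biased by order v/(k+1) with k sampling
columns, and the shell *centroid* carries an unbounded per-bin phase bias
when the lattice aligns with the edge tangent.  The edge set (per-column
extremes) also provides the robust tangential/axial position of the wall
point.  Wall contours are then regularized with a Savitzky–Golay filter
(window ≤ 15 samples, order 2, shrunk until no point moves more than one
voxel); a boundary-stable local filter is used rather than a global smoothing
spline, whose open-end flaring dominated the error budget.  Sections at the
spiral's free ends that occupy their angular bin only partially are dropped —
they are not full radial cross-sections.

On phantoms with ≥ 8 voxels across the ribbon this chain keeps the
per-sample width error under 5% (typically under 2%) and per-band mean
errors under 1%.

## Tonotopy

`f(x) = A·(10^(a·x) − k)` with the Greenwood human organ-of-Corti constants
as documented defaults.  The spiral-ganglion frequency map that motivates the
octave partitioning is supported by overriding (A, a, k, total length) and by
the `from_base` convention (x → 1 − x), since SG maps are commonly stated
base-first; the original SG constants are not printed in the source material,
so they are configuration here.  Octave boundaries sit at f_min·2^j, clipped
at f_max; positions come from the closed-form inverse, so adjacent bands
share boundaries exactly and coverage is exact.  Band intervals are
half-open with boundary values assigned to the higher band.  Normalized
position is arc length along the measured contour midline, normalized by its
total length — the dendrite-ridge tracing that links SG partitions to OSL
borders in the interactive workflow is approximated by radial projection
within the angular half-plane, since no algorithmic description of ridge
tracing exists.  Inclusion voxels are mapped to the nearest centreline point
(k-d tree) and binned; note that a blob generated exactly at an octave
boundary (2 kHz with 250 Hz-based bands) legitimately splits across the two
adjacent bands, while full-range octaves place it strictly inside one band.

The sample SD uses ddof = 1; a single-sample band reports SD 0 and an empty
band reports n = 0 with null statistics.

## Porosity

Plate splitting assigns each voxel of an angular turn cluster to the
vestibular side if its axial coordinate exceeds the cluster's axial
mid-extent, tympanic otherwise; if fewer than half the sections show an
internal axial gap between two sheets, the mask is a single sheet and a
topology error is raised.

The primary fill backend is morphological closing with the discrete Euclidean
ball {d ≤ R}, implemented exactly via two distance transforms (threshold the
EDT of the complement for dilation, of the dilated set for erosion) —
mathematically identical to structuring-element closing, an order of
magnitude faster on large volumes, and oracle-tested against
`scipy.ndimage` closing.  The array is zero-padded by R + 1 so structures may
touch the volume border.  Closing fills every cavity in which no R-ball fits;
with R = 1.5× the maximum pore radius (the documented default; exposed as a
flag because no equivalent parameter is published for the interactive
procedure) and thin plates, recovery on slab phantoms is exact across
10–65% porosity.  Vf − Vo counts enclosed pores *plus* any surface concavity
the fill bridges, exactly as the formula implies; no attempt is made to
separate the two.

The secondary backend emulates a 3-D graphics shrink-wrap of the exported
STL models: a bounding sphere tessellated within the face budget is
iteratively relaxed (Laplacian) and projected onto the nearest point of a
dense deterministic sampling of the target surface.  Enclosed pores are
separate interior surface components unreachable by the wrap, so the result
is an approximately non-porous adaptation with sphere topology.  The original
procedure's software settings (wrap mode, offset, decimation ratio) are
unpublished, so only enclosure and approximation properties are asserted —
within 2% volume on convex solids, agreement with the voxel backend within
5 percentage points on slabs.  It degrades on strongly concave targets
(e.g. arcs much beyond ~90°), which is why the voxel backend is primary.
Mask-to-mesh conversion uses marching cubes on the zero-padded mask, with a
light Gaussian pre-filter (σ = 0.5 voxel) applied only when diagonal voxel
contacts make the raw isosurface non-manifold.

Turn segments default to equal thirds of the unwrapped angular span
(basal / midturn / apex), overridable, since no zoom-scan boundaries are
published.

## Determinism and problem sizes

All randomness flows through one seeded NumPy generator per phantom; equal
spec + seed reproduces volumes, truths and the pipeline summary byte for
byte.  The default validation phantom is ~250×250×170 voxels at 30 µm
(≈ 10⁷ voxels, ~15 s to generate and ~25 s for the full pipeline on one
CPU); unit tests use a coarser 60 µm, 1.75-turn phantom.  These sizes were
chosen to keep ≥ 8 voxels across the apical ribbon — the validity floor of
the width estimator — while remaining comfortable for routine test runs.

## Known limitations

- Segmentation is plain intensity thresholding plus size filtering; the
  interactive brush-based cleanup it replaces is irreproducible by
  definition, and no claim of equivalence is made.
- The phantom does not emulate partial-volume blur, beam hardening, ring
  artifacts, or soft-tissue texture; accuracy claims are conditional on a
  good segmentation.
- Landmarks (centre, helicotrema, basal point) are inputs, as in the manual
  workflow.
- The mesh-wrap backend is a topological emulation, not a reimplementation of
  any specific software's shrink-wrap operator.
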