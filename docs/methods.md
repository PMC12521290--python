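# Methods

This note documents the models, procedures, numerical choices, and
limitations behind `platefit`. Units are millimetres (geometry),
centimetres (subject height), and years (age) throughout.

## The measurement protocol

### Distance metric

Every fit-criterion distance is a **nearest-vertex distance**: the
Euclidean distance from a measurement point on the placed plate to the
nearest *vertex* of the outer-cortex triangle mesh, not to the nearest
point on a triangle. This reproduces the measurement semantics of
batch scripts that operate on vertex lists. The metric overestimates
the true surface distance by up to roughly half the mesh edge length;
the femur generator therefore enforces a mesh resolution ≤ 1 mm so the
quantisation stays far below the 1–3 mm criterion thresholds. The
KD-tree-accelerated query recomputes the winning distance with the same
arithmetic as an exhaustive scan and breaks ties by the lowest vertex
index, so both paths return identical results.

Contact and collision checks during positioning, by contrast, use exact
signed point-to-surface (point-to-triangle) distances: a 0.2 mm contact
criterion cannot be certified with a vertex-quantised metric on a 1 mm
mesh, and collision is a statement about the surface, not its vertices.

### Containment

Point-in-mesh tests (screw tip inside the canal; penetration
verification) use the generalized winding number — the summed signed
solid angle of all triangles — which is exact for closed oriented
surfaces, with a numba-compiled kernel and a chunked numpy fallback.
Points within 1e-9 mm of the surface count as outside: touching is not
penetrating. For batch penetration checks, candidates are prefiltered
by a signed nearest-vertex proxy and an exact point-to-triangle signed
distance; only samples within 0.005 mm of the surface are
winding-verified. This hierarchical test is conservative for smooth,
closed cortical surfaces of the kind the generator produces.

### Plate positioning

The original protocol positioned plates interactively. Here the
placement is automated and deterministic:

1. **Landmark alignment** — closed-form Kabsch fit of three plate
   reference points (distal anterior and posterior contact anchors on
   the template surface, and the shaft midline point at 60% of shaft
   length) onto the corresponding bone landmarks. The bone-side shaft
   correspondence is constructed by sectioning the bone perpendicular
   to its shaft axis at the matching level and stepping laterally from
   the section centroid — a straight-line offset from the condyle would
   miss the bowed surface by the arc sagitta (several mm).
2. **Feasibility refinement** — the pose is polished by a small
   outward "lift" that clears sub-resolution penetrations; if the
   constraints are then satisfied, the placement is accepted as-is.
   Otherwise a penalised objective is minimised over the 6 rigid
   degrees of freedom (rotation vector about the contact-anchor
   centroid plus translation):

   * one-sided squared zone-contact distance above a margin of
     threshold − 0.02 mm (= 0.18 mm by default). Driving contacts all
     the way to zero gap is over-constrained under bow mismatch and
     drags the pose away from the landmark alignment; the protocol
     itself only requires ≤ 0.2 mm;
   * penetration penalty λ·Σ depth² with λ = 10³;
   * a screw-tip containment penalty (one-sided on the signed distance
     of the most proximal screw tip to the inner cortex) so feasible
     poses keep the screw aimed into the canal.

   The minimiser is a deterministic multiscale coordinate pattern
   search, with a Nelder–Mead fallback (plus deterministic restart)
   when the local search ends close to feasibility, and is skipped
   entirely when the residual shows a geometrically hopeless mismatch.
   Convergence means, exactly: all three zone distances ≤ 0.2 mm, zero
   penetrating undersurface samples, fossa clear, proximal screw tip in
   the canal. Non-convergent bones are reported as unplaceable and
   excluded from cohort summaries with a logged reason.

   The contact "locations" are zones, not points: the distal anterior
   and posterior zones are 5 mm patches of undersurface samples around
   their anchors; the shaft zone is by default the entire shaft strip
   (contact may occur anywhere along the shaft, as in the surgical
   rule), with a config option (`shaft_zone='anchor'`) restricting it
   to a 5 mm patch at the 60% shaft anchor.

### Plate length selection

The longest of the 9/11/13-hole plates whose proximal tip, with the
plate seated flush distally (distal end 9 mm proximal of the most
distal bone point), remains ≥ 20 mm (inclusive) distal of the lesser
trochanter base along the shaft axis. If even the 9-hole plate
violates the rule the bone is flagged as too short.

### Bow radius of curvature

* **Femur**: the shaft axis is the principal direction of the
  inner-cortex vertices (landmark-free and reproducible), oriented
  proximal→distal by the trochanter/condyle landmarks. Twenty section
  planes perpendicular to this axis are placed at arithmetically
  spaced levels — endpoints included — between the lesser-trochanter
  base and 10 mm proximal of the lateral condyle start (the "~10 mm"
  is fixed at exactly 10 mm, config-overridable). Each section's
  centre point is the area centroid of the polygon bounded by the
  outermost canal loop; centroids are robust to non-uniform loop
  sampling, and for near-circular canals they are indistinguishable
  from boundary-point means (the difference is far below mesh
  resolution).
* **Plate**: all centre-curve samples of the shaft span.
* **Circle fit**: total-least-squares plane (SVD), in-plane projection,
  algebraic circle fit, then geometric Gauss–Newton refinement. The
  fit is exact (zero residual) on noiseless circles, rigid-motion
  invariant, and scale-equivariant; a direct 3D nonlinear fit is kept
  as an independent cross-check and agrees to < 0.1% on low-noise
  data. Collinear inputs raise an error (a straight shaft has no
  finite bow radius).

### Statistics

Two-sided Mann–Whitney U (exact enumeration when both groups have ≤ 8
observations and no ties, tie-corrected normal approximation
otherwise), Pearson chi-square without continuity correction on 2×2
pass/fail tables (error on zero expected cells), and Spearman rank
correlation with average-rank ties. α = 0.05 per test with no
multiple-testing correction. Descriptive tables deliberately report
`median ± SD (range)` — an unusual pairing, replicated as printed in
the source tables rather than "corrected" to mean ± SD.

## The synthetic anatomy

No bone meshes are distributed with the protocol, so the package
generates parametric stand-ins that preserve exactly the features the
protocol measures.

### Femur

An idealized long bone: inner (canal) and outer cortex are tube
surfaces around a common centreline that is a circular arc of radius
`r_bow` in the sagittal plane (the anterior bow). The arc is anchored
at the distal end with its apex fixed 230 mm proximal of the distal
end, so distal anatomy depends only on the bow radius and not on bone
length — bones of equal bow present identical geometry to a plate. A
condylar block blends in over the distal 60 mm with lateral/medial
flares (17 mm), posterior condyle masses (8 mm), an intercondylar
notch (10 mm carve, posterior-distal), and a lateral facet inclined
medially by 10°. Landmarks (lesser trochanter base at z = 50 mm,
lateral condyle start, distal anterior/posterior contact points at
±40° around the lateral direction, and a 12-point fossa region) are
computed analytically from the construction, giving every measurement
an exact ground truth. Default shaft cross-section: canal radius 6 mm,
cortex thickness 6.5 mm (outer radius 12.5 mm). Bone model length is
2.5 × height(cm) mm — the femur minus the head/neck segment above the
lesser trochanter. Right-side bones are sagittal mirrors; all fitting
canonicalises to the left side first.

Meshes are ring-stitched tubes with end caps: watertight by
construction, outward-oriented (checked via signed volume), with ring
spacing equal to the resolution parameter (default 1.0 mm, the allowed
maximum) and circumferential spacing matched to it at the largest ring.

What the generator does *not* model: metaphyseal canal flare, cortical
thickness variation, femoral neck/trochanters, antetorsion, coronal
(lateral) bow, and surface roughness (available as optional Gaussian
ring jitter, default off). Passing tests therefore demonstrate the
correctness of the measurement pipeline on controlled geometry, not
anatomical realism of the misfit magnitudes: synthetic proximal-tip
distances are of order 1–3 mm where clinical studies report order
10 mm, because the idealized shaft lets a mismatched plate slide
tangentially where a real proximal femur (flaring into the greater
trochanter) cannot.

### Plate

The plate undersurface is a strip conforming to a *template femur*
whose bow equals the plate's bow radius (default 940 mm — a
reverse-engineered commercial plate contour): the head wraps 110°
around the condylar template at a 0.1 mm standoff; the shaft follows
the 940 mm arc with a transverse "edge clearance" (12 mm flattening
amplitude, i.e. the strip is flatter than the bone cross-section so
only the apex line seats) and a 1 mm tapered tip relief over the
proximal 60 mm. Both features mirror real plate design and are what
keeps the rigid no-penetration constraint satisfiable over the
clinically typical bow range; without them, any bow mismatch beyond a
few percent is geometrically unplaceable, which would contradict the
study setting where every bone received a plate. With them, the
feasible envelope is roughly bone bows of 790–1120 mm against the
940 mm plate (wider for shorter plates); bones outside it are honestly
reported as unplaceable.

Plate lengths: head 51 mm plus shaft of 40 × rows + 20 mm, rows =
(holes+1)/2 → total 271/311/351 mm for 9/11/13 holes, consistent with
commercial lengths and with 2 × 20 mm hole pitch per size step.
Criterion-3 rows sit 30 mm below the meta-diaphyseal transition at
exactly 40 mm pitch ("~4 cm" fixed at 40 mm); the sub-pitch residual
is absorbed before the proximal-tip point. Criterion-2 is a 3×3 grid
over the head (rows at the distal end, −17 mm, −34 mm; anterior/
centre/posterior at ±30°) whose row-1 centre is the distal tip, kept
disjoint from the criterion-1 most-anterior point. The measurement
anchors are generator constructions: the protocol's figures show the
dot layout but no coordinates, so anchor placement is config for any
real scanned plate. The shaft centre curve used for the plate ROC
traces the plate body midline (standoff only, without the tip relief,
which is an undersurface machining feature rather than body
curvature). Four head screws run laterally→medially with a 15°
anterior tilt (clearing the posterior fossa by construction); the most
proximal screw sits 10 mm from the tip and aims at the template canal
centreline.

### Cohort

Eight strata (2 ethnicities × young/old at the 65-year cut × sex) with
the published stratum sizes (n = 159 total), heights and ages drawn
from truncated normals matching the published medians, SDs, and
ranges. Bow radius is coupled to height as
`ROC = intercept_stratum + 10 mm/cm × height + N(0, σ_stratum)`,
clipped to [400, 1800] mm; each stratum's intercept reproduces its
published median ROC at its median height, and σ tops the residual ROC
variance up to the published stratum SD (floor 80 mm). The common
slope of 10 mm/cm was fixed once so that the cohort-level height–ROC
rank correlation lands near the published ρ ≈ 0.45; across seeds the
realised Spearman ρ falls in [0.30, 0.60] for ≈ 95% of draws. The
slope/intercepts are configuration (per-stratum `StratumSpec`), not
code constants.

## Problem sizes and determinism

Default meshes: ~90k outer-cortex vertices per bone at 1 mm
resolution. Unit tests use shortened diaphyses (250–300 mm) where bone
length is irrelevant; the end-to-end suites use 10–16 bone/plate
positioning runs and a 12-subject mechanism cohort, with the full
159-subject specification exercised at the metadata level (no meshes)
where only heights/ROCs matter. Every random draw flows through an
explicit integer seed (`numpy.random.default_rng`); the geometry
pipeline itself contains no randomness, so repeated runs are
bit-identical, and stage CSVs round-trip exactly (`read_table` uses
round-trip float parsing) so re-running the analyze stage on saved
intermediates reproduces its tables byte-for-byte.

## Known limitations

* The positioning automation is a local method around the landmark
  alignment; it does not search globally over initial poses, and a
  `converged=False` verdict means "no feasible pose found near the
  surgical alignment", not a proof of global infeasibility (the
  deliberately mismatched acceptance case is infeasible by
  construction).
* The three contact zones are not traded off when simultaneous 0.2 mm
  contact is impossible; the bone is reported unplaceable rather than
  ranked by partial contact.
* Criterion distances inherit ~0.3–0.5 mm of nearest-vertex
  quantisation at 1 mm resolution; this is part of the metric's
  definition, not an error term to be corrected.
* Absolute misfit magnitudes on synthetic cohorts are smaller than
  clinical values (see above); only orderings and signs — misfit
  grows with bow mismatch, decreases with height under positive
  height–ROC coupling, shorter strata fit worse — are meaningful
  comparisons to published cohorts.
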