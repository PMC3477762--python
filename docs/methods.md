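# Methods

This note documents the models, numerical choices and limitations behind
`kneedea`. It is the package's own account of its science; every number
quoted here is computed by the test suite or by `scripts/acceptance.py`.

## Problem

Tibiofemoral contact stress is a direct mechanical exposure implicated in
knee osteoarthritis. Estimating it per subject at cohort scale requires a
cheap, scriptable pipeline: (1) take triangulated femur and tibia surfaces
(in practice segmented from MRI), (2) recover their weight-bearing pose by
registering each surface to the bone edges visible in a standing
posterior-anterior (PA) fixed-flexion radiograph, and (3) compute the
contact stress distribution with discrete element analysis (DEA) rather
than finite elements. A reliability layer (ICC, Bland-Altman) quantifies
how much the resulting stress metrics vary across raters and days.

Because the cohort imaging this workflow targets is not redistributable,
the package ships a synthetic phantom generator that produces every input
the pipeline needs with known ground truth, and all tests and benchmark
experiments run on those phantoms. What a green test establishes is
therefore internal consistency and recovery of known synthetic truths —
not clinical accuracy on real knees.

## Virtual radiographic scene

The acquisition is modelled as a point source and a planar detector:

- detector in the plane z = 0, spanned by x (horizontal/medial-lateral)
  and y (vertical); represented, as on real systems, by two adjacent
  coplanar polygons;
- source at 1828.8 mm (72 in, exact) from the detector centre along a
  central ray tilted caudally by 5, 10 or 15 degrees about the detector's
  horizontal axis (other angles require an explicit override);
- the knee's nominal position sits on the central ray at a configurable
  object-to-detector distance (default 100 mm), giving a magnification of
  SDD/(SDD − d) ≈ 1.06.

One geometric ambiguity deserves note: "source at SDD from the detector"
can mean the perpendicular foot-point distance or the distance along the
tilted central ray. This package uses the central-ray convention
(|source − detector centre| = SDD exactly), which also keeps the
zero-angle case degenerate-free.

## Silhouette projection and contour cost

Model silhouettes are extracted per pose as the mesh edges whose two
adjacent facets face opposite sides of the source (boundary edges always
included), projected by intersecting source-to-vertex rays with the
detector plane, and rasterized with 8-connected line runs between
projected edge endpoints (equivalent in contract to Bresenham segments).

The registration cost between the model contour M and the radiograph edge
tracing R is the symmetric mean distance transform, in millimetres:

    cost(M, R) = mean_{p in M} dist(p, R) + mean_{q in R} dist(q, M)

It is zero iff the foreground sets coincide, symmetric by construction,
and decreases monotonically as a displaced contour approaches truth. The
radiograph side is precomputed once as a Euclidean distance transform; the
model side is evaluated per pose with a KD-tree over model pixels, which
gives the identical numbers at a fraction of the cost of a per-pose
distance transform (verified bit-exact in the tests). Distances in pixels
vs millimetres, and one-way vs symmetric, were open choices; mm and
symmetric are fixed here.

## Pose model and registration

A pose is (tx, ty, tz) in mm and intrinsic z-y-x Euler angles (rx, ry, rz)
in degrees, rotating about the bone's centroid fixed at optimization
start. Centroid-centred rotation decorrelates rotation from translation
for the optimizer; z-y-x is an arbitrary but fixed convention.

The cost landscape is nonconvex, so poses are sought with a canonical
(mu/mu_w, lambda)-CMA-ES (log-rank weights, cumulative step-size
adaptation, rank-one plus rank-mu covariance updates) implemented
in-package on a single seeded `numpy` generator, making every run
bit-reproducible. Defaults follow the workflow this mirrors: 70 candidates
per generation, at most 8000 cost evaluations per run, three independently
seeded runs with the lowest-cost run winning (ties broken by run index).
Additional choices the source workflow left open:

- initial search scales sigma0 = (5, 5, 10) mm and (3, 3, 3) degrees —
  the out-of-plane translation gets the larger scale because a single
  projection constrains depth only through magnification;
- stagnation stop: best cost unimproved (relative 1e-12) over 20
  consecutive generations;
- the start pose is scored explicitly, so a registration is never worse
  than its initialization.

The femur is registered first; its best transform is applied to the tibia
as the tibial start, and the tibial cost adds a proximity penalty
`weight * max(0, gap − threshold)` with gap the minimum vertex-sampled
intersurface distance, threshold 6 mm (the combined cartilage thickness)
and weight 1 — the penalty's form and constants are this package's
choices. Expected behaviour, confirmed by the acceptance experiment: mean
in-plane translation error well under 0.5 mm and beam-axis rotation error
well under 0.7 degrees when recovering a self-rendered phantom pose from a
±5 mm / ±5 degree perturbed start; out-of-plane error is recorded but not
bounded, since depth is nearly unobservable in a single projection.

## DEA contact model

Bones are rigid; the combined tibiofemoral cartilage is a uniform bed of
independent compressive-only springs (Winkler / elastic foundation) of
thickness t = 6 mm. For a tibial facet with separation s to the femoral
surface along its normal, the deformation is d = max(0, t − s) (d > t when
the bone surfaces overlap; tension never modelled) and the stress follows
the linear-elastic confined-compression law

    sigma = E (1 − nu) / ((1 + nu)(1 − 2 nu)) · d / t

with E = 12 MPa, nu = 0.42 (aggregate modulus 30.634 MPa, foundation
stiffness k = 5.106 N/mm^3 at t = 6). The law is a pluggable function so
alternative deformation-stress relations can be swapped in.

**Separation measurement.** The separation s is measured by casting the
tibial facet-normal ray against the femoral triangles (Möller–Trumbore,
signed distance, minimum over hits). An earlier variant projected the
vector to the nearest femoral facet centroid onto the tibial normal; its
lateral pairing mismatch adds an error of order slope × facet size, which
at equilibrium deformations of ~0.15 mm produced 30–40% spurious
thickness sensitivity in peak stress on the conforming phantom. Ray
casting leaves only the chord-sagitta error of the femoral mesh and
restores the expected < 10% sensitivity. Because the femur only
translates along the load axis during the equilibrium search, all
ray-triangle quantities are linear in the offset; they are assembled once
(KD-tree candidate generation, chunked to bound memory) and each force
evaluation is a handful of vectorized passes. The nearest-facet KD-tree
pairing remains as `find_contact_pairs` (verified identical to exhaustive
search) and generates the candidate sets.

**Load control.** The femur is translated along the vertical axis until
the summed vertical contact force (stress × facet area; 1 MPa·mm² = 1 N)
matches the applied 1000 N within 0.5% (5 N): the target is bracketed by
1 mm marching within a ±10 mm travel bound, then bisected (force is
monotone in the offset, so the solve is deterministic); 100-iteration cap.
Only the vertical translation is iterated — the modelled load is a single
vertical force, so AP/ML balance is not enforced. The 1000 N is treated as
the total across both condyles.

**Metrics.** Facets are split into medial/lateral compartments by a
sagittal plane through the tibial centroid (configurable). Peak is the
maximum facet stress; mean is the area-weighted mean over facets in
contact (averaging over the whole compartment would dilute by arbitrary
segmentation extent). Stress is reported on the tibial surface.

Verified against closed forms: a rigid sphere (R = 40 mm) on a flat bed
matches p0 = sqrt(kP/(πR)) ≈ 6.374 MPa within 2% at coarse and well
under 1% at fine meshes; congruent nested spherical patches produce a
uniform stress equal to load over projected contact area.

## Synthetic phantom

The knee phantom is parametric and deterministic:

- femur: two spherical condyles (default radii 40 and 36 mm — unequal so
  the silhouette determines the pose uniquely) on a capped-cylinder shaft
  stub; components are closed and outward-wound (the shaft may interpenetrate
  the condyles; contact only involves the condyle surfaces);
- tibia: a closed extruded heightfield plateau carrying two spherical
  sockets matched to the condyles (socket radius = condyle radius +
  0.5 mm clearance, rim radius 15 mm);
- apposition: each condyle rests touching its socket bottom, so the gap
  grows parabolically toward the rim with effective radius
  R(R + c)/c ≈ 3240 mm — conforming, rim-limited contact whose stress
  peaks at the smooth cup centre rather than at the discretization-noisy
  rim crease. The ground-truth relative pose is the identity.
- the conforming variant (equal 40 mm condyles, 85 mm spacing) is the
  thickness-sensitivity fixture; default refinement 1 gives ~6k/29k
  facets (≥ 2000 per bone).

Radiograph edge images are produced by the pipeline's own forward
projector at a known pose, so registration experiments have exact ground
truth and zero model-image mismatch. Segmentation variability is emulated
by displacing vertices along their normals with mesh-graph-smoothed white
noise (iterated neighbour averaging, then rescaled to a target RMS
amplitude); the exact noise spectrum is not controlled, only smoothness
and RMS. Rater studies are simulated from the two-way random-effects
model value(i,j,d) = mu + a_i + b_j + e_ijd with specified variance
components, whose population single-score ICC is
sigma_t² / (sigma_t² + sigma_r² + sigma_e²).

What the phantom does **not** emulate: anatomic bone shape, cartilage
thickness gradients, radiographic noise/trabecular texture, segmentation
bias (only smooth random error), and asynchronous biplanar views.

## Reliability statistics

ICC(2,1) — two-way random-effects, absolute-agreement, single measure —
is computed from the ANOVA mean squares of an n × k matrix:

    ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n)

Rows with missing cells are deleted listwise (logged); a zero-variance
matrix raises an error rather than returning a sentinel, so batch reports
cannot silently absorb degenerate inputs. The study-level report collapses
a knees × raters × days design into four ICCs per metric: day-to-day uses
the 2 days as columns with knee × rater rows stacked; interrater uses
raters as columns at day 1. This aggregation is a convention of this
package (configurable through the matrix builders), as is using day-1
values for the interrater arm.

Bland-Altman summaries use differences a − b against pair means, limits
at exactly mean ± 2 SD (sample SD, not 1.96), and omit (with a count)
pairs in which either measurement is zero — "no contact" observations.

## Quality control and batch behaviour

Batch runs isolate failures per knee. Flags (thresholds configurable):
registration cost > 1.0 mm; inter-run in-plane pose spread > 1 mm or
> 1 degree; equilibrium nonconvergence; a compartment with no contact;
peak stress outside (0.5, 30) MPa. Every summary records the config hash
and all derived seeds.

## Known limitations

- Single static vertical load; no gait, friction, shear springs, or
  subject-specific cartilage thickness maps.
- Depth (out-of-plane) pose is weakly constrained by design; biplanar
  registration is out of scope.
- Mesh repair is limited to duplicate-vertex merging and degenerate-facet
  removal; inputs are assumed closed or boundary-tolerant.
- ICC confidence intervals are not computed.
- The registration accuracy and thickness-sensitivity figures are
  phantom-scale analogues, not reproductions of any cohort statistic.
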