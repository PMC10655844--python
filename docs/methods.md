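# Methods

This note documents the models, numerical choices and limitations of
`seegrs` at the level a maintainer or reviewer needs to judge what a
passing test suite does and does not establish.

## Source model

Interictal spikes are generated by centimetre-scale sheets of
synchronously active cortex.  We represent them as *patch sources*: one
patch grown around every triangle ("element") of the cortical surface
mesh, as contiguous sets of per-element dipoles oriented along the
outward surface normal.  Patch growth is ring-wise breadth-first over
edge adjacency, admitting whole rings until the cumulative area first
reaches the target, so growth is deterministic and orientation-free.
The returned area `A` therefore overshoots: `A >= target` and
`A − area(last ring) < target`; on coarse meshes the overshoot can be
tens of percent of the target.  Patch *extent* is the mean Euclidean
distance from the area-weighted centre of mass to the boundary vertices
(vertices on edges shared with non-member triangles); Euclidean rather
than geodesic distances are used because extents are compared with
Euclidean source-contact distances.

The standard source grid crosses areas {6, 10, 20} cm² with dipole
moment densities {0.16, 0.465, 0.77} nA·m/mm² — nine source types, with
(10 cm², 0.465 nA·m/mm²) the default used in all analyses.  Patch
voltages are assembled from the per-dipole lead field by scaling each
member column by its triangle area (mm²) and the density, giving
microvolts via the fixed bookkeeping 1 nA·m = 10⁻⁹ A·m and
1 V = 10⁶ µV.  Patch voltages are kept signed; magnitudes are taken
only when thresholding, so assembly stays exactly linear in the
density.

## Forward model

The volume conductor is an unbounded homogeneous medium with
σ = 0.33 S/m (standard bulk brain-tissue conductivity), for which a
current dipole has the closed-form potential
V(r) = p·(r−r₀) / (4πσ|r−r₀|³) with the reference at infinity.
Observation points closer than 0.1 mm to a dipole raise a singularity
error.  This analytic model deliberately replaces patient-specific
finite-element head models: it preserves every property the downstream
metrics rely on (linearity, superposition, 1/r² on-axis decay,
orientation selectivity) while remaining exactly testable.  It omits
tissue boundaries and anisotropy, so absolute voltages — and hence
absolute RS values on the synthetic head — are indicative, not
clinical.  Externally computed lead fields can be imported from an HDF5
container (`/matrix`, `/contacts`, `/source_ids`, attribute
`units="V_per_Am"`) and flow through the identical code path.  A
post-hoc reference-contact subtraction is provided in place of a
grounded-surface reference, which an infinite medium does not have.

## Discernibility thresholds

The analysis thresholds 200/500/1000 µV bracket clinically discernible
interictal-spike amplitudes.  Their empirical basis is implemented in
the trace statistics: the noise floor is 4× the standard deviation of
spike-free samples (a Gaussian's ±4 SD span covers
2Φ(4)−1 = 99.99% of samples), and spike amplitudes are summarized as
per-spike maxima of |V| after common-average referencing, reported as
the mean and the 25th percentile (linear interpolation between order
statistics).  Threshold comparisons are inclusive (|V| ≥ thr) and use
magnitudes; spike polarity carries no information for detectability.

## Recording sensitivity and recording radius

A patch is recordable by an electrode when |V| ≥ thr at a minimum of
two of its contacts — source localization needs the same event on
multiple contacts.  RS of a configuration is the percentage of ROI
patches recordable by at least one electrode; the optimizer's cost is
the complementary count of unrecordable patches, so
RS·P_total/100 + C = P_total holds exactly (integer patch counts).

The recording radius sorts patches into half-open 0.25 cm
source-to-contact distance bins per sampled contact, computes the
percentage of each bin's patches above threshold (single-contact
recordability here, since the quantity characterizes one contact),
takes the median across contacts per bin, and reports the right edge of
the farthest bin whose median is ≥ 20%.  Bins that are occupied for
only some contacts enter the median with the contacts that have them;
when no bin passes, radius 0 is reported with a flag.  Contact
locations are sampled per labelled cortical subregion (3 per region,
35 regions per hemisphere → 105 per hemisphere), area-weighted within
regions.

## Trajectory generation and safety constraints

Electrodes are 16-contact depth electrodes with 2 mm contacts and
1.5 mm insulators (3.5 mm centre-to-centre pitch), each contact modelled
as a point at its centre.  Candidate lines are (entry, direction) pairs:
entries are sampled uniformly by area from a scalp cap, directions on a
≤ 10° cone about the inward scalp normal using a deterministic Fibonacci
spiral (uniform in solid angle) with an optional seeded azimuth
rotation.  Depths are discretized at the pitch with total length
≤ 100 mm; since contacts share the same lattice, consecutive depths of
one line share 15 of 16 contacts, and a full-length line yields
⌊(100−52.5)/3.5⌋+1 = 14 trajectories.  Contacts are placed tip-first
(deepest contact centre at the tip).

Shafts are represented as 128 evenly spaced points for both clearance
filtering and collision detection (< 4 mm between any point pair of two
electrodes; strict inequality).  Minimum distances to critical
structures use an axis-aligned-box BVH (median split, leaf size 8) with
batched traversal; query upper bounds are seeded with the exact distance
to the nearest-centroid triangle, and an exact strided shortcut (the
distance to a fixed structure is 1-Lipschitz along a straight shaft)
decides most shafts from 17 of the 128 points.  Both shortcuts are
provably equivalent to the brute-force check and are audited against it
in the tests.

The skull clearance (4 mm) applies only "away from the insertion site":
shaft points within 15 mm of the entry are exempt, because every
electrode necessarily crosses the skull where it enters and the exempt
zone must cover that transit plus the clearance itself (on the synthetic
head the scalp-to-inner-skull transit is ~7 mm).  The skip distance is a
parameter.

## Sulci surface

The sulci surface — used both as a critical structure (1.5 mm
clearance; 2.5 mm invalidates transferred configurations) and as a
vasculature proxy — is the sub-mesh of cortex triangles lying inside a
super-smoothed copy of the cortex.  Smoothing is 100 iterations of
shrink-compensated (HC/Vollmer) Laplacian smoothing (α = 0, β = 0.5);
plain Laplacian smoothing is available but collapses the global scale
long before 100 iterations, which destroys the comparison.  Containment
is a generalized-winding-number test plus the requirement that the
centroid lie *deeper* than a 1.5 mm margin inside the smoothed surface
(BVH distance).  The margin absorbs two faceting artefacts — triangle
centroids sit inside any smooth surface by the chord sagitta, and HC
smoothing can overshoot outward by a fraction of a millimetre — and
must stay well below the sulcal depth (~7 mm on the default synthetic
head).  Zero smoothing iterations define an empty sulci surface.

## Optimizer

The next-best search is greedy set cover with a threshold-priority
order: at each step the candidate with the maximal cost decrease at the
primary threshold is chosen; ties fall through the secondary and
tertiary thresholds and finally a dedicated seeded random draw recorded
in the configuration.  Cost comparisons are exact integer comparisons of
patch counts.  Candidates colliding with any selected electrode are
masked permanently.  The search stops at the electrode budget (31 by
default) or when no remaining candidate improves the primary-threshold
cost.  Because the search is iterative, the first X electrodes are the
optimized configuration of size X.  Greedy set cover is not optimal
(the problem has no optimal substructure); the tests compare it against
the exhaustive optimum on small instances and report the gap, and the
classical (1−1/e) coverage guarantee is asserted.

Fixed (e.g. clinically implanted) sets are *ordered* by the same loop
without selection; electrodes belong to an ROI when at least one
contact is within 3 mm of the ROI surface and at least half the
contacts are within 10 cm.  Configuration transfer applies a rigid
6-DOF transform (orthonormality and det = +1 are enforced), recomputes
the lead field at the transferred contacts with the target head's
forward model, evaluates RS at the matched case's minimum electrode
count reaching 75% RS (the full set, flagged, when never reached), and
marks electrodes passing within 2.5 mm of the target sulci as invalid
while keeping them in the RS estimate (best-case sensitivity).

## Synthetic data

The synthetic head consists of concentric subdivided icospheres
(scalp 92 mm, inner skull 85 mm) and a cortex whose radius is
70 + 7·sin(6θ)·sin(6φ) mm — folds deep enough (±7 mm) to create
unambiguous gyri and sulci at mesh subdivision 3 (1280 faces, the
working resolution) while staying under the skull.  The midline is an
explicit plane (x = 0), not derived from geometry.  Region labels for
contact sampling are quantile cells in spherical coordinates, 35 per
hemisphere.  Voltage traces are Gaussian noise plus biphasic triangular
spike templates 60 ms wide (only the peak amplitude enters any
implemented statistic), assigned round-robin to channels so that
common-average referencing does not cancel them; a spike-free mask is
returned for noise estimation.  All generators are bit-reproducible
under a fixed seed.

What the synthetic head does *not* emulate: realistic cortical folding
geometry and curvature statistics, tissue heterogeneity and anisotropy,
CSF, vasculature, and the sub-millimetre co-registration error of real
imaging.  Tests passing on it establish the correctness of the
geometry, metrics and optimization logic — not clinical RS magnitudes.

## Problem sizes and tolerances

The shipped tests and examples run the full chain at subdivision 3 with
40 entry points × 6 angles (3360 candidate trajectories, ~600 valid
after filtering and line downsampling, 1280 patches); these sizes keep
the suite fast while leaving every code path at realistic density.  The
large-scale defaults from clinical practice (800 entries × 366 angles,
95 000 valid trajectories, ~40 000 cortical elements) remain the
documented parameter defaults.  Oracle equivalences are asserted at
1e-9 mm (distances) and 1e-12 relative (lead fields); analytic
geometry checks use 1–5% bands reflecting mesh faceting; stochastic
estimates (noise SD recovery) use 2% at n ≥ 10⁵ samples.  The
optimized-beats-random acceptance check compares, at each threshold,
the configuration optimized with that threshold as primary priority
against 100 seeded random non-colliding sets of the same size, at every
prefix size — greedy at one priority does not in general dominate
random sets at *other* thresholds.

## Known limitations

- The infinite-medium forward model shifts absolute voltages relative
  to a bounded, layered head; thresholds retain their clinical meaning
  only through the imported-lead-field path.
- Patch areas overshoot their nominal value by up to one triangle ring;
  on coarse meshes the nine source types are correspondingly coarser.
- The sulci criterion depends on the smoothing schedule and the 1.5 mm
  containment margin; both are parameters, and very coarse meshes
  (subdivision 2) yield empty sulci because smoothing then shrinks the
  reference copy below the troughs.
- Vasculature is only proxied by sulci; no risk scoring of trajectories
  is implemented.
- Greedy configurations carry no optimality certificate beyond the
  (1−1/e) coverage bound.
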