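# Methods

## Coordinate and label conventions

All internal geometry is world millimetres, RAS+. Voxel indices are
0-based; voxel `i` owns the half-open interval `[i − 0.5, i + 0.5)` of
continuous voxel coordinates along each axis, so every point maps to
exactly one voxel and boundary behaviour is deterministic. TRK files
store corner-origin voxel-mm coordinates; they are converted to world mm
at read time (via nibabel), so no other module ever sees an on-disk
convention. Label semantics (name, hemisphere, lobe, tissue class
CGM/SWM/DWM/other, anterior/posterior terminal side) live in a TSV table
separate from the NIfTI label image.

## Streamline-to-voxel assignment

The traversal set of a streamline — every voxel whose ownership cell its
polyline intersects — is computed by an exact plane-crossing walk: for
each segment the crossing parameters of all inter-voxel boundary planes
are enumerated, and the segment is evaluated at the midpoint of each
sub-interval. This is exact up to floating point and catches corner
clips of arbitrarily small chord length. Fixed-step polyline sampling
(the more common implementation) was rejected for the production path:
a half-voxel step provably skips the intermediate voxel of a double axis
crossing, so traversal sets would depend on the sampling phase. Sampling
remains available (`geometry.sample_polyline_points`) and serves as an
independent cross-check in the tests, alongside a per-voxel segment/AABB
slab-clipping oracle. Endpoint labels use nearest-voxel lookup on the
once modally-dilated atlas, which closes the one-voxel gap between
cortical labels and white matter at the tissue interface.

Modal dilation assigns each background voxel the most frequent non-zero
label among its 26 neighbours; ties break to the lowest label id (a
deterministic choice the downstream statistics never depend on).

## Dissection pipeline

Preparation removes, in a fixed order with first-match attribution:
(1) streamlines shorter than 10 mm; (2) streamlines confined to cortical
grey matter; (3) U-shaped superficial streamlines, operationalized as
*never entering deep white matter* (traversal within CGM ∪ SWM) — long
association fibres also cross SWM near their terminations, so a naive
"touches SWM" rule would delete everything; (4) streamlines entering the
cerebellum/brainstem; (5) streamlines crossing the mid-sagittal plane,
tested as a world `x = 0` sign change between consecutive vertices (a
fissure-mask variant would be a config extension; phantom and MNI-like
spaces put the fissure at x = 0).

Stem exposure additionally hides streamlines with an endpoint in the
insula or temporal pole (IFOF) or the insula or superior temporal gyrus
(UF); it is a drawing aid only. The stem ROI is a single-slice binary
mask — drawn externally or proposed by the waist search, which reports
the slice in a caller-given range with the fewest streamline-occupied
voxels (zero-occupancy slices excluded; ties to the lower index).

Extraction always returns to the *original* tractogram: every streamline
whose traversal intersects the stem mask is kept, minus those touching
per-tract exclusion labels (temporal pole for the IFOF) or extending
beyond an optional exclusion plane (the UF's posterior coronal cut-off,
a per-run configuration value since no fixed coordinate generalises
across subjects). Endpoints in the insula or subcortical nuclei are kept
but flagged excluded-from-analysis; endpoints that fail to reach
cortical grey matter are flagged broken. The claustro-cortical decoy
system that skirts the IFOF stem is excluded purely by ROI geometry (the
mask must not include its voxels); no shape-cohesiveness classifier is
implemented.

Broken streamlines stay in the extracted tract by default
(`discard_broken=False`): they pass the stem and belong to the tract,
and keeping them in the NTDS denominator is what makes the per-region
scores sum to less than one in the presence of premature terminations —
the behaviour the termination statistics are designed around. Setting
`discard_broken=True` restricts the tract to whole streamlines.

## Termination statistics

Endpoint tallies, NTDS, the false-positive-region threshold
(mean + 2 × *sample* SD, n − 1 denominator), adjusted scores, presence
percentages, territory tests and asymmetry statistics follow the
formulas in the README. Design choices:

- Adjusted scores are computed for **all** subjects, negatives retained,
  so the signed-rank test has a complete paired sample; "presence" means
  an adjusted score strictly above zero.
- The FP threshold pools hemispheres by default (`per_hemisphere=True`
  available); with one reference region per tract the pooled estimate is
  the more stable of the two readings.
- Wilcoxon signed-rank: zeros dropped (the original convention), exact
  null distribution for n ≤ 25 without ties, otherwise the normal
  approximation with tie correction. The Bonferroni divisor is the
  number of region × hemisphere cells actually tested, computed from the
  data, never hard-coded.
- The asymmetry test is a two-sided one-sample location test of the
  per-subject asymmetry indexes against zero (t by default, Wilcoxon
  selectable), Bonferroni-corrected over tested regions; regions with
  fewer than five non-missing indexes are skipped and reported as
  untested. An index is missing (not zero) when both hemispheres score
  zero.

## Stem morphometry

Stem volume is voxel count × voxel volume; the centre of mass is the
unweighted mean of non-zero voxel-centre world coordinates (binary
masks; no density weighting), optionally pushed through a user-supplied
affine standing in for spatial normalization. Inter-operator reliability
reports signed volume differences (mean ± SD, paired t) and
centre-of-mass Euclidean distances per tract × hemisphere. The
stem-volume ANOVA is the classical split-plot decomposition with Tract
and Hemisphere (two levels each) within subjects and Sex between; each
within effect is tested against its own subject-interaction error
stratum. With two-level factors no sphericity correction applies. The
implementation is hand-coded sums of squares (no installed Python
package covers two within factors plus a between factor) and was
validated against an independent statistical environment; a frozen
four-subject decomposition guards it in the tests. Degenerate inputs are
handled explicitly: a zero effect sum of squares reports F = 0, p = 1; a
non-zero effect over a zero error stratum reports F = ∞, p = 0.

## The phantom

The phantom atlas is a deterministic block-world on a 60 × 72 × 60 grid
of 2 mm isotropic voxels centred on the origin: per hemisphere, an
anterior (frontal) and a posterior (occipito-temporo-parietal) bank of
gyral CGM blocks (4 voxels thick), an SWM layer (4 voxels) beneath each
bank, a DWM core filling the interior, an insular block on the lateral
surface and a subcortical block inside the core (both endpoint-excluded
regions), and a midline cerebellum/brainstem block below. The
false-positive reference regions are `precentral` (IFOF) and
`superior_parietal` (UF). Hemispheres stop 1 voxel short of x = 0, so no
jittered tract streamline can cross the mid-sagittal plane.

Tract streamlines are piecewise-linear paths densified at 1 mm from a
uniform-random point inside the origin region's CGM block, through the
stem, to a point inside the destination CGM block. The stem passage is a
funnel: the streamline's in-slice offset from the stem centre (uniform
within ±1.4 mm, inside the designed 2 × 2-voxel waist) doubles two
slices away on either side, which makes the waist's occupied-voxel count
a strict minimum — the geometry the waist search must find. Region
choices follow per-hemisphere termination probability vectors; the
defaults mirror the relative group-mean termination densities of the two
tracts, including their known asymmetries (e.g. a rightward
inferior-frontal IFOF branch), with near-zero mass on the FP regions.

Premature termination is modelled per streamline **end**: each end is
independently truncated with probability `broken_fraction` (default 0.2)
at a uniform-random interior DWM vertex, keeping ≥ 8 mm of path around
the stem so a doubly-broken streamline never falls under the 10 mm
fragment threshold and every class stays exactly decidable. Under this
law a region's expected NTDS is `(1 − broken_fraction) × p × share` of
its hemisphere's streamlines — the quantity the recovery tests check.

Nuisance classes are realised with explicit margins: U-fibres connect
two frontal gyri dipping only into the anterior SWM layer; GM-confined
fragments zig-zag inside one CGM block; shorts are 4 mm DWM segments;
interhemispheric streamlines cross x = 0 through deep white matter;
cerebellar streamlines descend from the DWM into the cerebellum block;
stem-bypass decoys replicate tract geometry with the funnel displaced
6 mm laterally (≥ 1.5 mm clear of the mask at its closest approach), so
only ROI geometry excludes them. Default cohorts have 60 subjects (half
female, alternating), 250 streamlines per tract per hemisphere, and a
modest complement of every decoy class.

`simulate_termination_counts` generates endpoint-count cohorts directly
(per-end survival Bernoulli, multinomial region assignment) without
streamline geometry. The count law is identical to the geometric route —
which is verified end-to-end elsewhere — so replicate-heavy power and
family-wise-error studies run in seconds. Per-subject stem masks grow
from the designed waist by random in-slice accretion, with more voxels
in the right hemisphere (the rightward stem-size effect the ANOVA should
find) and an optional in-slice shift emulating a second operator.

**What the phantom does not emulate:** cortical folding, partial-volume
and crossing-fibre effects, registration error, spatially varying
streamline density, or anatomically realistic stem shapes. Passing tests
therefore certify the *logic* of the filters and statistics — exact
recovery when class margins hold, correct count laws, calibrated tests —
not robustness to real-data geometry violations.

## Problem sizes and numerics

Recovery studies use 30-subject cohorts with 250 streamlines per
hemisphere and 100 replicate cohorts for power/error-rate checks; the
filter-exactness fixture uses 500 tract streamlines against 250 decoys.
These sizes put all binomial 3-SE bands well inside the designed effect
margins while keeping a full run in tens of seconds. Statistical
tolerances in the tests are three standard errors of the quantity under
its own sampling law — never tuned constants. Numerical edge cases are
pinned by tests: empty tractograms and masks, all-zero score vectors,
exact-tie waist slices (lower index wins), exact threshold boundaries
(`adj = 0` is absence), and the reconstruction identity
`adj + threshold = NTDS`.

## Known limitations

- The published cohort behind the reference stem table is not public;
  group-level numbers from real data are represented only by the printed
  coordinate means used in the consistency checks, and the reported
  posterior inter-stem contrast there (2.0 mm left) is inconsistent with
  the difference of the printed mean y-coordinates (2.9 mm); the package
  computes contrasts from coordinates and documents the discrepancy
  rather than matching the printed value.
- Spatial normalization is an affine stand-in; no nonlinear warping.
- The interhemispheric filter assumes the fissure at x = 0.
- Stem ROIs are single-slice by contract; oblique stems are out of scope.
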