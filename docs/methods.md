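# Methods

## The measurement model

The quantity of interest is the cross-sectional lumen area of the murine
common carotid artery as a function of position between the aortic arch and
the carotid bifurcation. Two measurement chains estimate it:

**CT chain.** A contrast-enhanced volume is thresholded at the midpoint of
the mean blood and mean muscle intensities, measured in two operator-defined
box ROIs. The midpoint rule assumes the lumen wall separates blood from
tissue of approximately muscle intensity, so the threshold falls near the
half-occupancy isosurface of the partial-volume edge. The binary lumen is
the 26-connected component containing a seed (26-connectivity because thin
oblique vessels fragment under 6-connectivity at 18 µm voxels). A
radius-weighted geodesic then traces the vessel between a start seed placed
shortly distal to the arch and an end seed shortly proximal to the
bifurcation: on the voxel graph of the mask, a step from u to v costs
`‖u−v‖ · (1/r(u) + 1/r(v))/2`, with `r` the Euclidean distance-map value.
This is the behaviour of an "elastic sphere" that inflates against the wall
and slides between the seeds: paths through wide lumen are cheap, narrow
gaps are expensive, and the optimum follows the medial axis. The symmetric
edge weight makes the cost direction-independent; seeds are canonically
ordered before solving so forward and reverse traces are exact reversals.
Local diameter is twice the distance-map radius at each path voxel; the
path coordinates (not the radii) are smoothed by a 3-point moving average
with fixed endpoints before arc lengths are accumulated.

**Histology chain.** Sections are cut every 500 µm from arch to
bifurcation (nine per 4.2 mm vessel). Because embedding compresses vessels,
lumen area is not taken from planimetry of the traced contour but from its
perimeter under a circular assumption: `d = P/π`, `A = P²/(4π)`. This is
exactly invariant under perimeter-preserving deformation, and by the
isoperimetric inequality it upper-bounds the planimetric area (equality for
circles). For plaque-bearing sections, the traced contour is the inner
boundary of the tunica media — the pre-disease lumen — and the annotated
plaque area is subtracted from the media circle; negative remainders clamp
to zero with a warning.

**Profile.** Both chains are reduced to nine equidistant segments over
normalized vessel length (segment i covers [(i−1)/9, i/9), the last bin
closed). Diameters are averaged arithmetically within bins and converted to
areas by `πd²/4`. Exactly nine histology sections map index-to-segment;
otherwise positions are normalized and assigned to the nearest of nine bin
centres. Group summaries are per-segment mean ± SEM (SD/√n, ddof = 1);
time-point comparisons use one-way ANOVA on per-animal mean areas with
Bonferroni-corrected pairwise t-tests (raw p × number of comparisons, capped
at 1); per-segment group differences use unadjusted equal-variance
two-sample t-tests. Cross-modality agreement is OLS of modality A
(imaging) on modality B (reference) with Pearson r and the n−2 df t-test,
plus Bland-Altman bias and bias ± 1.96 SD limits of agreement.

## The phantom generator

The generator exists so every stage above can be validated against known
truth. A vessel is a tube of varying diameter around a uniform Catmull-Rom
spline through control points (the carotids are curved; a straight-tube
phantom would not exercise the tracer), optionally rescaled to a prescribed
arc length. Stenoses are cosine-squared constrictions
`d(t) = d₀ · Π (1 − sᵢ · cos²(π(t−pᵢ)/eᵢ))` on the normalized position t,
reaching `d₀(1−s)` at the centre; severity < 1 enforces the partial (never
total) occlusion of the ligation model. The tube terminates in hemispherical
caps (the natural geometry of a distance-to-centerline tube); analytic
volume oracles therefore use the capsule formula.

Rasterization: voxel intensity is
`background + (blood − background) · occupancy`, where occupancy is the
fraction of a 3×3×3 sub-voxel grid inside the tube's signed distance field —
sub-voxel partial-volume behaviour is the point, since threshold placement
at the wall is the dominant accuracy concern. Only the boundary shell is
supersampled; interior/exterior voxels are classified directly. The volume
is then blurred by a Gaussian PSF and corrupted by seeded Gaussian noise
(the calibrated quantities are a mean ± SD in arbitrary units, which
determines only second moments; Poisson physics is out of scope). A muscle
cuboid sits ten voxels beside the vessel for the calibration ROI. The
auto-fitted grid origin is offset by an irrational sub-voxel fraction per
axis so that synthetic geometry never aligns degenerately with the lattice
(an axis exactly on voxel centres puts the wall through lattice points and
distorts digitized volumes by up to 10% at small diameters — an alignment
real scans never produce).

Defaults are the study conditions: in vivo 18 µm isotropic voxels, blood
148.3 ± 2.0 intensity units; ex vivo 9 µm, 155.8 ± 1.6; vessel length
4.2 mm (nine 0.5 mm sections); diameters around 0.328 mm (ligated LCCA) and
0.454 mm (control RCCA). Muscle (100) and background (90) are free
parameters with no measured counterpart; background sits just below muscle
because the lumen borders perivascular soft tissue of near-muscle intensity —
the anatomy that makes the midpoint rule work. The PSF sigma defaults to
half a voxel, a realistic system blur at nominal resolution.

The virtual sectioner cuts perpendicular to the true centerline at 0, 0.5,
1.0, … mm. Each section starts as the true lumen circle, scaled by the
linear shrink factor (default 0.77; areas scale by 0.77² ≈ 0.59, i.e. a
~1.7× area underestimate, the magnitude histology typically shows against
in vivo CT), optionally deformed to an equal-perimeter ellipse of given
axis ratio (embedding compression deforms but does not destroy the wall, so
perimeter is conserved; the ellipse semi-axes follow in closed form from
the complete elliptic integral of the second kind), and annotated with a
plaque occupying a fraction of the shrunken media circle.

What the phantom does *not* emulate: X-ray physics (beam hardening, dose),
motion/gating artefacts, bifurcating geometry, stained-tissue texture,
non-circular true cross-sections, and observer variability in contour
tracing. Passing phantom tests therefore demonstrates the correctness and
calibration of the algorithms, not the biological accuracy of any specific
animal measurement.

## Numerical choices and accuracy floor

- **Distance convention.** The distance map reports distance to the nearest
  *background voxel centre* (a lone foreground voxel at spacing s has value
  s). Radii and diameters inherit this convention.
- **Quantization floor.** The chain "midpoint threshold → voxel mask →
  distance map at path voxels" carries a systematic diameter deficit of
  roughly one voxel: the threshold erodes the mask by ~0.1–0.2 voxel, path
  voxels sit up to half a voxel off the continuous medial axis, and an
  inscribed sphere near a constriction touches the approaching waist rather
  than the in-plane wall. Measured end-to-end: mean absolute diameter error
  ≈ 0.9 voxel across 8–30-voxel phantoms, hence per-segment area recovery
  within ~10% at ≥ 20-voxel diameters but only ~20–25% at 8 voxels. Vessels
  below ~10 voxels in diameter should be imaged at higher resolution rather
  than measured harder.
- **Steep features.** Because the inscribed sphere is three-dimensional,
  focal constrictions steeper than the sphere radius are smoothed in the
  diameter profile. The validation cohorts use gradual stenoses (0.8–1.7 mm
  transitions) matching the diffuse multi-segment lumen loss of the
  ligation phenotype; a focal web would be localized correctly but its
  depth underestimated.
- **Tie-breaks and determinism.** Equal-cost geodesics are resolved by the
  solver's deterministic node order; identical configs and seeds reproduce
  bit-identical volumes, traces and CSV outputs (checked via SHA-256 in the
  run manifest). All seeds are explicit — no wall-clock seeding anywhere.
- **NIfTI-2 output.** Volumes are written with float64 headers so spacing
  round-trips to 1e-9 mm; NIfTI-1's float32 pixdim cannot hold 0.018 mm to
  that precision.
- **Regression direction.** Agreement regresses imaging on histology
  (configurable by swapping inputs). OLS is used as specified; with noise on
  the reference modality OLS attenuates slopes (the motivation for Deming
  regression, deliberately out of scope).
- **ANOVA calibration.** The null-calibration experiment measures the
  omnibus one-way ANOVA rejection rate at α = 0.05 (nominal by
  construction); family-wise Bonferroni rates are conservative by design.

## Validation experiment sizes

The self-validation suite (also run by `scripts/acceptance.py`) uses: 50
random ≤ 8³ masks against a Bellman-Ford exhaustive-search oracle; 20
phantoms at 18 µm spanning 8–30-voxel diameters for diameter recovery; 12
vessels at the ex vivo 9 µm resolution for the shrinkage slope (the finer
grid isolates the shrinkage mechanism from voxel-scale segmentation bias);
2000 null simulations for ANOVA calibration; 10⁴ pairs for Bland-Altman
coverage; and a five-vessel, two-modality demo cohort run twice for
determinism. These sizes keep the whole validation run within a few minutes
on one CPU while leaving Monte-Carlo noise well below the asserted
tolerances.

## Known limitations

- Exactly one path per trace: no bifurcation detection or tree extraction.
- Plaque area is consumed as annotated planimetry, not segmented from
  images; media/adventitia morphometry beyond the inner-media perimeter is
  out of scope.
- No multi-class segmentation, bone removal, or in vivo/ex vivo
  registration.
- The paper-derived intensity calibration fixes only the blood mean ± SD;
  muscle/background contrast, and hence the contrast-to-noise ratio of the
  default scene, is a model choice.
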