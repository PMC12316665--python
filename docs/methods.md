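# Methods

## The measurement chain

A reconstructed ⁹⁹ᵐTc-PYP SPECT volume is converted to body-weight SUV,

    SUV = counts × CCF / (injected dose / body weight),

with counts in count/voxel, CCF in (Bq/mL)/(count/voxel), dose in Bq and
weight in g (1 g of tissue is taken as 1 mL, the usual SUV convention).
Two analyses run on the SUV volume: a *differentiation* analysis comparing
whole-heart uptake with aortic blood pool, and a *regional* analysis that
maps the left ventricle onto an AHA 17-segment polar map and condenses it
into heterogeneity/burden indices. Cohort-level statistics relate those
indices to each other and to echocardiographic measures of cardiac
function.

## Cross-calibration

The CCF is estimated from a uniform cylinder phantom (defaults: inner
diameter 160 mm, height 150 mm, ≈ 3016 mL) of known activity concentration
as `concentration / mean counts` over the cylinder interior. The averaging
mask is eroded inward by one PSF FWHM (default 8 mm) so that
partial-volume roll-off at the wall does not bias the mean; the
acquisition protocol does not state an averaging region, so the eroded
interior is this package's convention. No decay correction between
injection and acquisition is applied anywhere — an explicit, logged
assumption. A dose-protocol helper implements the weight-standardized
injection rule 555 × weight[kg]/60 MBq capped at 555 MBq.

## Differentiation metrics

* **SUV_H**: arithmetic mean over all voxels whose centres fall inside an
  ellipsoidal VOI enclosing the entire heart. Voxel membership is by
  voxel-centre inclusion with no partial-volume weighting — the simplest
  deterministic contract.
* **SUV_Ao**: the unweighted mean of the means of three cylinder VOIs
  (height fixed at 19.5 mm = five 3.9 mm pixels; diameter adjustable per
  subject) placed along the descending aorta. The alternative reading —
  pooling all voxels of the three cylinders — differs only when the VOIs
  have unequal voxel counts; mean-of-means is used and documented.
* **rSUV_H/Ao** = SUV_H / SUV_Ao. Dose and weight cancel, so the ratio is
  invariant to global rescaling of the volume.
* **H/CL**: mean counts in a circular heart ROI on the anterior planar
  image divided by the mean in an equal-area ROI mirrored across the image
  midline at the same height (the standard contralateral-lung convention;
  the ROI shape is not specified by clinical protocols in any detail).
* **Classification**: positive iff metric ≥ cutoff; a value exactly at the
  cutoff counts positive. Default H/CL cutoff 1.3; rSUV cutoffs of
  1.1–1.3 are exercised by the tests.

## Polar map

Short-axis slices orthogonal to the LV long axis are resampled by
trilinear interpolation at the volume's in-plane pitch, ordered base →
apex. Each slice's LV centre defaults to the centroid of pixels at or
above 50% of the slice maximum (clinical software does this with
proprietary heuristics; an explicit override is accepted). From each
centre, the maximum bilinearly interpolated SUV along `n_rays = 60` rays
(sampling step 0.5 pixel) forms one ring of the polar map; rings are
stacked base-outermost with the apex at the centre.

Parcellation follows the AHA model: rings split into basal/mid/apical
thirds by count; basal and mid rings into six 60° sectors (the anterior
sector spans 60°–120° from the anterior reference, angles increasing
counterclockwise viewed from the apex); apical rings into four 90°
sectors; and an apex-cap disk (segment 17) overrides the innermost
⌈10 %⌉ of rings. Populating all 17 segments therefore needs the apical
third to exceed the cap — at least ~7 rings; clinical stacks have 10–20.
Per-segment statistics use the population SD (denominator *n*), treating a
segment's cells as the complete description of its dispersion; `ddof=1` is
available and tested. Rendered maps use the conventional SUV display
ceiling of 4.0.

The analysis stack stops one voxel short of the epicardial apex: the final
half-voxel of the tip is pure partial volume and would register an
artificial dispersion in segment 17 even on a noiseless uniform shell.

## Regional indices

With `m_s` the mean SUV of segment `s`:

* Summed SUV over a region is `Σ m_s` for anterior {1,7,13}, septal
  {2,3,8,9,14}, inferior {4,10,15}, lateral {5,6,11,12,16}, apical {17};
  the second scheme uses basal {1–12} vs apical {13–17}.
* Total cardiac SUV = `Σ₁₇ m_s`; "Summed SUV_All" in the %DS/%BA formulas
  is this total — the only reading consistent with the packaged table,
  where basal + apical reproduces the printed total on every row.
* COV = `Σ₁₇ (SD_s/m_s × 100)`; %DS = (septal − lateral)/All × 100;
  %BA = (basal − apical)/All × 100.

Indices operate on unweighted segment means (the summed-SUV formula sums
per-segment SUVs; cell counts do not enter). Note that a perfectly uniform
heart has %BA = 700/17 ≈ 41.2 because the basal region holds 12 segments
against the apical region's 5 — %BA measures gradient *relative to that
baseline*, not deviation from zero.

## Statistics

* Pearson r with the two-tailed t-transform p (n − 2 df). Missing echo
  values are handled by pairwise-complete deletion.
* Kruskal–Wallis with tie correction (scipy); an all-identical sample
  returns H = 0, p = 1 rather than an error.
* Steel–Dwass: each pair of groups is re-ranked jointly; the rank-sum
  statistic is standardized with the tie-corrected variance
  `n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))]` and √2·|t| is referred to the
  studentized range with k groups and infinite df (computed by direct
  quadrature of the normal-range distribution; this matches scipy's
  studentized-range tail at df → ∞ to ~1e-12). An exact mode enumerates
  every reassignment of the pooled values to groups of the observed sizes
  (feasible to ~8 per group, three groups) and reports max-T permutation
  p-values, the exact analogue of the range-based family-wise adjustment.
  With k = 2 the reference reduces to the two-sided normal, i.e. the
  ordinary Wilcoxon rank-sum approximation.
* Fisher: 2×2 via the exact hypergeometric two-sided test; 2×k overall via
  Freeman–Halton enumeration of all tables with the observed margins,
  summing probabilities ≤ the observed table's (with a 1e-9 relative
  slack against ties in floating point). Pairwise 2×2 p-values are
  Bonferroni-multiplied by the number of pairs and capped at 1.

## The phantom: what it emulates and what it does not

The generators emit *post-reconstruction* volumes directly: a noiseless
activity-concentration map is blurred with an isotropic Gaussian PSF
(default FWHM 8 mm, the clinical reconstruction filter) and then
Poisson-sampled when a seed is set (expected counts = concentration ×
`count_scale`). Projection physics, OSEM, scatter and CT attenuation
correction are deliberately not simulated — the indices operate on
reconstructed images, and blur + noise emulate the net effect.

Geometry (defaults; 128³ grid of 3.9 mm voxels, from the 19.5 mm =
five-pixel anchor): the LV is an ellipsoidal shell, outer semi-axes
(35, 35, 55) mm, inner (22, 22, 41) mm — a hypertrophic ATTR-like wall of
~13 mm. The apex half of the outer ellipsoid holds the shell and LV
cavity (blood); the basal half is blood pool standing in for the atria
and right heart. Segment labels are assigned geometrically (long-axis
thirds × the same angular sectors as the polar map, solid tip = apex cap)
*before* blurring, so ground truth is exact and parameter-recovery tests
are meaningful. Lungs are two low-uptake boxes lateral to the heart; the
descending aorta is a cylinder posterior to it. There are no ribs (a
planar-imaging confounder only), no anthropomorphic anatomy, no motion.
Consequences: planar H/CL ratios are realistic only in ordering, not in
magnitude (no soft-tissue background), and passing tests demonstrate
correctness of the measurement chain, not clinical performance on
patients.

Each phantom draws every stochastic quantity from a single seed;
realisations are bit-reproducible.

`GroundTruth.true_indices` applies the same index formulas to per-segment
voxel statistics of the noiseless concentration map. On a uniform shell
the polar-map chain reproduces them essentially exactly; with strong
segment gradients the polar-map %DS is diluted towards zero (by roughly a
quarter at 2× septal contrast) because rays near sector boundaries pick up
the neighbouring segment's interpolated values and the apex-cap rings mix
into the apical sectors. This is a property of radial-maximum bullseye
mapping itself, shared by the clinical software; tests therefore assert
exact recovery only for uniform shells, and sign, monotonicity and
rank-order for graded ones.

## Synthetic differentiation cohort

The seeded cohort used to exercise the rSUV_H/Ao classifier contains 20
ATTR-like subjects with myocardium/blood concentration ratios drawn
uniformly from 2.5–4.0 and 20 controls with ratios 0.8–1.0, on 64³ grids
of 4 mm voxels with 8 mm PSF and `count_scale = 0.05` (≈ 50 expected
counts/voxel in blood). Those ratio ranges put the simulated SUV_H,
SUV_Ao and rSUV_H/Ao inside the clinically reported ATTR and
non-amyloidosis ranges (ATTR rSUV ≈ 1.4–2.3 vs control ≈ 0.85–0.93 under
this geometry). Dose/weight are fixed at 70 MBq / 70 kg so blood-pool SUV
is 1.0 by construction. The heart sits 40 mm lateral of the midline so the
mirrored planar ROI falls over the contralateral lung.

## Synthetic echo parameters

`synth_echo` adds echocardiographic columns as affine transforms of a
chosen index plus Gaussian noise, the slope chosen so the *population*
Pearson correlation equals the requested value (sample correlations
scatter around it; ±1 requires zero noise and is exact). This supports
testing the correlation machinery at stated strengths without patient
echo data.

## Numerical notes and edge cases

* Interpolation is trilinear/bilinear (`scipy.ndimage.map_coordinates`,
  order 1, zero outside). A constant input can acquire last-ulp
  perturbations, so "COV = 0 for a uniform stack" holds to ≤ 1e-9, not to
  the bit.
* Negative reconstructed counts are clamped to zero at SUV conversion and
  logged.
* Division errors (zero segment mean in COV, zero total in %DS/%BA, zero
  aortic SUV) raise with the offending quantity named.
* Problem sizes used by the test suite and the acceptance script: 96³
  noiseless phantoms for gradient recovery, 64³ for the 40-subject
  differentiation cohort, 128³ calibration cylinders, and exhaustive
  enumeration (126 126 partitions) for the Steel–Dwass oracle at k = 3,
  n = 5.

## Known limitations

* VOI placement is explicit input; there is no CT-based auto-segmentation.
* Only body-weight SUV is implemented (no SUVlean/SUVbsa).
* The polar-map parcellation cannot populate all 17 segments from stacks
  of fewer than ~7 slices (the apex cap would swallow the apical third);
  `segment_stats` raises a parcellation error in that case.
* Whether the clinical workflow decay-corrects the injected dose to scan
  time is unknown; none is applied here.
* Echo parameters are synthetic correlates, not physiology.
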