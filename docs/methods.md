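# Methods

`radialpos` quantifies the radial nuclear position of chromosome
territories two ways: a 2D equal-area concentric-shell ("erosion")
analysis of flattened, DAPI-counterstained FISH images, and a 3D
center-to-periphery distance analysis of structurally preserved nuclei
imaged as confocal stacks. Both are validated end-to-end against a
synthetic-nucleus generator with known ground truth.

## 2D erosion analysis

**Model.** The nucleus is whatever the DAPI channel segments as one
connected object (Otsu's inter-class-variance threshold on the channel
histogram, holes filled, largest component kept, minimum area 20 μm² to
reject debris). The nucleus is partitioned into `n_shells = 5`
concentric shells of equal area: pixels are ranked by their Euclidean
distance transform value (distance to the nearest background pixel,
physical spacing respected) and the ranked list is cut into five equal
blocks — shell 1 the most peripheral, shell 5 the most interior. For
each shell the percentage of total probe intensity is divided by the
percentage of total DAPI intensity, giving a per-nucleus normalized
profile in which 1.0 means "distributed like bulk DNA". Cohorts of
50–70 nuclei are summarized by the per-shell mean ± SEM (sample SD,
n−1) of the normalized profiles; no background subtraction is applied
to either channel.

**Why distance-transform quantiles instead of literal repeated
erosion.** Both constructions realize "concentric shells of equal
area", but on a discrete grid iterated morphological erosion yields
shells whose areas depend on boundary roughness and structuring
element, while quantile cuts guarantee equal areas up to ties. Pixels
sharing one distance value that straddles a cut are assigned as a block
to the shell holding the majority of the tie group (lower shell on an
exact split), which makes the partition deterministic and invariant
under grid rotations of the mask. On a solid disk of radius R the cut
radii converge to the analytic equal-area annuli `R·sqrt(1−k/5)`
(within one pixel at R = 50, checked in the tests).

**Statistics.** Condition comparisons use the unpaired, unequal-variance
(Welch), two-tailed t-test per shell, with unrounded
Welch–Satterthwaite degrees of freedom, each shell at α = 0.05 with no
multiple-testing correction — the per-shell flags mirror how erosion
histograms are annotated in practice. The lack of correction is a
deliberate caveat: with five shells, the family-wise false-positive
rate is higher than 5%. A DNA-content control applies the same test to
the raw per-shell DAPI percentages; a probe relocation should leave it
flat. Degenerate inputs are defined explicitly: two groups that are
identical and constant compare as t = 0, p = 1.

**Position classification.** A cohort's radial position is summarized
by the center-of-mass index of its mean normalized profile,
`com = Σ k·m_k / Σ m_k` (k = 1..5), and classified peripheral (P),
intermediate (IM) or interior (I) by two thresholds on that index. The
index is scale-invariant. The default thresholds (3.114, 3.932) are a
calibration, not round numbers, for a geometric reason: shells have
equal *area*, so on a disk half the area lies outside 71% of the
radius, and a territory at mid-radius (radial fraction r = 0.5)
occupies shells around index 3.5–4, not 3. Symmetric cut points around
3 cannot separate peripheral, mid and interior placements for any
territory size. The defaults are therefore the midpoints of the cohort
com-index measured on noiseless-by-construction synthetic cohorts at
the three canonical anchor fractions r = 0.85, 0.50 and 0.15 (300
nuclei per anchor, generator defaults, fixed seed);
`calibrate_position_thresholds()` reproduces them. The classifier is a
surrogate validated on synthetic ground truth only — the thresholds are
exposed in the API for anyone preferring a different convention.

## 3D distance analysis

The territory's geometric center is the unweighted centroid of its
segmented voxels ("geometric center" read literally, not
intensity-weighted). The nuclear periphery is the set of DAPI-mask
voxels with at least one background 6-neighbor (26-connectivity is used
for component labelling, the 6-neighborhood for the periphery). The
reported distance is the minimum anisotropic Euclidean distance from
the center to any *exposed voxel face midpoint* — each periphery voxel
center shifted half a step toward each background neighbor. Because the
true boundary crosses every center-to-background-neighbor segment, each
sample lies within half a step of a true surface point, so the
discretization error is bounded by half the coarsest voxel dimension
(0.1 μm at the default (0.2, 0.1, 0.1) μm spacing); distances to
periphery voxel *centers* would instead be biased inward by up to a
full step. The tests verify exact agreement with an independent
brute-force enumeration of the same convention and the half-voxel bound
on digitized spheres and ellipsoids.

Distances are reported raw (μm) and normalized by nuclear size, either
by (major+minor)/2 or by the major axis alone; axes are measured by
second central moments (full axis = 4·√eigenvalue of the coordinate
covariance, exact for solid ellipses) on the maximum-area z-slice,
since flattened fibroblast nuclei are essentially 2D ellipses in every
section. Cohort orderings of median distance are checked to be
invariant across the three scales (`rank_invariance_check`). Frequency
distributions use half-open 0.5 μm bins from zero (configurable).

## Synthetic data generator

The generator emulates the imaging design the measurements come from:
flattened elliptical nuclei, nominal in-plane semi-axes 10.0 × 6.5 μm
at 0.2 μm/pixel (2D) and flattened ellipsoids with a 2.0 μm axial
semi-axis sampled at (0.2, 0.1, 0.1) μm (3D); per-nucleus axis jitter
(5% SD, multiplicative) and orientation jitter (15° SD); uniform DAPI
plateau (level 100, optional radial gradient) plus additive Gaussian
noise (SD 10, clipped at zero) on both channels. Each territory is an
isotropic Gaussian blob of σ = 2 μm — a few-μm-wide territory in a
~20 μm nucleus — with fixed peak amplitude 1.5× the DAPI level, centered
at radial fraction r of the center-to-boundary ray along a random
direction. Default cohort sizes are 60 nuclei (2D) and 20 (3D).

What it does **not** emulate: chromatin texture, nucleoli, irregular
nuclear outlines, the microscope PSF, Poisson photon statistics, and
touching nuclei. Passing tests therefore demonstrate that the
*measurement procedure* is correct and well calibrated on idealized
images with known truth — not that segmentation is robust on real
micrographs.

Seeding: each nucleus uses `default_rng(seed + index)`, so cohorts are
bit-reproducible and order-independent; regenerating a cohort yields
identical images.

## Numerical choices and degenerate inputs

- Otsu thresholding uses `skimage.filters.threshold_otsu`; territory
  thresholds are computed from probe intensities *inside* the nucleus
  only.
- Equal-size components are disambiguated by labelling (scan) order —
  deterministic.
- Shell percentages must sum to 100 within 1e-6 (enforced by the
  `ShellProfile` invariant); zero total probe or a zero-DAPI shell
  raise typed errors rather than producing NaNs.
- Welch p-values use the t-distribution survival function with
  unrounded degrees of freedom.
- All physical coordinates are voxel centers; grids are (row, col) /
  (z, y, x), 0-based; distances are in μm.

## Problem sizes used in validation

The acceptance script and the cohort-scale tests use 100 replicates for
position recovery and detection power and 200 replicates for the
false-positive calibration, each replicate a full 60-nucleus cohort
pipeline run (segmentation → partition → profile → statistics), plus
two 20-nucleus 3D cohorts — about 55,000 synthetic nuclei in total,
chosen to estimate rates with ~2–5 percentage-point Monte-Carlo error.

## Known limitations

- The P/IM/I classifier is calibrated to this generator's geometry; on
  real nuclei with different shapes or territory sizes the thresholds
  would need recalibration against a reference set.
- No multiple-testing correction across shells or chromosomes.
- Segmentation is global-threshold based and assumes one nucleus per
  field with good DAPI contrast.
- The 3D axis normalization uses in-plane axes of the widest section,
  which underestimates size effects for nuclei that are not flattened.
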