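# Methods

## Thickness by maximal inscribed sphere

Local cortical thickness at a landmark is defined geometrically: the
diameter of the largest sphere that contains the landmark and lies entirely
inside the binary gray-matter segmentation. The implementation discretizes
this definition:

* Candidate sphere centers are restricted to foreground **voxel centers**;
  no subvoxel optimization is attempted. This keeps the search deterministic
  and exhaustively checkable, at the cost of a discretization error bounded
  by one voxel (0.2 mm at the intended 0.2 mm isotropic resolution).
* Each candidate `c` carries radius `r(c) = d(c) − h/2`, where `d(c)` is the
  Euclidean distance from `c` to the nearest **background voxel center**
  (computed with an exact Euclidean distance transform honoring anisotropic
  spacing; positions outside the grid count as background, realized by one
  layer of zero padding) and `h` is the smallest axis spacing. The half-voxel
  margin prevents balls that graze the interior of background voxels, and
  makes the measurement *exact* for axis-aligned slabs with an odd number of
  foreground planes: a k-plane slab at spacing s yields diameter k·s.
* "Overlapping the dot" means the dot lies in the closed ball:
  `‖c − dot‖ ≤ r(c)`, evaluated with a 1 nm slack (1e-9 mm) to absorb float
  round-off at exact tangency. Ties in radius are broken by distance to the
  dot, then by lexicographic voxel index, so results are reproducible.
* The search is limited to candidates within `search_radius_mm` of the dot
  (default 10 mm, the scale of the gray-matter patch segmented around each
  landmark). A landmark with no admissible candidate returns an *invalid*
  fit — a value, not an exception — so cohort pipelines degrade to
  missingness the way damaged-tissue locations do in practice.
* Per subregion, the diameters at the (up to) two landmark locations are
  averaged over the locations that produced a valid fit, and the per-location
  values are retained for anterior/posterior analyses.

Accuracy contract, verified by the test suite: exact agreement with an
exhaustive brute-force search (every foreground center as candidate,
nearest-background distance by direct nearest-neighbor query, ball
containment verified voxel-by-voxel) on random masks; exact recovery for
odd-plane slabs; absolute error at most two voxels for tilted slabs and
spherical shells. Whether an off-grid sphere center could do better is
outside this contract.

## Synthetic phantoms

`make_phantom` voxelizes analytic geometries whose local thickness is known
in closed form — a slab of thickness t (axis-aligned or tilted; truth t)
and a spherical shell with inner radius a and outer radius b (truth b − a)
— marking a voxel foreground exactly when its center lies inside the
geometry. Tears are axis-aligned boxes of background carved from the
foreground: the simplest defect that reproduces the missing-measurement
mechanism of torn tissue. Landmarks are placed on the medial surface (slab
center plane, shell mid-radius), rejected and resampled until they are
strictly inside the foreground and at least the local thickness away from
every tear and grid boundary, so the analytic truth holds at each dot. The
phantoms do not attempt anatomy-shaped meshes, MRI intensities or bias
fields; they exercise the geometry of the measurement, nothing else.

## Cohort simulator

`simulate_cohort` emulates the structure of a brain-donor cohort:

* **Latent severities.** Per donor, one latent severity per lesion (tau,
  amyloid-β, TDP-43, α-synuclein) from a multivariate normal whose
  correlation matrix models comorbidity (defaults: 0.4 tau–amyloid, 0.3
  tau–TDP-43, 0.2 elsewhere). Latent means (1.4, 0.5, −0.6, −1.2) order the
  lesions by prevalence, tau nearly ubiquitous and α-synuclein rare.
* **Ordinal scores.** Each composite region (CA1/SUB, ERC, dentate gyrus)
  adds independent N(0, 0.25) jitter to the lesion latent and thresholds it
  at cut points (0.2, 0.8, 1.5, 2.3) onto {0, 0.5, 1, 2, 3}, giving the
  right-skewed marginals typical of semi-quantitative ratings. A/B/C staging
  scores threshold the amyloid (A, C) and tau (B) latents at cut points set
  to resemble a mixed-neuropathology autopsy series; B is occasionally
  missing (primary tauopathies can defy Braak staging).
* **Thickness.** Subregion thickness = baseline + Σ slope×composite +
  age_effect·(age − 75) + sex_effect·male + N(0, noise_sd). Slopes are
  *mm per unit composite score*, negative = thinning; defaults give tau a
  circumscribed effect (ERC −0.25, BA35 −0.30, CA1 −0.20, SRLM −0.10) and
  TDP-43 a diffuse −0.30 across all seven subregions, with
  age_effect −0.01 mm/yr, sex_effect +0.05 mm (male), noise_sd 0.4 mm.
  Baselines (ERC 2.6, BA35 2.8, BA36 2.9, PHC 2.4, SUB 2.2, CA1 1.5,
  SRLM 0.5 mm) are plausible fixed-tissue values with SRLM the thin dark
  band. Each of the two per-subregion locations jitters by N(0, 0.1) and
  goes missing independently with probability 0.05.
* **Demographics.** Age ~ N(75, 11²) clipped to [44, 97]; 60.3% male;
  hemisphere balanced. Default n = 58 donors.

One `numpy.random.Generator` seeded by a single integer drives everything;
a fixed spec reproduces the cohort byte-identically.

What passing tests show — and do not. The simulator produces exactly the
linear-on-composite, Gaussian-noise world the statistics assume, so
calibration and recovery results certify the estimator, not the biology:
real specimens add fixation effects, hemisphere selection bias, non-linear
dose–response and diagnosis-driven comorbidity structure that the generator
does not model. The ordinal marginals are a modeling choice; no published
per-donor score distribution exists to reproduce.

## Statistics

* **Ranking.** Average ranks on ties (the conventional Spearman treatment);
  missing values excluded from ranking and propagated as missing.
* **Partial correlation.** Precision-matrix formula on the rank correlation
  matrix, p from t with n − 2 − k degrees of freedom — the conventions of
  the standard partial-rank-correlation packages. The test suite pins the
  semantics two independent ways: against double residualization (regress
  x- and y-ranks on covariate ranks, correlate residuals; agreement to
  1e-10) and against `pingouin.partial_corr`.
* **Complete cases per cell.** Each (lesion, subregion) cell determines its
  own complete cases, so every column reports its own n; a listwise mode is
  available by flag. Cells with fewer than k + 3 complete cases are
  reported absent with a reason, not raised.
* **Degenerate inputs.** Perfectly rank-correlated x and y would make the
  rank correlation matrix singular; this case is detected first and returns
  estimate ±1 with the smallest representable positive p and a warning.
  A condition number above 1e12 (collinear covariates) is an error naming
  the variables.
* **Two conditioning modes.** `covariates_only` conditions on age, sex and
  hemisphere; `covariates_plus_other_pathologies` additionally conditions
  each lesion on the other three composites ("all pathologies in the same
  model"). Subsets: full, amyloid-negative (A-score 0 or 1; strict — a
  missing A-score is an error), and amyloid-negative + TDP-low (composite
  TDP-43 < 0.5, strictly below the cut).
* **Interactions.** No specific model family is canonical for rank-scale
  interaction tests; this package fits OLS of outcome ranks on the ranks of
  both exposures, their product of mean-centered ranks, and covariate
  ranks, and t-tests the product term. Reports flag these as rank-scale
  interpretations.
* **Sex-stratified analyses** rerun the matrix per stratum with sex removed
  from the conditioning set.
* Two-sided p-values throughout; significance tiers at strict thresholds
  0.10 (trend) / 0.05 / 0.01 / 0.001; no multiple-comparison correction by
  default (Holm behind a flag).

## Pipeline

`run_pipeline` joins thickness and cohort tables on `donor_id` (specimens
without cohort rows are dropped with a logged warning; zero overlap is an
error), writes the bundle (thickness CSV, full and amyloid-negative
summaries, one correlation table per analysis as CSV and Markdown, a
provenance record with the config hash, seed, per-cell sample sizes and all
behavioral flags), and is byte-identical across reruns at the same seed —
the timestamped log file being the only exception. Default analyses: all
four pathologies in one model on the full cohort; tau-only in the
amyloid-negative subset; tau-only in the amyloid-negative + TDP-low subset.

## Verification problem sizes

The acceptance checks run the sphere-fit oracle on 200 random masks of up
to 25³ voxels (exact nearest-neighbor brute force), the partial-Spearman
oracle on 1,000 random problems (n = 12–80, k = 1–4, with ties), type-I
calibration on 2,000 independence replicates at n = 58, and sign recovery
on 500 simulated cohorts with a −0.3 mm/unit tau→BA35 slope at 0.4 mm
noise. These sizes give stable Monte-Carlo estimates (binomial SE ≈ 0.005
on the rejection rate) while the whole script completes in well under a
minute.

## Known limitations

* Sphere centers are grid-bound; sub-voxel landmark placement shifts the
  admissible set and can change the diameter by up to one voxel.
* The distance transform assumes an axis-aligned affine; rotated NIfTI
  orientations are not resolved.
* Composite scores average over present regions (missing regions shrink the
  denominator); a strict mode propagates missingness instead.
* The interaction test's rank-scale product term is an interpretation, not
  a canonical definition; raw-scale alternatives would differ.
* The simulator draws regional scores from a shared lesion latent plus
  independent jitter — real regional gradients (e.g. anterior-predominant
  TDP-43) are not modeled, so per-location analyses exercise plumbing, not
  anatomy.
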