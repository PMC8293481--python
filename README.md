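# mtlmorph

Tools for studying how comorbid neurodegenerative pathologies relate to the
thickness of medial temporal lobe (MTL) subregions measured on ultra-high
resolution (0.2 mm isotropic) postmortem MRI.

The MTL — entorhinal cortex (ERC), perirhinal cortex (BA35/BA36),
parahippocampal cortex (PHC), subiculum (SUB), CA1 and the stratum radiatum
lacunosum moleculare (SRLM) — is an early target of tau, TDP-43, amyloid-β
and α-synuclein pathology. `mtlmorph` implements the three pieces needed to
relate semi-quantitative burden ratings of those pathologies to subregional
neurodegeneration, plus a synthetic-data generator so the whole pipeline is
testable without specimen data:

1. **Landmark-based sphere thickness.** At an anatomical landmark (a "dot")
   inside a binary gray-matter segmentation, local thickness is the diameter
   of the sphere that overlaps the dot, is fully contained in the
   segmentation, and has maximum possible radius:

   `T(dot) = 2 · max { r(c) : c foreground voxel center, ‖c − dot‖ ≤ r(c) }`

   where `r(c) = d(c) − h/2`, `d(c)` is the Euclidean distance (mm, honoring
   anisotropic spacing) from `c` to the nearest background voxel center and
   `h` the smallest axis spacing. Each subregion is measured at two
   anterior–posterior locations and averaged; an unmeasurable location
   (tear, damage) degrades to a missing value, never an exception.

2. **Composite semi-quantitative pathology scores.** Regional lesion burden
   is rated on the ordinal scale none/rare/mild/moderate/severe =
   0/0.5/1/2/3; the composite MTL score per lesion is the mean of the
   CA1/SUB, ERC and dentate-gyrus ratings. Cohort subsets: amyloid-negative
   (A-score 0 or 1) and TDP-low (composite TDP-43 < 0.5).

3. **Partial Spearman correlation.** For exposure x, outcome y and
   covariates Z (age, sex, hemisphere, optionally the other lesion
   composites), all variables are rank-transformed on the complete cases and

   `r_xy·Z = −P_xy / √(P_xx · P_yy)`, `P = R⁻¹`

   with R the rank correlation matrix; p-values from
   `t = r·√((n−2−k)/(1−r²))` on `n−2−k` degrees of freedom. Interaction and
   sex-stratified analyses run on the same rank scale. No
   multiple-comparison correction is applied by default.

## Worked example

```python
import numpy as np
from mtlmorph import (PhantomSpec, make_phantom, fit_max_sphere,
                      CohortSimSpec, simulate_cohort, AnalysisSpec, correlation_matrix)
from mtlmorph.stats import encode_covariates, matrix_to_wide

# a 2.2 mm plate phantom measured with the maximal-sphere method
spec = PhantomSpec(shape=(41, 41, 41), spacing=(0.2, 0.2, 0.2),
                   geometry="slab", geometry_params={"thickness_mm": 2.2},
                   subregions=("ERC",), seed=0)
mask, landmarks, truth = make_phantom(spec)
fit = fit_max_sphere(mask, landmarks[0])
print(f"measured diameter: {fit.diameter:.2f} mm (truth {truth[('ERC', 1)]} mm)")

# a simulated 58-donor cohort analyzed with all pathologies in one model
cohort = encode_covariates(simulate_cohort(CohortSimSpec(n_donors=58, seed=1)))
results = correlation_matrix(cohort, AnalysisSpec(name="full_all_pathologies"))
print(matrix_to_wide(results).to_string())
```

prints

```
measured diameter: 2.20 mm (truth 2.2 mm)
                    ERC      BA35   BA36    PHC    SUB      CA1   SRLM
Sample size          57        58     58     58     57       58     57
tau              -0.28*  -0.51***  -0.19  -0.09  -0.23  -0.41**  -0.19
amyloid_beta     -0.26a     -0.10  -0.10   0.03  -0.03     0.02  -0.21
TDP43             -0.12     -0.09  -0.15  -0.17  -0.22   -0.35*  -0.10
alpha_synuclein    0.02      0.17   0.03  -0.01   0.09     0.03   0.13
```

The phantom's known 2.2 mm thickness is recovered exactly (an odd number of
foreground planes makes the discrete search exact). In the simulated cohort
the generator's built-in tau effect on ERC/BA35/CA1/SRLM shows up as
negative partial correlations (markers: `a` p<0.10, `*` p<0.05, `**` p<0.01,
`***` p<0.001); each column keeps its own complete-case sample size, as
per-location missingness differs by subregion.

A CLI wraps the same functionality:

```sh
mtlmorph simulate --seed 1 --n-donors 58 --outdir sim/
mtlmorph measure  --mask-dir masks/ --landmarks-csv landmarks.csv --out thickness.csv
mtlmorph analyze  --cohort-csv sim/cohort.csv --subset full --subset A_negative
mtlmorph run      --seed 1 --outdir results/
```

`mtlmorph run` produces the full bundle: a thickness table, demographic
summaries for the full cohort and the amyloid-negative subset, one
correlation table per configured analysis (by default: all pathologies in
the full dataset; tau-only in the amyloid-negative subset; tau-only in the
amyloid-negative + TDP-low subset), and a provenance record. Bundles are
byte-identical across reruns of the same seed.

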