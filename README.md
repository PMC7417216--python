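# ocellus

Eyespot allometry and ontogenetic presence in coral reef fishes.

Many reef fishes carry an *eyespot* (ocellus): a dark, roughly circular
"pupil" wrapped in a pale ring, resembling a vertebrate eye. Two
questions drive this package, aimed at researchers analysing specimen
collections of eyespot-bearing fishes:

1. **How does eyespot size scale with eye size?** Matched eye/eyespot
   measurements (diameters, areas) are compared by phylogenetic
   generalized least squares (PGLS): for response y and predictor x
   over specimens, β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y with V the Brownian-motion
   covariance of a species tree carrying zero-length *replicate tips*
   for conspecific specimens, plus an ML-estimated specimen-level
   white-noise component. Isometry (slope 1, intercept 0 on raw mm/mm²
   scales) is tested per model, and models are compared by 95% CI
   overlap of their slopes and intercepts.
2. **At what body size are eyespots gained and lost?** A bootstrap
   resamples one specimen per species within each presence state and,
   per iteration, fits a gamma GLM (log link) of standard length on
   presence and a logistic regression of presence on standard length.
   The *50–50 point*, −intercept/slope on the logit scale, is the
   standard length at which a fish is equally likely to have or lack an
   eyespot (an ED50 analogue).

A synthetic-data module generates specimen tables and trees with known
truth (isometric eyespots, a 4× enlarged eyespot pupil at the gain
size, a gain-near-20-mm / loss-near-80-mm presence window), so the whole
pipeline is testable without any data download.

## Worked example

```sh
ocellus simulate --out demo --seed 3
ocellus report --data demo/specimens.csv --tree demo/tree.nwk \
    --out demo/report --iterations 50 --seed 3
```

which logs:

```
INFO ocellus: 1086 specimens: 544 with eyespot (50.1%), 542 without (49.9%)
INFO ocellus: 50-50 point over 50 iterations: mean 78.71 mm, median 78.96 mm
    (range 76.17-81.01); mean gamma p 1.039e-46
```

Half the simulated specimens carry an eyespot, and across bootstrap
iterations a fish is equally likely to have or lack one at ≈ 79 mm
standard length — the generator's loss window is centred on 80 mm, so
the pipeline recovers the truth. `demo/report/pgls_coefficients.csv`
holds the four regressions (area and linear variants, two terms each);
for this run the eye-area model gives slope 1.006 (95% CI 0.997–1.014)
with intercept −0.24 (CI −0.64–0.16), i.e. eyespot area matches eye
area one-to-one, while the eyespot-pupil model keeps slope ≈ 1 (0.996,
CI 0.983–1.010) but an intercept of 8.54 mm² above zero — the eyespot's
pupil is
systematically enlarged. `demo/report/pgls_comparison.json` records the
verdict: same slopes, different intercepts.

The same subcommands accept real data: a specimen CSV with columns
`species_id, specimen_id, standard_length_mm, eyespot_present` (0/1),
optionally the eight measurement columns
`eye_diameter_mm, pupil_diameter_mm, eyespot_diameter_mm,
eyespot_pupil_diameter_mm, eye_area_mm2, pupil_area_mm2,
eyespot_area_mm2, eyespot_pupil_area_mm2`, and a rooted Newick tree
with branch lengths whose tips match `species_id`.

## Library use

```python
import numpy as np
from ocellus import (GeneratorConfig, simulate_tree, simulate_dataset,
                     fit_feature_regressions, BootstrapConfig, run_bootstrap)

cfg = GeneratorConfig(seed=1)
tree = simulate_tree(cfg.n_species, np.random.default_rng(cfg.seed))
dataset, truth = simulate_dataset(tree, cfg)
fits, table = fit_feature_regressions(dataset, tree)
boot = run_bootstrap(dataset, BootstrapConfig(n_iterations=250, seed=2))
print(fits["eye_area"].slope, boot.mean_5050_mm)
```

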