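# gelflux

Analysis of solitary sinking phytoplankton cells captured in sediment-trap
**gel layers**, for biological-oceanography and carbon-export studies.

Most phytoplankton carbon leaves the surface ocean packaged inside large
detrital particles — aggregates and fecal pellets. Gel layers at the bottom
of trap tubes preserve sinking particles intact and separated, which makes a
usually invisible pathway countable: individual cells sinking on their own
through the mesopelagic. `gelflux` turns gel counts and bulk chemistry into
fluxes with honest uncertainties and asks the downstream questions: how much
carbon do solitary cells carry relative to bulk POC, how do their
communities differ across depth and time, do their fluxes co-vary with
detrital particle classes, and how fast must they have been sinking?

## What it computes

* **Number and carbon fluxes** — `count / (area × duration)` with Poisson
  counting uncertainty (`√N` errors), bulk POC fluxes from replicate splits,
  spherical-biovolume carbon per cell (`C = a·V^b`, diatom allometry),
  percent-of-bulk-POC, depth averages and fold changes, and the
  gel-vs-bulk *solitary fraction* partitioning cells sinking alone from
  cells embedded in detritus.
* **Community structure** — Bray-Curtis dissimilarity (`Σ|x−y|/Σ(x+y)`),
  PERMANOVA with permutation p-values (exact enumeration at small n),
  metric MDS ordination, and a threshold network (dissimilarity < 0.25)
  whose connected components are the distinct sinking communities, with
  per-cluster mean compositions.
* **Covariation** — Spearman rank correlation with permutation p-values and
  PCA loadings of min-max-normalised flux features (cells vs detrital
  particle classes).
* **Sinking speed** — the geometric capture floor (tube height / deployment
  duration) and a rigid-translation inversion: the depth-integrated flux
  loss of a taxon between deployments, `ΔI = ∫early − ∫late`, is matched to
  the bottom-`d`-meters integral of the earlier profile,
  `∫_{z_max−d}^{z_max} early(z) dz = ΔI`, solved by bisection;
  `speed = d / Δt`.
* **Synthetic campaigns** — a first-class generator
  (`ScenarioConfig` / `generate_scenario`) producing the four input tables
  with known ground truth: Poisson counts, lognormal replicate-platform
  variability (CV constrained to the observed 22–79% band), configurable
  depth shapes including a Gaussian layer translating at a known speed, and
  copula-coupled detrital fluxes.

## Worked example

Simulate a recycling-system campaign with a deep diatom layer translating at
6.6 m d⁻¹, densely instrumented between 240 and 500 m, then run the full
pipeline:

```python
import numpy as np
import gelflux as gf
from gelflux.io import write_dataset

base = gf.ScenarioConfig.north_pacific_like(seed=11)           # layer at 6.6 m/d
cfg = gf.ScenarioConfig(**{**base.__dict__,
                           "depths_m": tuple(np.arange(240.0, 501.0, 20.0))})
write_dataset(gf.generate_scenario(cfg), "demo/data")

res = gf.run_pipeline(gf.AnalysisConfig(
    input_dir="demo/data", output_dir="demo/out", seed=11,
    sinking_taxon="Fragilariopsis", sinking_deployments=(2, 3)))
print(res["community"]["permanova"].summary())
print(res["covariation"]["spearman"].summary())
print(res["sinking"].summary())
```

Output:

```
PERMANOVA: pseudo-F = 1.617, p = 0.16 (permutation, 999 permutations, n = 84, groups = 3)
Spearman rank = -0.347, p = 0.003 (permutation, n = 84)
Rigid-translation sinking-speed inversion
  taxon:                 Fragilariopsis
  depth window:          240-500 m
  net integrated loss:   4.282e+06 (flux x m)
  translation depth d:   41.56 m
  time between profiles: 7.00 d
  sinking speed:         5.94 m d-1
  assumptions:           rigid_translation, no_loss_processes
  note: competing losses are assumed absent, so the speed is
        a conservatively large estimate.
```

Reading this: grouping by deployment does not separate the whole-community
composition (p = 0.16 — the layer involves one taxon among six), the
solitary-cell flux is negatively rank-correlated with the small-detrital POC
flux as configured (ρ = −0.35), and the inversion recovers ≈ 5.9 m d⁻¹
against the 6.6 m d⁻¹ used to generate the layer — an upper-bound style
estimate whose assumptions are stamped on the result. The output directory
contains every table (fluxes, dissimilarity matrix, network edge list and
clusters, PCA loadings, sinking record) as commented CSV plus a
`manifest.json`; rerunning with the same config and seed reproduces the
bundle byte for byte.

The same stages are available from a shell:

```bash
gelflux simulate --out demo/data --scenario north-pacific-like --seed 11
gelflux all --in demo/data --out demo/out --seed 11
gelflux sink-speed --in demo/data --out demo/out --taxon Fragilariopsis --seed 11
```

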