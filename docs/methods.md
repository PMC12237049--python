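# Methods

`gelflux` analyses solitary phytoplankton cells captured in polyacrylamide
gel layers at the bottom of sediment-trap tubes. This note documents the
models and procedures the package implements, the choices made where the
design was genuinely open, and what the synthetic-data generator does and
does not emulate.

## Observation model and flux arithmetic

A gel layer preserves sinking particles intact and spatially separated, so
individual cells can be identified and counted under a stereomicroscope.
A count `N` of a taxon over a surveyed gel area `A` (m²) during a collection
period `T` (days) estimates the number flux

    F = N / (A · T)        [cells m⁻² d⁻¹],  σ_F = √N / (A · T).

Counting is modelled as Poisson — cells arrive independently and are counted
in grid fields placed randomly over the gel — which makes the familiar
square-root-of-counts uncertainty exact, not an approximation. Taxa are
surveyed at different magnification tiers (a high-magnification subsample
for small cells, the whole gel surface at low magnification for large rare
forms); each taxon is counted at one tier and, when a taxon appears at two
tiers, tier fluxes are summed with independent counting errors combined in
quadrature.

Bulk particulate organic carbon (POC) fluxes come from replicate volume
splits of the pooled brine tubes (combined area 2 × 0.0113 = 0.0226 m²):
mean split mass divided by the split fraction (default 1/8), the duration
and the area. The mass inputs are PIC-corrected upstream. The flux sigma is
the standard error of the replicate mean, scaled the same way; the field
protocol states only that uncertainty propagates from the replicate spread,
and the standard error is the spread of the quantity actually reported (the
mean). A single replicate yields sigma 0 with a `single_replicate` flag.

Depth-averaged fluxes are the unweighted arithmetic mean over trap depths.
Trap spacing is uneven and no weighting scheme is canonical; the unweighted
mean is the default because it reproduces the fold-change arithmetic between
reported depth averages, and a trapezoidal depth-weighted alternative
(`scheme="trapezoid"`) is provided for sensitivity analysis.

Carbon per cell uses a spherical biovolume at a representative diameter
(default 45 µm, the midpoint of the 10–80 µm measured size range) and a
diatom allometric regression `C[pg] = a · V[µm³]^b` with defaults
`a = 0.288`, `b = 0.811` — the standard diatom carbon-biovolume fit for
biovolumes above ~3000 µm³. Both coefficients are configuration
(`CellCarbonModel`), never hard-coded downstream. Unit conversion uses
1 mmol C = 12.011 × 10⁹ pg C.

Ratios of fluxes (fold changes, gel-vs-bulk solitary fractions,
percent-of-bulk POC) combine relative sigmas in quadrature. A gel/bulk
ratio with a zero-count numerator reports its sigma from the upper 68%
Poisson bound on zero counts (1.84 counts) rather than √0 = 0, which would
claim certainty the data cannot support. Ratios above 1 (sampling noise in
the co-deployed pair) are allowed and flagged.

## Community structure

Samples-by-taxa matrices of number fluxes feed the Bray-Curtis
dissimilarity `Σ|x−y| / Σ(x+y)`. Fluxes enter untransformed by default —
absolute flux magnitude is part of the signal being compared — with
`relative` and `fourth_root` transforms behind flags.

Group differences are tested by PERMANOVA with the Anderson partition
computed directly from the dissimilarity matrix:

    SS_total = Σ_{i<j} d²_ij / n,   SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g,
    F = (SS_among / (a−1)) / (SS_within / (n−a)),

significance by free label permutation, `p = (1 + #{F* ≥ F}) / (1 + n_perm)`
(default 9999 permutations; a `strata` option restricts shuffles to blocks,
e.g. depth horizons). An exact mode enumerates all orderings for n ≤ 9 and
is the oracle against which the Monte-Carlo p is tested. Degenerate inputs
(all samples identical) return F = 0 with p ≈ 1 rather than 0/0.

The permutation null is discrete at small n: with 4+4 samples only
C(8,4) = 70 distinct partitions exist and permutations frequently tie the
observed statistic, making the test conservative (rejection ~3–4% at
α = 0.05). The type-I calibration experiments therefore use 5+5 samples
(252 partitions), where the empirical rate sits at 4–6%.

Ordination is metric MDS: classical Torgerson scaling (eigendecomposition of
the double-centred squared dissimilarities) followed by a Guttman/SMACOF
stress-minimisation pass, reporting Kruskal stress-1. Ordination is a
visualisation aid; no inference is attached to it.

The community network links samples whose Bray-Curtis dissimilarity is
strictly below a threshold (default 0.25; ties at the threshold are
excluded). Connected components are the distinct sinking communities;
singletons are retained. Component labels are deterministic, ordered by
earliest deployment then shallowest member depth. Per-cluster composition
is the mean of member samples' relative compositions (each sample first
normalised to sum 1), with taxa below a display floor (default 5%) pooled
into `other`; rows sum to 1 by construction.

## Covariation

Flux features (solitary-cell POC flux plus per-class detrital POC fluxes)
are min-max normalised to [0, 1] per column; constant columns raise (or are
dropped with a warning, by option). PCA eigendecomposes the covariance
matrix of the normalised columns — covariance, not correlation, because the
normalisation already equalises ranges and the residual variance structure
is the signal; a correlation-matrix option is flagged. Loadings are
unit-norm with the largest-magnitude element of each component made
positive (a deterministic sign convention); with fewer than two numerically
nonzero eigenvalues a single component is reported.

Spearman rank correlation is the Pearson correlation of mid-ranks (average
ranks on ties) with a two-sided permutation p-value (no
coupling direction is assumed a priori); exact enumeration is available for n ≤ 8 and a t
approximation for speed.

## Sinking speeds

Two estimators bracket the kinematics:

* **Capture floor.** Any cell recovered from the gel fell the height of the
  collection tube (0.70 m) within the deployment, so its speed was at least
  `0.70 / T` m d⁻¹ — about 0.1–0.4 m d⁻¹ for 5.9–1.7 day deployments.

* **Rigid-translation inversion.** When one taxon's depth profile of flux
  translates downward between deployments, the depth-integrated loss over
  the observation window, `ΔI = ∫early − ∫late`, equals the part of the
  early profile that slid below the deepest trap. The solver finds the
  translation depth `d` with `∫_{z_max−d}^{z_max} early(z) dz = ΔI` by
  monotone bisection (tolerance 10⁻⁶ m; the left side is nondecreasing in
  `d`), and `speed = d / Δt`. Profiles are tabulated, so integration is
  trapezoidal with linear interpolation at window endpoints; below the
  deepest node the profile is held constant (flagged), with a no-extrapolation
  mode for sensitivity — neither rule is canonical for sparse trap profiles.
  Gains at individual depths (noise) are absorbed into the
  single net ΔI. A non-positive ΔI returns speed 0 (`no_net_loss`); a ΔI
  larger than all early mass reachable by the bottom window raises a
  loss-unexplainable error.

  The inversion assumes rigid translation and no competing losses (grazing,
  remineralisation, patchiness). Any unmodelled loss inflates ΔI and hence
  the speed, so the estimate is conservatively large; the results object
  says so explicitly. The inversion is exposed as
  `RigidTranslationModel(early, late, delta_t_d).fit()` returning a results
  object with a `summary()`.

## Synthetic campaigns

`ScenarioConfig`/`generate_scenario` emulate a month-scale process study:
3 deployments 7 days apart, 5 trap depths between 50 and 500 m, paired
surface-tethered (STT) and neutrally buoyant (NBST) platforms, 5-day
collections. Structure, in generation order:

* **True fluxes** per taxon follow a configurable depth shape: exponential
  decay (scale 200 m; surface bloom export), monotone increase, or a
  Gaussian subsurface layer (default center 330 m, width 40 m) that
  translates rigidly downward at `layer_speed_m_d` between deployments —
  the signal the inversion recovers. An optional per-deployment fold factor
  emulates a developing bloom.
* **Platform variability** is one mean-1 lognormal multiplier per trap
  sample, shared by all taxa and the bulk catch of that trap (inducing
  realistic cross-taxon correlation). Its CV is constrained to the observed
  replicate-platform band of 0.22–0.79 (default 0.40).
* **Counts** are Poisson with mean `true flux × multiplier × tier area ×
  duration`; small taxa are counted on a 5 cm² high-magnification subsample,
  rare large taxa over the whole 0.0113 m² gel.
* **Bulk POC masses** are three replicate 1/8 splits with independent 10%
  lognormal noise, pegged so the true solitary-cell carbon flux is a
  configured fraction of bulk POC (default 3%).
* **Detrital class POC fluxes** are lognormal, with the small-detrital and
  aggregate classes rank-coupled to the realized total cell flux through a
  Gaussian copula at the configured Spearman coupling (long fecal pellets at
  0.8×, salp pellets at −0.5×, other classes independent — the qualitative
  covariation pattern of a bloom-export system).

Every dataset carries a truth sidecar (noise-free fluxes, layer centers,
platform multipliers, bulk truth), and round-trips losslessly through the
delimited-text writers/readers (17-significant-digit floats, round-trip
parsing).

Two presets summarise contrasting regimes: a bloom-export scenario
(decaying profiles, fluxes doubling per deployment, coupling +0.7) and a
recycling-system scenario (tenfold lower fluxes, a deep translating diatom
layer centred at 420 m so it exits past the deepest trap over the campaign,
coupling −0.3).

What the generator does **not** emulate: advection and patchiness beyond
the lognormal platform multiplier, within-gel spatial clustering of cells
(grid placement is assumed uniform — the counting distribution across grid
squares is not documented for real gels), swimmer contamination,
magnification-dependent detection efficiency, and any chemistry of the bulk
measurements. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated statistical assumptions, not robustness to
those unmodelled features of real field data.

## Problem sizes and numerical choices

Recovery and calibration experiments use deliberately moderate sizes chosen
to give stable statistics: 100 replicate count realisations for the
sinking-speed recovery (on a 10 m depth grid from 200–500 m, where
trapezoidal discretisation error is ≪ the 15% acceptance band; noise-free
recovery is within 0.1%), 1000 null simulations at 199 permutations for the
PERMANOVA type-I rate, 1500 replicates for the 68%-interval coverage check,
and 50–200 replicate campaigns for coupling recovery. Bisection tolerance
is 10⁻⁶ m; eigenvalues below 10⁻¹² of the trace are treated as zero in the
PCA; Bray-Curtis of two all-zero samples is undefined and raises.

## Known limitations

* The inversion attributes the whole integrated loss to settling; in real
  data loss terms are not separable, so reported speeds are upper-context
  estimates by design.
* The layer inversion needs the taxon's profile resolved by several traps
  across the layer width; on a sparse 5-depth campaign the trapezoidal
  integrals are coarse and estimates correspondingly noisy (the pipeline
  still reports them, with flags).
* PERMANOVA p-values at very small n are granular; exact enumeration is
  provided but the discreteness is a property of the test, not a bug.
* Min-max normalisation is sensitive to single extreme samples; the PCA
  should be read qualitatively (sign structure of loadings), as in the
  covariation analyses it supports.
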