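# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic generators do and do not emulate.

## Canopy temperature and stress degree day

A plot's thermal raster (°C per pixel; 120 × 120 in the reference
acquisition geometry) is reduced to a single canopy temperature by a
fixed pipeline, in this order:

1. **Central region of interest.** A centered `roi_size × roi_size`
   square (default 30) avoids contamination from neighbouring plots.
   When `(dimension − roi_size)` is odd the extra row/column is dropped
   on the high-index side; for the reference 120→30 case the remainder
   is even, so this convention never bites there.
2. **Canopy segmentation.** Interactive segmentation is replaced by two
   reproducible modes: pass-through of an externally produced mask, or a
   temperature band `t_min ≤ T ≤ t_max` (canopy is several °C cooler
   than sunlit soil at midday, so a cut at the histogram antimode
   separates the classes). Mode and parameters travel with the result.
3. **Percentile trimming.** The 1st and 97.5th percentiles of the
   remaining pixels (linear interpolation between order statistics,
   numpy's default definition) bound a closed retained interval
   `[p_low, p_high]`. Closedness keeps a constant image fully retained.
   Degenerate case: a two-value sample places both interpolated
   thresholds strictly between the values; trimming is then meaningless
   and the full sample is retained with thresholds widened to min/max,
   so the retained set is never empty. Note the operation is *not*
   idempotent — a second pass recomputes percentiles inside the trimmed
   range and removes a few more pixels — only nestedness of the
   thresholds holds.
4. **Mean and SDD.** `Tc` is the arithmetic mean of the retained pixels;
   `SDD = Tc − Ta` with `Ta` taken from the nearest-hour weather record.
   Negative SDD is a legitimate reading (freely transpiring canopy).

Mask-then-trim ordering is a deliberate choice (trimming operates on
canopy pixels only); the alternative trim-then-mask ordering is not
offered. All counts (`n_roi`, `n_masked`, `n_retained`) and realized
thresholds are recorded in the `TcSummary` so a reading can be audited.
Pixels outside a plausibility window of [−20, 70] °C are rejected at
load time: they almost always indicate a raw-count raster misread as
degrees. Radiometric calibration, emissivity and view-angle geometry are
out of scope.

## Environmental indices

* **VPD.** Tetens/FAO-56 saturation vapor pressure,
  `es(T) = 0.6108·exp(17.27·T/(T + 237.3))` kPa; `VPD = es·(1 − RH/100)`.
* **Daily VPDmax** is VPD evaluated *at the hour of the daily maximum
  temperature with that hour's humidity* — not the maximum of hourly
  VPDs (the two differ whenever the hottest hour is relatively humid).
  Temperature ties resolve to the earliest hour.
* **Seasonal windows** are closed on both ends, sowing→harvest for Tmax,
  VPDmax and precipitation. Days with fewer than 18 hourly records are
  excluded from the means (no imputation) and counted in the result;
  precipitation totals sum every record in the window.
* **SWC** converts volumetric content θ to stored water via a 500 mm
  profile depth, averages the (up to six) 4-hourly scans of each day
  with equal weight, then averages daily values over anthesis→harvest.
  Harvest stands in for the unrecorded grain-maturity date; an
  `end="grain_filling"` option narrows the window instead.

## Isotope discrimination

`Δ13C = (δ13C_a − δ13C_p)/(1 + δ13C_p/1000)` with δ13C_a = −8.0 ‰.
The algebraic inverse (used by the simulator to write plot tables on the
measured composition scale) round-trips to 1e−9 ‰. The mass-spectrometry
measurement of δ13C_p itself is upstream of this package.

## Association statistics

Linear fits are ordinary least squares with `r² = 1 − SSE/SST` and the
slope's two-sided t-test. The environment-level yield response to stress
is fitted as `y = a·exp(b·x)` by nonlinear least squares *on the
original scale*, initialized from the log-linear fit — original-scale
fitting keeps r² comparable with the linear fits, at the cost of
requiring positive responses for initialization. The significance of b
uses its asymptotic standard error with n − 2 degrees of freedom. A flat
response drives b → 0 and the fit collapses to the mean, as it should.

The correlation matrix uses pairwise-complete deletion (one environment
lacks kernel Δ13C), p-values from the t transform of r with
`n_pairs − 2` degrees of freedom, stars at p < 0.05 (*) and p < 0.01
(**), and no multiple-testing correction. Cells with fewer than three
complete pairs are flagged and carry no p-value.

## Environment typing

Feature table: three phenology durations (sowing→anthesis,
anthesis→grain filling, grain filling→harvest, in days) plus GY, Δ13C,
SDD, Tmax, VPDmax, SWC. Raw calendar dates are not comparable across
seasons, hence the duration encoding (a day-of-year encoding is
available as an option). Missing Δ13C is imputed by the column mean and
flagged. Zero-variance columns are dropped with a warning.

**Normalization** defaults to min–max (each feature rescaled to [0, 1]);
z-scoring (ddof = 1) is available. The choice matters: with min–max
scaling the k = 2 and k = 3 cuts of the reference table reproduce the
published environment grouping exactly (the three 2011 trials form the
high-stress group), whereas z-scoring lets the extreme SDD of the single
hottest trial dominate and isolates it as a singleton. We therefore
treat min–max as the default reading of "normalizing the data" for this
analysis and document the alternative.

**Ward.D2** is implemented in-package: the Lance–Williams recurrence on
squared Euclidean distances,

    d²(k, i∪j) = [(nᵢ+nₖ)d²(k,i) + (nⱼ+nₖ)d²(k,j) − nₖ d²(i,j)] / (nᵢ+nⱼ+nₖ),

merging the minimum-distance pair at each step with deterministic
tie-breaking by the lowest cluster-index pair. Heights are reported on
the √d² (distance) scale, matching R's `hclust(method = "ward.D2")`;
monotonicity of Ward heights is what makes "remove the k−1 tallest
merges" equivalent to stopping after n−k merges in `cut_groups`. The
test suite checks the implementation against an exhaustive oracle that
recomputes the Ward criterion from cluster means at every step, and
against scipy's independent ward linkage.

PCA is the SVD of the column-centered normalized table; variance
fractions are reported over all components (they sum to 1) and component
signs are fixed by making each loading vector's dominant entry positive.
The two-component variance share depends visibly on the feature
encoding, so it is treated as descriptive, not as a calibrated quantity.
Group contrasts are percent changes of raw (unscaled) feature means
against a reference group, with a zero reference mean flagged as NaN.

## Synthetic data

The generators define the study conditions under which the package is
validated; all are pure functions of (spec, seed).

* **Scenes** (default 120 × 120, air 25 °C): canopy rows
  `N(ta + sdd_true, 0.5 °C)` with a 7/12-pixel row geometry (~58%
  canopy), soil `N(ta + 12, 1.0 °C)`. The +12 °C soil offset represents
  midday Mediterranean acquisition; it is configurable. Not emulated:
  mixed boundary pixels, ears and weeds, oblique-view geometry,
  vignetting — so segmentation accuracy on real rasters will be lower
  than the ≥99% the tests demonstrate at ≥8 °C class separation.
* **Weather** (default 135 days): cosine diurnal cycle peaking at 15:00
  with 12 °C range; daily peaks = seasonal mean (23.4 °C default) +
  full-cycle sinusoid (amplitude 3 °C, mean ≈ 0) + AR(1) noise (φ = 0.6,
  sd 1.5 °C); RH anchored at 40% at the daily peak, rising 2.2 %/°C as
  air cools, clamped to [5, 100]; sparse exponential rain events.
  Fronts, wind and radiation are not modeled.
* **Soil moisture**: linear seasonal dry-down (0.32 → 0.20 m³ m⁻³) on
  the 4-hourly grid plus small noise.
* **Trials**: under water stress, environment SDD = −11.0 + 9.7·VPDmax
  (°C per kPa) + N(0, 0.4); environment-mean GY = a·exp(b·SDD) with
  (a, b) = (11.0 t ha⁻¹, −0.15 °C⁻¹) — calibrated so yields span
  ≈ 8.1 → 1.7 t ha⁻¹ over SDD 2 → 12.3 °C, the observed multi-season
  span; Δ13C = 17.5 − 0.25·SDD ‰. Irrigated environments sit at
  SDD ≈ 0.85 °C (below the 2 °C stress threshold) with flat mean yield
  9.1 t ha⁻¹. Plot noise defaults: 0.6 t ha⁻¹ (GY), 0.8 °C (SDD),
  0.5 ‰ (Δ13C). Genotype-by-environment interaction, spatial field
  trend and the alpha-lattice design are not emulated, so passing
  recovery tests demonstrate estimator correctness under the assumed
  structure, not robustness to real-trial nuisance.
* **Genotype cohorts** (for the genotype-level regressions): 384
  genotypes with SDD ~ N(6, 2²) °C and GY linear in SDD with noise
  scaled to a programmed population r²; at n = 384 the sample r²
  concentrates within ±0.05 of the target.

## Problem sizes and determinism

The test suite and the acceptance script use 100 scene seeds, 100 cohort
seeds per r² target, 200 trial seeds at 10 environments × 24 genotypes,
and random clustering tables of ≤ 20 rows; the whole suite runs in a few
seconds. Every stochastic routine takes an explicit seed;
hypothesis-based property tests are derandomized. Pipeline outputs are
serialized at fixed precision so identical configs reproduce identical
bytes (manifests differ only in their timestamp).

## Known limitations

* Segmentation quality on real imagery is bounded by the band-threshold
  model; an external mask is the better route when available.
* The exponential yield link is a phenomenological summary; nothing
  mechanistic is implied, and with ≤ 5 environments per regime its r² is
  unstable.
* Clustering of ten environments is sensitive to feature encoding and
  normalization (documented above); conclusions about group membership
  should be checked under both normalizations.
* Air temperature at capture uses the nearest hourly record; no
  sub-hourly interpolation.
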