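# thermotype

Canopy-temperature phenotyping for multi-environment wheat trials: from
thermal images and weather records to stress degree day, seasonal stress
indices, carbon isotope discrimination, trait–environment association
statistics, and Ward.D2 environment typing.

## The problem

Infrared thermography is a fast proxy for plant water status: when a
crop cannot meet atmospheric water demand its stomata close,
transpirational cooling drops, and the canopy warms above the air. The
**stress degree day** summarizes this as

```
SDD = Tc − Ta
```

where `Tc` is the mean canopy temperature of a plot (°C, from a thermal
image after region-of-interest cropping, canopy segmentation, and
percentile trimming of the pixel histogram) and `Ta` is the air
temperature at capture time. How well SDD predicts **grain yield (GY)**
and **kernel carbon isotope discrimination (Δ13C)** depends strongly on
the environment, so each trial season is characterized by:

* `Tmax` — mean of daily maximum air temperature, sowing→harvest (°C);
* `VPDmax` — vapor pressure deficit at the hour of the daily maximum
  temperature (Tetens form, `es = 0.6108·exp(17.27·T/(T+237.3))` kPa),
  averaged sowing→harvest;
* `SWC` — volumetric soil water content × 500 mm profile depth, averaged
  over anthesis→harvest (mm);
* Δ13C — `(δ13C_air − δ13C_plant)/(1 + δ13C_plant/1000)` with
  δ13C_air = −8.0 ‰.

Environments are then *typed* by min–max normalizing the environment ×
feature table (phenology durations, GY, Δ13C, SDD, Tmax, VPDmax, SWC)
and clustering with the Ward.D2 minimum-variance criterion on Euclidean
distances, with a PCA projection for display.

The package is aimed at crop physiologists and phenotyping groups who
collect plot-level thermal images plus standard agro-met station data
and want a reproducible path from rasters to environment-level
inference. Because no raw trial data are deposited, a synthetic-data
module generates thermal scenes, weather/soil series and
multi-environment genotype tables with known ground truth; a
transcription of the published ten-environment summary table ships with
the package and drives the offline reproduction of the
multi-environment results.

## Worked example

```python
import thermotype as tt

env = tt.load_reference_environments()          # ten trial environments
corr = tt.pearson_matrix(env, ["sdd", "gy", "d13c", "tmax", "vpdmax", "swc"])
print(corr.r.loc["gy", "sdd"].round(2), corr.stars.loc["gy", "sdd"])
# -0.81 **

ft = tt.build_feature_table(env)                # min–max normalized, Δ13C imputed
groups = tt.cut_groups(tt.ward_d2_linkage(ft), 3)
print(groups.to_dict())
# {'FIsr 2011': 1, 'FIsr 2012': 2, 'FIsr 2014': 2, 'FIsr 2015': 2,
#  'FIc 2015': 3, 'WSsr 2011': 1, 'WSc 2011': 1, 'WSc 2012': 3,
#  'WSsr 2015': 2, 'WSc 2015': 3}
```

Across the ten environments, mean grain yield correlates with SDD at
r = −0.81 (p < 0.01): hotter canopies, lower yields. Cutting the
Ward.D2 tree at k = 3 puts the three highest-stress 2011 environments
(`WSc 2011`, `FIsr 2011`, `WSsr 2011` — group 1 above) together,
separating them from the mild irrigated group and the intermediate
group.

Thermal extraction on a synthetic scene with known truth:

```python
spec = tt.SceneSpec(ta=25.0, sdd_true=5.0, noise_sd=0.5, seed=3)
sample = tt.simulate_scene(spec)
s = tt.extract_tc(sample.image, ta=spec.ta, mask=sample.mask)
print(round(s.tc, 2), round(s.sdd, 2), s.n_retained)
# 29.95 4.95 491
```

The same operations are exposed on the command line (`thermotype
extract-tc`, `env-indices`, `correlate`, `fit`, `cluster`, `simulate`,
`run`); `thermotype run --config config.yaml` executes the whole chain
and writes a reproducibility manifest.

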