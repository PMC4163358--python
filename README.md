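# grasscasa

Monthly grassland net primary productivity (NPP) on raster grids with the
CASA (Carnegie–Ames–Stanford Approach) light-use-efficiency model, together
with the preprocessing, in-situ validation and zonal summary statistics a
regional grassland NPP study needs — and a seeded synthetic-scene generator
so the entire pipeline is testable without any satellite downloads.

## Who this is for

Ecosystem modellers and rangeland scientists who estimate grassland
productivity from satellite FPAR, land-surface temperature, precipitable
water and solar radiation, and validate it against clipped-biomass surveys.

## The model

CASA is a production-efficiency model: carbon fixation is absorbed light
times the efficiency of its use,

```
NPP(x, t) = APAR(x, t) × LUE(x, t)                [gC·m⁻²·month⁻¹]
APAR(x, t) = SOL(x, t) × FPAR(x, t) × 0.5         [MJ·m⁻²]
LUE(x, t)  = Tε1(x) × Tε2(x, t) × Wε(x, t) × εmax,  εmax = 0.604 g/MJ
```

with two temperature stress scalars around each cell's optimal temperature
Topt (the air temperature of its greenest month, FPAR as the greenness
proxy),

```
Tε1 = 0.8 + 0.02·Topt − 0.0005·Topt²
Tε2 = 1.1814 / (1 + e^{0.2(Topt−10−T)}) / (1 + e^{0.3(−Topt−10+T)})
```

and a moisture stress scalar driven by vapor pressure deficit D (kPa),

```
Wε = 1.2·e^{−0.35·D} − 0.2   (clamped below at 0)
D  = 0.611·[e^{17.27(Ts−273)/(Ts−36)} − e^{17.27(Td−273)/(Td−36)}],  D = 0 if Ts < Td
```

where Ts is land-surface temperature (K) and the dew point Td comes from a
regional regression on total precipitable water U (mm): ln U = 1.8084 +
0.0735·Td (Td in °C).

Validation converts clipped aboveground dry yield to total NPP carbon via a
0.45 carbon fraction and per-type root:shoot ratios (mountain meadow 6.23,
alpine and alpine shrub meadow 7.92), then scores the model with

```
Error % = mean(|X1 − X2| / X2) × 100,   Precision % = 100 − Error %
```

Preprocessing covers 8-day→monthly compositing (day-overlap weighted),
per-cell cubic-spline gap filling in time, and elevation-aware gridding of
station air temperatures (lapse-rate regression plus a thin-plate spline on
the residuals).

## Worked example

```python
import numpy as np
from grasscasa import (SceneConfig, generate_scene, generate_insitu_points,
                       run_casa, cell_area_grid, monthly_series, validate_by_type)

config = SceneConfig(grid_shape=(64, 64), seed=7)
inputs, truth = generate_scene(config)     # inputs + scalar-oracle ground truth
out = run_casa(inputs)                     # APAR, stress scalars, LUE, NPP

valid = ~out.npp_annual.mask
print(f"mean annual NPP: {out.npp_annual.values[valid].mean():.1f} gC/m2")

areas = cell_area_grid(out.npp.georef, out.npp.shape)
totals, _ = monthly_series(out.npp, areas)
print(f"peak month: {np.argmax(totals) + 1}, total: {totals.sum():.1f} TgC")

points = generate_insitu_points(truth.npp_annual, truth.grassland_types,
                                inputs.type_legend, rel_noise_sd=0.3, seed=9)
for row in validate_by_type(points, out.npp):
    print(f"{row.grassland_type:22s} n={row.n_points:3d} precision={row.precision_pct:5.1f}%")
```

prints

```
mean annual NPP: 358.5 gC/m2
peak month: 8, total: 367.9 TgC
alpine meadow          n=100 precision= 76.0%
alpine shrub meadow    n= 30 precision= 69.3%
mountain meadow        n= 20 precision= 80.3%
Total                  n=150 precision= 75.2%
```

The scene is a mountainous province: NPP peaks in August (the configured
greenness peak), and a 150-point survey (100/30/20 across the three
grassland types) with 30% lognormal yield noise scores ~75% pooled
precision — the mean absolute relative deviation the noise law implies.

The same pipeline runs from the shell:

```
grasscasa simulate --seed 7 --out scene/
grasscasa preprocess --config scene/config.yaml --out prep/
grasscasa run --config prep/config.yaml
grasscasa validate --config prep/config.yaml
grasscasa stats --config prep/config.yaml --breaks 1000,2000,3000,4000,5000
```

writing NPP rasters, a validation report, elevation-band / grassland-type /
region partition tables, monthly series and an NPP histogram as CSV.

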