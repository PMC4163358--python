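# Methods

## Model

`grasscasa` implements a production-efficiency (light-use-efficiency) NPP
model of the CASA family on monthly raster stacks. Monthly NPP is the
product of absorbed photosynthetically active radiation (APAR) and actual
light-use efficiency (LUE). APAR is total solar surface radiation times the
fraction of absorbed PAR (FPAR) times a PAR fraction of 0.5. LUE is a
maximum efficiency for grass, εmax = 0.604 g·MJ⁻¹, down-regulated by two
temperature stress scalars and one moisture stress scalar. The model works
on a monthly time step over one calendar year (12 layers per stack) and
assumes all input stacks are aligned on one north-up geographic grid — no
on-the-fly reprojection is performed.

Assumptions inherited from this model family:

* NPP is simulated directly (no GPP/autotrophic-respiration split) and no
  soil-moisture submodel is used — moisture stress comes entirely from the
  atmospheric vapor pressure deficit (VPD).
* εmax is a single grass-wide constant; 0.604 g/MJ is read as grams of
  carbon per MJ because NPP is reported in gC·m⁻².
* The optimal temperature Topt of a cell is the monthly mean air
  temperature of its greenest month. Greenness is proxied by FPAR (the
  product actually in the input set); ties take the earliest month so the
  result is deterministic.

## Parameters

All constants live in one frozen `ModelParams` value:

| parameter | default | units | role |
|---|---|---|---|
| `par_fraction` | 0.5 | — | PAR share of total solar radiation |
| `eps_max` | 0.604 | g·MJ⁻¹ | maximum light-use efficiency for grass |
| `te2_scale` / `te2_k_warm` / `te2_k_cold` / `te2_offset` | 1.1814 / 0.2 / 0.3 / 10 | —, °C⁻¹, °C⁻¹, °C | double-logistic temperature stress Tε2 |
| `we_a` / `we_b` / `we_c` | 1.2 / 0.35 / 0.2 | —, kPa⁻¹, — | moisture stress Wε(D) |
| `we_floor` | 0.0 | — | lower clamp on Wε |
| `svp_coeff` / `svp_a` / `svp_t0` / `svp_b` | 0.611 / 17.27 / 273 / 36 | kPa, —, K, K | saturation vapor pressure form |
| `dew_intercept` / `dew_slope` | 1.8084 / 0.0735 | —, °C⁻¹ | ln U = a + b·Td regression |
| `carbon_fraction` | 0.45 | gC·g⁻¹ | dry biomass → carbon |
| `root_shoot` | 6.23 / 7.92 / 7.92 | — | belowground/aboveground ratio per type |

Notes on the less obvious choices:

* **Wε clamp.** The bare expression 1.2·e^(−0.35·D) − 0.2 turns negative
  above D ≈ 5.12 kPa; negative productivity is non-physical, so Wε is
  clamped at `we_floor = 0`. Clamp activations are logged so extreme-VPD
  scenes are auditable.
* **Tε1 is not clamped.** The quadratic is evaluated as printed; a Topt
  extreme enough to drive Tε1 below zero is reported as a logged warning
  rather than silently truncated, because such a value indicates inputs
  outside the model's intended range.
* **Tε2 shape.** Tε2 depends only on T − Topt. With the default constants
  its value at T = Topt is 0.9912 and its single maximum (0.9968) sits
  about 1.1 °C above the optimum, within 1% of the value at the optimum.
  Exponential arguments are clipped at ±700 so extreme temperatures
  saturate the logistic factors to 0/1 instead of overflowing.
* **Dew-point units.** The precipitable-water regression is inverted with
  Td in °C (a Kelvin reading gives physically absurd U); the result is
  shifted by +273 K — the model's printed Celsius/Kelvin offset, kept at
  273 rather than 273.15 and configurable — before entering the saturation
  vapor pressure formula. Temperatures at or below the 36 K singularity of
  that formula are masked with a warning.
* **Nodata.** Masks are explicit booleans, and any operation unions the
  masks of its inputs; the annual NPP layer sums unmasked months and is
  masked only where all 12 months are masked.

## Preprocessing

* **Compositing.** Fixed-period composites (e.g. 8-day) are aggregated to
  calendar months by day-overlap weighting: a period contributes to a month
  with weight equal to the number of days it overlaps it, per cell,
  excluding masked cells. This is unbiased at month boundaries, unlike
  assigning each composite to its start month.
* **Gap filling.** Missing months are filled per cell with a natural cubic
  spline along the month axis. Outside the observed span the nearest
  observed value is used — cubic extrapolation on seasonal data diverges.
  Observed values are never altered; cells with fewer than two observations
  stay masked.
* **Station temperature gridding.** A two-step scheme: (1) ordinary
  least-squares regression of station temperature on station elevation (the
  lapse-rate fit, logged per month); (2) thin-plate-spline interpolation of
  the regression residuals over lon/lat (`scipy.interpolate.RBFInterpolator`,
  smoothing 0 by default, i.e. exact at stations); the gridded field is
  intercept + slope·DEM + residual surface. The scheme was chosen over a
  single 3-D spline because its elevation component is directly testable:
  noise-free stations on a pure lapse field recover the field to < 0.01 °C
  and the lapse rate to well under 5%. If station elevations are collinear
  the lapse step is skipped (spatial spline only, with a warning); fewer
  than three reporting stations is an error.

## Validation

Clipped dry yield (g·m⁻², aboveground) is converted to total NPP carbon as
`yield × 0.45 × (1 + R)`, reading the root:shoot ratio R as
belowground/aboveground biomass — alpine meadows are strongly
root-dominated, hence R ≈ 8 and totals ≈ 9× the aboveground carbon.
Modeled NPP is extracted at the cell containing each point (nearest cell,
not bilinear: NPP is a cell aggregate), using the annual layer by default;
pairing against a single month's layer is selectable where surveys are
dated. The error statistic is the mean absolute relative deviation in
percent, with precision its complement; observations of exactly zero are
excluded (the statistic divides by them) with a warning. The pooled row
equals the point-count-weighted mean of the per-type errors by
construction.

## Summaries

Cell areas on the geographic grid are spherical:
R²·Δλ·(sin φ_top − sin φ_bottom) with R = 6371.0088 km. Partition
(zonal) statistics report per-class area, area %, mean, max, total and
total %; means are area-weighted by default (cells shrink with latitude)
with a simple-mean flag. Totals integrate value × cell area and are scaled
gC·m⁻²·km² → TgC by 1e-6. Elevation bands are half-open [lo, hi) — a cell
exactly at 4000 m belongs to 4000–5000 — with default breaks
1000/2000/3000/4000/5000 m. Histograms use [lo, hi) bins with the last bin
closed.

## Synthetic scenes

The generator builds an internally consistent mountainous-province year:

* DEM: Gaussian-smoothed seeded noise rescaled to 500–5500 m;
* air temperature: sea-level seasonal cycle (mean 18 °C, amplitude 10 °C,
  peaking in July) plus a −6.5 °C·km⁻¹ lapse over the DEM;
* LST: air temperature + 2 °C, in Kelvin; dew point: air temperature − 4 °C,
  pushed *forward* through the precipitable-water regression so the model's
  inversion recovers it exactly;
* FPAR: Gaussian seasonal bell peaking in August with a 1.5-month standard
  deviation, scaled per grassland type (0.85/0.75/0.65), baseline 0.05. The
  1.5-month width keeps the August greenness peak dominant over the June
  solar maximum, so APAR and NPP peak in August — the phenology the model
  is meant to reproduce;
* SOL: seasonal cycle 450 ± 250 MJ·m⁻²·month⁻¹ peaking in June;
* three grassland types from a smooth random field's quantiles, four
  administrative regions as lon/lat quadrants.

Ground truth for every derived layer is computed by a deliberately naive
per-cell scalar-loop implementation kept in a separate module from the
vectorised model, so truth-recovery tests are a genuine dual-route check.
Station networks (default 41 stations, Gaussian temperature noise, default
0.5 °C) and in-situ surveys (default 150 points split 100/30/20 across the
three types) are sampled from the truth; dry yields invert the carbon
conversion exactly and then receive multiplicative lognormal noise
(default sigma 0.3). For observations `truth·e^Z`, Z ~ N(0, σ²), the
expected validation error is E|e^Z − 1| = e^{σ²/2}(2Φ(σ) − 1) — about
24.7% at σ = 0.3, i.e. ~75% precision — which the test suite verifies by
Monte-Carlo calibration. All randomness flows from explicit seeds; equal
seeds give bit-identical scenes.

What the synthetic scenes do **not** emulate: real orbital/cloud gap
geometry and quality flags, spatially correlated yield errors, horizontal
advection (temperature is a pure function of elevation and season), and
realistic topography. Passing tests therefore demonstrate the correctness
of the equations, conversions and statistics — not the accuracy of the
model on real satellite inputs.

## Problem sizes and I/O

The default scene is 64×64 cells × 12 months, large enough for stable
area-weighted statistics while keeping the scalar-loop truth computation
and the full CLI pipeline fast; tests use 16×16 where spatial extent is
irrelevant. Rasters are stored as plain-text ESRI ASCII grids with a JSON
sidecar carrying the full georeference (the `.asc` header alone cannot
express non-square cells), CRS string and band list; values are written
with 17 significant digits and CSVs are read with round-trip float
parsing, so write→read is bit-exact for float64.

## Known limitations

* No reprojection: all inputs must already share one geographic grid.
* Gap filling is temporal only; spatially contiguous gaps covering a cell's
  whole year are left masked.
* The dew-point regression is a regional empirical fit; applying it far
  outside its calibration humidity range will distort VPD.
* Validation precision conflates model error with representativeness error
  (a point sample vs a ~km-scale cell mean); the statistic cannot separate
  them.
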