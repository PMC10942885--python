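# Methods

`agbsat` estimates aboveground biomass (AGB, kg/m²) of dense grassland
from 8-band visible/near-infrared imagery, targeting the *biomass
saturation* regime: once leaf area index (LAI) is high, red-band
chlorophyll absorption peaks while near-infrared (NIR) reflectance keeps
rising, so the classical NDVI = (NIR − red)/(NIR + red) compresses and
loses sensitivity exactly where monitoring matters most. The package
implements a mitigation pipeline — per-band contrast enhancement, SVD
denoising of the plot × band matrix, an exhaustive modified
normalized-difference index catalog, and random-forest regression with
backward feature elimination — together with a synthetic
fertilization-trial simulator that reproduces the saturation phenomenon
so the whole pipeline is testable without commercial imagery or field
campaigns.

## Scene simulator

### Trial structure

The default `TrialDesign` is a 96-plot trial of 9 m × 3 m plots in three
replicate blocks. Treatments are an unfertilized control plus two
ammonium fertilizer series at three rates each (ammonium nitrate at
21.0 / 42.1 / 63.2 g/m²; ammonium sulfate at 33.6 / 67.2 / 100.8 g/m²),
randomized to plots with per-treatment counts fixed so that the four
upper-rate ("high-nitrogen") treatments cover exactly `n_high_density`
plots (47 by default). The *high-density* label is treatment-based by
default — the rule that yields the canonical count of 47 — with an
AGB-threshold alternative (`selector="threshold"`, ≥ 3 kg/m²)
available because the two definitions of "high density" (treatment
stratum vs. biomass threshold) do not coincide on sampled data; the
treatment rule is primary and the tension is deliberately left visible
in the API rather than resolved silently.

### Biomass distribution

High-density AGB follows a truncated normal on [1.5, 4.5] kg/m² with
*truncated* mean 3.37 and sd 0.7075 kg/m². These four numbers are the
published field summary the generator is calibrated to; because
truncation shifts moments (a parent N(3.37, 0.7075²) truncated to
[1.5, 4.5] has mean ≈ 3.29), the generator solves for the parent normal
whose truncation matches the target moments (moment matching via
`scipy.optimize.fsolve`; parent ≈ N(3.72, 1.03²)) and samples by seeded
rejection, which enforces the bounds exactly. Low-density plots use the
same machinery with mean 1.5, sd 0.6, bounds (0.2, 3.0) kg/m² — chosen
once as a realistic unfertilized/low-nitrogen stratum sitting below the
3 kg/m² high-density threshold. Units satisfy
`agb_kg_per_plot = agb_kg_per_m2 × 27` exactly for the default plots.

### Canopy reflectance

Per-band reflectance follows a Beer–Lambert soil/canopy mixture

ρ_b(AGB) = ρ∞_b + (ρ_soil,b − ρ∞_b) · exp(−k_b · c · AGB)

with LAI = c · AGB (c = 1.5 m²/kg, giving LAI ≈ 5 at the mean
high-density biomass). Defaults (band order coastal, blue, green,
yellow, red, red-edge, NIR1, NIR2):

| parameter | values |
|---|---|
| ρ_soil | 0.12, 0.14, 0.24, 0.21, 0.22, 0.25, 0.28, 0.30 |
| ρ∞ | 0.03, 0.04, 0.05, 0.07, 0.015, 0.35, 0.50, 0.48 |
| k | 0.90, 1.00, 0.18, 0.50, 2.00, 0.25, 0.15, 0.17 |

The constraint k_red > k_NIR1, k_NIR2 is enforced at construction: red
must saturate first. The defaults are stylized rather than fitted — red
extinction is large (dead above ≈ 3 kg/m²), green extinction is near the
sensitivity optimum for the 3–4.5 kg/m² range (k·c·AGB ≈ 1), and the NIR
bands stay responsive across the whole range — so that the simulator
exhibits the qualitative asymmetry the pipeline exists to exploit:
NDVI's rank correlation with AGB collapses in the top biomass tertile
while green↔red modified indices retain theirs. This behavior is
asserted by the test suite over seeded replicates.

Noise has two components. Per-pixel additive Gaussian noise
(`pixel_noise_sd`, default 0.01 reflectance) models sensor noise but
averages away under zonal means (σ/√n_pixels). A per-plot, per-band
multiplicative deviation (`plot_noise_cv`, default 0.05) models
plot-scale canopy heterogeneity, illumination/BRDF variation and
residual atmospheric effects — the error term that does *not* shrink
with pixel count and therefore governs plot-level index noise. Without
it, simulated plot spectra would be essentially noiseless and every
monotone index would correlate perfectly with AGB, hiding the
saturation phenomenon entirely. With `pixel_noise_sd = 0`, all pixels
of a plot equal the plot's realized (deviation-included) reflectance.

Rendering places plots on a grid with 1 m gaps and rasterizes at
`pixel_size_m / supersample` (default 2 m / 4 = 0.5 m), so a plot covers
~108 pixel centers and zonal means are stable; the supersampling factor
exists because the method is being tested at plot scale, not to mimic
any particular sensor geometry. Overlapping plot polygons abort
rendering.

## Raster I/O and zonal statistics

Rasters are multiband float32 TIFFs (one page per band) with band
names, wavelength centers and the affine geotransform in a JSON
`ImageDescription` tag; polygons are GeoJSON. Zonal extraction uses the
center-in-polygon rule. Boundary ties are resolved deterministically:
a center exactly on a polygon edge is re-tested after a sub-nanometre
nudge toward (−x, +y), so a center on a shared vertical edge belongs to
the left polygon and one on a shared horizontal edge to the upper
polygon; adjacent plots never share a pixel. Only the mean statistic is
computed. Polygons covering no pixel center are dropped with a warning.
No reprojection is attempted — rasters and polygons must share a
coordinate frame.

## Contrast enhancement

Two global per-band stretches onto [0, 255]: min–max linear
(`v' = (v − min)(255 − 0)/(max − min)`) and histogram equalization via
the empirical CDF with mid-rank tie handling
(`v' = 255 · rank_avg(v)/n`). Both are applied band by band, either to
the full raster before extraction (default, mirroring image-processing
practice) or to the plot-mean table (`stretch_stage="table"`); for the
linear stretch the two stages are equivalent up to the order of
averaging. Outputs are continuous by default; quantization onto a
fixed number of levels (flooring, default 256) is opt-in, since nothing
downstream requires the information loss. A constant band is degenerate
under the linear stretch: all values map to `out_min` with a warning.
Both stretches are rank-preserving, so Spearman correlations with AGB
are invariant — what changes is the value distribution presented to the
SVD.

## SVD denoising

The plot table is viewed as M (m rows = predictors, n columns = plots)
and factorized by thin SVD, M = U Σ Vᵀ, with a deterministic sign
convention (each left singular vector oriented so its
largest-magnitude entry is non-negative). Large singular values capture
laterally coherent structure across plots; small ones are treated as
noise. Component retention requires (a) the maximum absolute entry of
the component's unit-norm left singular vector ≥ `threshold`
(default 0.5) and (b) σᵢ/σ₁ ≥ `sv_floor` (default 0.01); the leading
component is always retained, so the retained set is never empty.
Reported loadings rescale each component's |U| column to maximum 1 for
readability; selection operates on the raw unit-norm vectors, the
reading under which a threshold of 1.0 degenerates to
leading-component-only as intended. Denoising re-synthesizes
M' = Σᵢ∈retained σᵢ uᵢ vᵢᵀ. M contains predictors only — the AGB
response defines the sample axis but is never inserted as a matrix row,
which would leak the target into its own denoised predictors. No
centering or scaling is applied by default (`center=True` exists).
Truncation error obeys Eckart–Young: ‖M − M_k‖_F = √(Σ_{i>k} σᵢ²),
asserted to 1e-8 in the tests.

## Index catalog

The derived band `nir3` = (NIR1 + NIR2)/2 (arithmetic mean: the
simplest combination that preserves reflectance units) extends the
sensor bands to nine. The modified normalized-difference family
generalizes NDVI to any *ordered* band pair
(R_i − R_j)/(R_i + R_j); over nine bands that is 72 ordered pairs, of
which (NIR1, red), (NIR2, red), (NIR3, red) are the classical NDVI 1–3
and are catalogued with the standard indices instead, leaving 69
modified indices. Ids m1…m69 run consecutively in row-major band order
(coastal, blue, green, yellow, red, red-edge, NIR1, NIR2, NIR3) with
the three reassigned pairs skipped, which places m20 = green/red,
m34 = red/blue, m35 = red/green, m51 = NIR1/green,
m53 = NIR1/red-edge. Both orderings of a pair are distinct features
(they are antisymmetric, but tree ensembles treat them differently
under split selection and importance attribution).

The standard catalog holds five families × three NIR variants = 15
indices with canonical constants: NDVI_k, SR_k = NIRk/red,
EVI_k = 2.5(NIRk − red)/(NIRk + 6·red − 7.5·blue + 1),
SAVI_k = 1.5(NIRk − red)/(NIRk + red + 0.5), GDVI_k = NIRk − green.
Full catalog: 69 + 15 = 84. Band values are clipped at zero before
index evaluation so normalized differences stay in [−1, 1] even on
stretched inputs; zero denominators yield NaN cells and a per-plot
warning. Normalized-difference and simple-ratio indices are invariant
to positive rescaling of all bands; EVI and SAVI are not (their
additive constants break homogeneity), which is why the catalog is
evaluated per enhancement variant rather than once.

## Regression evaluation

`RandomForestRegressor` is the tree engine (ntree = 1000 trees,
mtry = ⌊√p⌋ candidate predictors per split — the stated default, kept
even though p/3 is the common regression choice; both are
configurable). Variable importance is out-of-bag permutation importance
in the %IncMSE style, implemented here because scikit-learn only offers
permutation importance on a fixed validation set: for each tree, the
MSE on its own out-of-bag samples is compared before and after
permuting one feature; the mean increase across trees, as a percentage
of the OOB MSE, is the importance. Backward feature elimination refits
the forest, records the 10-fold cross-validated RMSE at the current
size, and drops the least important variable, one per round, down to a
single feature; the selected set is the CV-RMSE argmin with ties
resolved toward the smaller set. The "optimal" model restricts to the
top-3 features by importance averaged over `n_repeats` seeded refits
(default 100) and reports repeated 10-fold CV metrics. R² is computed
on pooled out-of-fold predictions (1 − SSE/SST) rather than averaged
per fold — pooling is less biased at n = 47 with 10 folds — and RMSE is
in kg/m². The 70/30 split helper uses the floor rule (47 → 32/15).
Everything is deterministic per seed.

## Experiment grid

`run_experiment` crosses three enhancement variants (original;
linear stretch + SVD; histogram equalization + SVD) with five variable
groups (all variables = 9 bands + 84 indices; bands only; all indices;
standard NDVI 1 alone; top-3 optimal), running
stretch → zonal means → AGB join → nir3 → SVD → indices → forests, and
writes a results grid, ranked importances, per-plot out-of-fold
predictions, SVD diagnostics, and a run log with seed, configuration
hash (output path excluded) and library versions. Model fitting is
restricted to high-density plots by default, matching the saturation
regime the method targets.

## What the simulator does and does not show

Passing tests demonstrate that the pipeline behaves as designed on data
with the assumed structure: a monotone saturating band response, plot
exchangeability, Gaussian pixel noise, and multiplicative plot
heterogeneity. Real grassland imagery adds species composition and
phenology effects, soil moisture and shadow variation, atmospheric
residuals correlated across bands, georeferencing error, and
within-plot biomass gradients — none of which are simulated. Synthetic
results therefore validate the machinery and the *qualitative*
saturation-mitigation behavior, not field-accuracy levels; absolute R²
values on simulated scenes (typically 0.8–0.9 for the enhanced
pipeline) are an artifact of the simulator's noise budget and should
not be read as expected field performance.

## Numerical choices and problem sizes

Degenerate inputs fail loudly: negative AGB, constant observations in
R², empty component sets, absent bands, duplicate plot ids, overlapping
polygons. Seeds are propagated explicitly; independent substreams
derive from the user seed by fixed multipliers. The test suite runs the
statistical checks at reduced size — forests of 100–200 trees, 1–2
repeats, 20-seed replications for behavior properties, 200-seed
replications for calibration — sizes chosen to keep the full suite in a
few minutes while leaving comfortable statistical margins; the
paper-scale defaults (ntree = 1000, 100 repeats) remain the package
defaults for real use.

## Known limitations

- The simulator's canopy model is a two-parameter mixture per band; it
  cannot produce non-monotone band responses (e.g. yellow-band
  senescence effects).
- Zonal statistics assume a shared coordinate frame; there is no CRS
  handling or reprojection.
- Histogram equalization at raster stage and table stage are not
  equivalent (the ECDF differs); only the linear stretch commutes with
  plot averaging.
- OOB importance relies on scikit-learn's internal bootstrap-index
  helpers; a signature change upstream would require a shim update
  (both current signatures are handled).
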