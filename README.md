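# lakebloom

Satellite mapping of algal blooms on lakes, and ranking of the terrestrial
factors that drive them.

Eutrophication — nutrient over-enrichment of water bodies — shows up from
space as floating algal blooms. `lakebloom` is a tested, desk-scale pipeline
for the full analysis chain that links bloom metrics derived from
multispectral surface-reflectance imagery (Sentinel-2-like, 20 m) to
terrestrial drivers such as soil erosion, soil phosphorus and nitrogen,
temperature, and topography, summarized in buffer zones around each lake.
It is written for limnologists and land-management researchers who want the
method exercisable end to end without downloading continental rasters: a
first-class synthetic-data module generates scenes, lakes and covariates
with known ground truth and a plantable driver structure.

## The method

**Floating Algae Index (FAI).** Per pixel, the near-infrared reflectance is
compared against a linear baseline interpolated between the red and
shortwave-infrared bands:

    FAI = R_NIR − [ R_RED + (R_SWIR − R_RED) · (λ_NIR − λ_RED) / (λ_SWIR − λ_RED) ]

with band-center wavelengths λ in nm (Sentinel-2A B4/B8a/B11 defaults:
664.6 / 864.8 / 1613.7). Open water sits on or below its baseline; floating
algae push FAI positive. A pixel is classified as bloom when FAI ≥ 0.02
(the widely used threshold; 0.05 is available for sensitivity runs).

**Bloom occurrence (BO)** is the percentage of monthly scenes in which a
pixel is bloom, out of the scenes with valid data there. **Maximum bloom
extent (MBE)** is the area of a lake's pixels that bloomed in at least one
scene (pixels with BO = 0 are removed before summing). Lakes are classed
small (< 1 km²), medium (1–100 km²) or large (> 100 km²) by area and
shallow (< 3 m) or deep (≥ 3 m) by mean depth.

**Buffer zones.** Terrestrial covariates are summarized in cumulative
shoreline buffers at 100, 200, 500 and 1000 m (the lake surface excluded):
the mean of the cells whose centers fall in the zone, except soil erosion,
which is summed as a relative proxy for mobilized sediment.

**Driver ranking.** A random forest regresses per-lake MBE on the seven
covariate summaries, separately per buffer distance (ntree = 200,
mtry = ⌊p/3⌋ = 2). Importance is the residual-sum-of-squares metric — the
total RSS decrease over all splits on a covariate, across all trees —
reported as a percentage. Group contrasts (years, size and depth classes)
use two-sided Welch t-tests with compact letter displays.

## Worked example

The numbered scripts under `analysis/` run the study on a simulated
two-year, 40-lake region in which buffer-summed erosion is the planted
driver of bloom extent:

```
python analysis/01_simulate_region.py
python analysis/02_bloom_metrics.py
python analysis/03_zonal_covariates.py
python analysis/04_driver_importance.py
python analysis/05_group_comparisons.py
```

Script 02 prints the bloom bookkeeping:

```
2021: total MBE 4.153 km2, mean per-lake BO 69.5%
2022: total MBE 4.190 km2, mean per-lake BO 68.5%
threshold 0.02 -> 0.05: total MBE 4.356 -> 4.344 km2 (0.3% reduction)
```

i.e. about 4.2 km² of lake surface bloomed at least once per year, the
average ever-bloomed pixel was bloom in ~69% of months, and the stricter
0.05 threshold shrinks the detected extent (the margin is small here
because the simulated bloom spectrum sits well above both thresholds).
Script 04 then recovers the planted driver at every buffer distance:

```
d=   100 m: top driver erosion_sum (54.4% of RSS reduction)
d=   200 m: top driver erosion_sum (55.4% of RSS reduction)
d=   500 m: top driver erosion_sum (50.8% of RSS reduction)
d=  1000 m: top driver erosion_sum (39.9% of RSS reduction)
```

and script 05 reports, e.g., that medium lakes carry significantly larger
MBE than small ones (`t=3.15, p=0.0048`) while years do not differ — both
as constructed. Tables land in `results/`.

The same pipeline runs from one command over files on disk (GeoTIFF scenes
and covariates, GeoJSON lakes) or a built-in demo:

```
lakebloom run-all --synthetic --seed 7 --outdir demo_run
lakebloom simulate --seed 7 --outdir region && lakebloom metrics --help
```

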