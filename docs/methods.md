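# Methods

This note records the scientific and numerical choices behind `lakebloom`:
what each stage computes, the conventions adopted where the standard
description leaves room, what the synthetic data does and does not emulate,
and the known limitations.

## Index and classification

The Floating Algae Index is the baseline-subtraction form: the NIR
reflectance minus a red→SWIR linear baseline evaluated at the NIR
wavelength. It is invariant to adding a constant across the three bands and
exactly zero for any spectrum linear in wavelength; both properties are
enforced by tests at 1e-12. FAI is computed in double precision over the
full grid — restriction to lake surfaces happens downstream, so the index
raster stays reusable for inspection. Reflectance is not clamped beyond
nodata handling; a pixel missing in any contributing band is missing in
FAI and excluded from all downstream counts.

Threshold classification is inclusive (bloom ⇔ FAI ≥ t), so a pixel at
exactly the printed threshold is detectable; the comparison convention is
configurable and logged. The default threshold is 0.02, with 0.05 used in
sensitivity runs; extent is monotonically non-increasing in the threshold,
which the suite asserts lake-by-lake.

Default wavelengths are the Sentinel-2A band centers for B4/B8a/B11
(664.6, 864.8, 1613.7 nm); a Sentinel-2B set is provided. The green band is
carried in the data model for completeness but does not enter the index.

## Compositing conventions

- **BO denominator.** Bloom occurrence divides by the number of scenes
  with *valid data at that pixel*, not the total scene count. With complete
  scenes the two coincide; with per-pixel gaps the valid-scene denominator
  is the faithful generalization.
- **MBE.** Pixels with BO = 0 are removed; the remaining lake pixels are
  counted and converted by the pixel area (400 m² at 20 m), reported in
  km². MBE can never exceed the rasterized lake area.
- **Lake-level mean BO** averages per-pixel BO over the ever-bloomed
  pixels only (consistent with removing 0 % pixels before further
  analysis). Averaging over all lake pixels instead is a one-line change
  and the choice is recorded in run metadata.
- **Pixel-in-lake rule** is center containment. The all-touched
  alternative systematically inflates small lakes; center containment is
  unbiased for area.
- **Years.** Scenes carry `YYYY-MM` tags; summaries are produced per year
  and pooled, so two-season products and their comparison come from one
  pass.
- **Class boundaries.** Size: small < 1 km² ≤ medium ≤ 100 km² < large.
  Depth: shallow < 3 m ≤ deep; missing depth ⇒ unknown, excluded from
  depth contrasts.

## Buffers and zonal summaries

Buffer zones are **cumulative** (shoreline out to d) rather than annular;
zones for increasing distances are nested, which makes "importance at
distance d" read as "everything within d". An annular mode exists for users
who want disjoint bands. The lake's own surface is excluded — the
covariates here are terrestrial drivers — and that exclusion is an
assumption of this implementation, stated rather than inherited.

Polygon buffering uses 16 quadrant segments (64 per full circle); ring
areas agree with closed-form annulus/Minkowski values to well under 1 %.
Cell selection is center containment, consistent with the lake rule.
Covariates are summarized on their native grids with no resampling; nodata
cells are excluded, and a zone with no valid cell yields a missing value
whose row is dropped (and counted in the log) before model fitting.
Erosion's "sum" is the plain sum of cell values in native units — a
relative sediment proxy, deliberately not area-normalized to tonnes.

Spatial inputs must be in a projected, meter-based CRS; coordinates that
look geographic (degrees) are rejected on read rather than silently
buffered in degrees. Raster georeferencing travels in standard GeoTIFF
tags via `tifffile`; vectors are GeoJSON via `shapely`.

## Forest and importance

The forest is a standard regression forest (scikit-learn) with the two
fixed hyperparameters ntree = 200 and mtry = ⌊p/3⌋ (= 2 for seven
predictors; re-floored, minimum 1, after covariate-removal reruns).
Remaining settings follow common defaults — bootstrap resampling of rows,
minimum leaf size 5, no depth cap — and are echoed in output metadata.

Importance is **impurity (RSS) importance**, extracted in-package from the
fitted tree structures: each split's decrease in weighted node RSS is
credited to its split variable and summed over nodes and trees. It is not
the library's pre-normalized attribute, so raw scores, percentages (which
sum to 100 before rounding) and the ranking (descending, alphabetical
tie-break) are all well defined. Permutation importance is not the metric
here; the model's purpose is covariate ranking, not prediction, so no
hyperparameter search or OOB headline is reported. The response is
untransformed MBE in km²; a log10(ha) option exists only in the land-cover
table, where the display is conventionally logarithmic.

Fits are deterministic given the seed. A planted-recovery benchmark
(standardized MBE = 0.5·std(buffer-summed erosion) + N(0, 0.1²), 300
lakes, six independent nuisance covariates) must rank erosion first in at
least 18 of 20 seeded replicates; a null benchmark (response independent
of all covariates) must produce no covariate top-ranked in more than half
of 50 replicates. An independent forest implementation (R `ranger`,
impurity mode) is used as a cross-implementation check in the test suite.

## Statistics

Group contrasts use the two-sided independent t-test in its
unequal-variance (Welch) form — the default of R's `t.test`, matching how
such comparisons are conventionally run — with Student's pooled variant
behind a flag. The statistic and Welch–Satterthwaite degrees of freedom
are computed from the closed form, with the reference implementation
serving as an independent check (agreement to 1e-10). Both samples need
n ≥ 2 and at least one nonzero variance. No multiple-testing correction is
applied across pairwise comparisons; raw letters are reported and the
omission is noted in output metadata.

The compact letter display uses insert-and-absorb: start from one letter
covering all groups; for each significant pair, split every letter
containing both and keep only maximal sets. The defining invariant — two
groups share a letter iff their pairwise test is non-significant — is
verified exhaustively for every significance pattern on up to four groups.
Groups are lettered so the highest mean gets the earliest letter.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* of the real inputs: monthly
co-registered multiband stacks in which bloom pixels raise NIR above the
red–SWIR baseline; non-overlapping lake polygons spanning the small and
medium size classes and both depth classes; smooth covariate fields
(Gaussian-smoothed white noise, rescaled to plausible per-covariate
ranges, erosion strictly positive and right-skewed). Default class
spectra are water (R/N/S = 0.02/0.01/0.005, FAI ≈ −0.007), bloom
(0.03/0.10/0.01, FAI ≈ +0.074) and a vegetation-like land spectrum whose
high FAI deliberately *would* count as bloom if lake masking leaked — a
built-in canary. The noiseless separation margins across the threshold are
verified at generation time, not trusted. One scene per month, default
eight (a March–October season); sixteen months yields two tagged years.
Reflectance noise is Gaussian (default sd 0.005, ~7 % of the bloom–water
FAI gap) with clipping to the physical range.

The planted driver link operates at lake level: a standardized index
combines the standardized buffer summaries with configured weights
(default erosion 0.5) plus Gaussian noise (default sd 0.1), and is mapped
affinely onto per-lake bloom fractions — scaled by the smallest lake's
area so every fraction stays in (0, 1) — then quantized to whole pixels.
Standardized true MBE therefore equals the standardized index up to
quantization. Monthly bloom sets are nested prefixes of one contiguous
patch per lake, with one month forced to the full patch, so the
ever-bloomed extent equals the planted MBE exactly and per-pixel BO is
known in closed form.

What it does **not** emulate: atmospheric and sun-glint effects, clouds
and the cloud-screening step, sensor noise beyond the Gaussian
perturbation, mixed shoreline pixels, spatial correlation between
covariates (fields are independent by construction), watershed routing,
and between-lake ring overlap effects. Passing tests therefore demonstrate
the correctness of the *computation* — compositing, geometry, extraction,
ranking — not the radiometric detectability of blooms in real imagery.

## Problem sizes and numerics

The suite and the acceptance script run on deliberately modest sizes
chosen as desk-scale analogs: a 512×512 (≈ 10 km × 10 km at 20 m), 6-lake,
8-month region for exact oracle equivalence; 300 lakes on a 1400×1400 grid
per planted-recovery replicate (20 replicates); 120 lakes on 900×900 for
each of 50 null replicates; a 768×768, 40-lake, two-year region for the
worked analysis. Randomness everywhere derives from explicit
`numpy.random.default_rng` seeds; reruns of the full pipeline are
byte-identical, which the suite checks at the artifact level.

Degenerate inputs fail loudly rather than silently: equal red/SWIR
wavelengths, non-positive buffer distances, duplicate lake ids, constant
responses or all-constant predictors, empty scene lists, all-zero
importance totals. Geometry that can be repaired (`make_valid`) is
repaired and logged; what cannot be is dropped and logged.

## Limitations

- No reprojection: inputs must arrive in one projected meter-based CRS.
- Forest importance ranks drivers but carries no sign or effect direction;
  impurity importance can favor high-cardinality or high-variance
  predictors in ways permutation importance would not (offered as a
  cross-check, not the headline).
- Buffer zones are a pragmatic proxy for the contributing landscape, not
  hydrology: no watershed delineation, flow routing or sediment delivery
  modeling, and overlapping rings of neighboring lakes are not resolved
  (the 1000 m cap limits, but does not eliminate, interference).
- The land-cover table drops lakes with zero bloom extent (log10
  undefined), so it conditions on blooming lakes.
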