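# Methods notes

## Tracer mass balance

Recoveries use the constant-pool estimator: the pool's N stock is
assumed unchanged over the ~1-year labelling interval, so only the
enrichment change carries tracer signal. The full-balance estimator
(before/after pool sizes) is provided for diagnosis; when a pool grows
at background abundance it reports spurious recovery (the "growth
artifact"), which is why it is not used in the pipeline. When the two
pool sizes are equal the full-balance path delegates to the
constant-pool expression so the algebraic reduction is exact in
floating point, not merely close.

Conventions: abundances are stored as atom percent (0–100) and
converted to fractions only inside formulas; masses are kg N ha⁻¹.
Negative single-pool recoveries (enrichment noise below background)
are floored at zero with a warning — negative mass recovery is
unphysical and flooring is standard tracer practice. Ecosystem
recoveries above 100% are *flagged but not clipped*: they indicate a
measurement problem the analyst must see. Multi-plot sites are
averaged to a site mean with a standard error; multi-year additions
use the cumulative added ¹⁵N as the denominator (the assumption is
noted in the plot-table schema; no decay correction is attempted).

## Synthetic data

The site generator draws the nine predictors uniformly from forest
ranges (MAP 700–2500 mm, MAT 3–22 °C, N deposition 6–54 kg N ha⁻¹
yr⁻¹; soil C/N 10–25, clay 5–45%, leaf C/N 20–50, organic-layer mass
10–80 Mg ha⁻¹, woody biomass 50–350 Mg ha⁻¹, NPP 400–1400 g C m⁻²
yr⁻¹) and builds the fractions from four linear relations: loss
declining with soil C/N (slope −1.5 % per C/N unit), organic-layer
retention rising with organic mass (+0.35 % per Mg ha⁻¹), the plant
share of plant+mineral declining with NPP (−3.5·10⁻⁴ per g C m⁻²
yr⁻¹), and the woody share of plant retention rising with biomass
(+0.12 % per Mg ha⁻¹). Gaussian noise standard deviations (7, 4.5,
0.075, 4.2 in response units) were fixed once so that the refitted
single-predictor R² values land near the field-reported strengths of
these relationships (≈0.43, 0.73, 0.64, 0.86), and form offsets make
nitrate more plant-bound and ammonium more organic-layer-bound; at
mid-range predictors the ammonium means are plant 12, organic 33,
mineral 24, loss 31 (percent of tracer). Fractions are back-computed
so plant + organic + mineral + loss = 100 exactly; loss and organic
predictions are clipped to [0, 100] and proportionally rescaled in the
rare cells where they jointly exceed the budget.

The world generator produces smooth fields (Gaussian-filtered white
noise, rank-rescaled into the site ranges) on a coarse regular
lat/lon grid — 36 × 18 by default, spanning 60° S–70° N. Cell areas
come from the exact spherical band formula R²·Δλ·(sin φ₂ − sin φ₁).
Deposition uncertainty is emulated as four multiplicative smooth
perturbations (±15%) of one total-deposition field split into NHₓ and
NO_y by a smooth share field (0.4–0.7 NHₓ); wood C/N uncertainty as
six multiplicative sets (×0.75–×1.25) of a smooth 250–450 base layer.
Biomes are latitude bands: |lat| < 23.5° tropical, 23.5–50° temperate,
beyond boreal — a transparent stand-in for real biome maps.

What the generator does *not* emulate: real spatial covariance between
predictors (all fields are independent), land/ocean geometry, realistic
global deposition means (site-scale rates are applied everywhere, so
extensive totals are far larger than real-world budgets — intensive
quantities like efficiencies are the comparable outputs), the internal
structure of any real deposition model, or real land-cover classes.
Passing tests therefore demonstrate the correctness and stability of
the inference chain, not the realism of any absolute global total.

## Subset selection

OLS is solved by numpy least squares; rank-deficiency raises. AICc
uses the constant-dropped Gaussian form with k′ = k + 2 parameters
(slopes, intercept, residual variance) and is undefined unless
n > k + 3; inside the exhaustive enumeration, subsets too large for
the sample are recorded as excluded rather than raising, which matters
when ensemble draws refit on 10 sites. VIFs are diagonals of the
inverse correlation matrix of the subset; perfect collinearity is an
+inf sentinel. Ties in AICc (< 10⁻⁹) break toward fewer predictors,
then lexicographic predictor order, making selection deterministic and
order-invariant. The VIF screen is applied per candidate subset, not
to the full nine-predictor pool, since screening the pool would
exclude predictors that are unproblematic in small subsets.

With 13 sites and nine candidates, minimum-AICc selection is honest
but greedy: a pure-noise predictor clears the one-extra-parameter
penalty with probability ≈ 0.09, so the winning subset carries at
least one spurious term in a sizeable minority of replicates. That is
a property of AICc at this sample size, not an implementation defect;
the full ranked ledger is exposed so users can inspect near-ties, and
the simulation tests assert containment of the generative predictor
rather than exact set recovery.

## Upscaling

Two wirings are offered because the relationship chain and per-pool
regressions are both defensible readings of how site models map onto
rasters; *chained* is the default since it mirrors the four relations
used to build the maps and closes the budget by construction. In
regression mode the four pool predictions are clipped to [0, 100] and
proportionally renormalized to 100 (cells predicting nothing anywhere
are assigned 100% loss). Predictions outside the site predictor hull
are allowed but flagged in an extrapolation mask — a 13-site hull
cannot cover a global grid, and silently blocking extrapolation would
empty the map. Forest is cover > 0.2 by default with the 0.1 variant
available by argument; both definitions circulate and the choice is
left to the user.

## Carbon sink

The wood saturation factor f interpolates linearly between the anchor
points (15, 1), (30, 0.5), (100, 0) — the simplest continuous rule
honoring all three — and is evaluated from the *total* (NHₓ + NO_y)
load by default even for a single form's sink, since growth saturation
responds to the whole N input; per-form evaluation is available via
`n_dep_total`. The soil-immobilization fraction s = 0.8 multiplies
both the organic-layer and mineral-soil terms; non-woody plant
retention (foliage, fine roots) contributes nothing, as that tissue
turns over within years. Setting s = 1 and f ≡ 1 recovers the
classical rigid-stoichiometry product estimate, which is tested as a
limit.

## Uncertainty

Site resampling is 10-of-13 without replacement per draw; each draw
refits the full selection and re-upscales, then crosses with every
deposition map and wood-C/N set (desk default 50 × 4 × 6 = 1200
members; the reference crossing is 1000 × 4 × 6 = 24,000). The master
seed spawns one `SeedSequence` substream per draw, so runs are
bit-reproducible and draws replayable in isolation. Draws whose
selection fails (all subsets screened out) are skipped and logged,
never imputed. Totals are summarized with empirical percentile
intervals (members are sorted first, so summaries depend only on the
multiset); retention-map uncertainty is the per-cell standard
deviation of the fraction layers across draws. Gaussian intervals were
rejected because sink distributions across C/N sets are visibly
skewed.

## Numerical choices and degenerate inputs

- Sum-to-100 closure is enforced to ≤ 10⁻⁹ at every forest cell in
  both modes; the chained allocation clamps the available share at 0
  against float cancellation.
- Classic NetCDF (scipy backend) carries all grids; 64-bit ints and
  booleans are downcast on write.
- JSON artifacts are written with sorted keys so identical seeds give
  byte-identical files.
- Problem sizes were chosen for desk-scale iteration: 36 × 18 grids
  and 50-draw ensembles exercise every code path at a few seconds per
  run; all formulas are resolution-independent.

## Known limitations

- One-year tracer recoveries capture short-term fates only; no
  multi-decadal C–N turnover, no re-release of previously retained N.
- No gaseous-vs-leaching split of the loss term; no δ¹⁵N→atom-%
  conversion chain for raw mass-spectrometry output.
- No reprojection or resampling: grids must arrive co-registered.
- Linear regressions on the percent scale can predict outside [0, 100]
  far from the site hull; values are clipped and the extrapolation
  mask should be consulted before interpreting remote cells.
- The ensemble varies sites × deposition × wood C/N only; predictor-
  layer uncertainty and within-site plot variance are not propagated.
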