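# Methods

## Data model

One record is one (site, medium) pair: a site measured simultaneously
in bulk precipitation and throughfall contributes two rows sharing a
`site_id`. Bulk precipitation (open-funnel collection) captures wet
deposition plus sedimenting dry deposition; throughfall (collected
beneath the canopy) additionally captures canopy-filtered dry
deposition net of canopy exchange, and is treated as the better proxy
for total deposition. Chemistry fields are nullable per ion, so a
site can enter the SO₄²⁻ analysis but not the NO₃⁻ analysis; every
statistic reports its own n. Because H⁺ is carried as pH, a record
with null pH drops out of all three H⁺-derived analyses (pH curve, H⁺
concentration and H⁺ flux) at once.

Validation is strict-reject per row: literature-compiled tables are
ragged, and a malformed row is dropped with a row-indexed diagnostic
rather than aborting the file. Coordinates are WGS84 decimal degrees
only.

## Chemistry arithmetic

* H⁺ [μeq L⁻¹] = 10^(6 − pH); the inverse is exact to double
  precision, and both directions reject arguments outside (0, 14) /
  (0, ∞).
* Flux [keq ha⁻¹ yr⁻¹] = concentration [μeq L⁻¹] × precipitation
  [mm yr⁻¹] × 10⁻⁵. The constant is fixed by dimensional analysis
  (1 mm over 1 ha = 10⁴ L). Fluxes are always computed per site and
  then summarized; summarizing concentrations first and converting
  with an average precipitation gives a different (wrong) number, and
  a test pins the distinction.
* Summaries are geometric means, exp(mean(ln x)), the natural location
  statistic for positive right-skewed deposition data. Non-positive
  values are excluded with a warning and a reduced n; no pseudo-count
  is added because none is defensible. Across-site pH summaries use
  the reported site pH values as-is — site pH is already an aggregated
  quantity, and re-transforming it through H⁺ activity would
  double-transform.
* Event-level volume-weighted means are provided for users aggregating
  raw sampling events: Σvᵢcᵢ/Σvᵢ for concentrations, and for pH either
  in H⁺-activity space (default; chemically meaningful) or directly in
  pH units. Which mode produced a site's value is recorded in the
  pipeline report (`ph_mode`), since published site tables rarely say.

## Distances

Distances are haversine great-circle distances on a sphere of radius
6371.0088 km; at regional scales the sphere-vs-ellipsoid error
(< 0.5%) is far below the scatter in the chemistry. Each site is
assigned to its nearest registry city (nonagricultural population
strictly > 0.5 million by default); exact ties break lexicographically
by city name for determinism. A 1 km floor guards the power law's
divergence at x → 0; real forest sites sit outside city cores, so the
floor only matters for degenerate synthetic inputs. Distances
transcribed from publications can be kept (`keep` policy) or replaced
(`recompute`); a >10% divergence between the two is flagged.
Anisotropic (wind-driven) distances are out of scope.

## Regressions

The power law y = a·x^b is fitted by OLS on (ln x, ln y), i.e. under a
multiplicative lognormal error model, which matches how the synthetic
data are generated and why geometric means summarize the data. a > 0
is guaranteed by construction (a = exp intercept); non-positive y
values are rejected with a logged count. An NLS refinement on the
original scale (Levenberg–Marquardt, initialized from the log-log fit)
is available because the original fitting scale of such curves is
often unstated in the literature; each fit records which scale its R²
refers to. pH is fitted as pH = c + d·ln x. The two forms are
algebraically linked: a noise-free logarithmic pH profile corresponds
to an H⁺ power law with b = −d·ln 10 and a = 10^(6−c), and a test
checks the identity numerically.

Slope inference (standard errors, 95% t-intervals, two-sided p-value
of slope = 0) comes from the log-scale regression; each curve is
flagged significant at P < 0.05 with no multiple-testing correction —
the curves are reported individually, not screened as a family. The
minimum n is 3 (two parameters plus one residual degree of freedom);
cells with fewer usable points are recorded as unavailable rather than
failing the whole table. A complete study yields 18 fits: per medium,
one pH curve plus {H⁺, SO₄²⁻, NO₃⁻, NH₄⁺} × {concentration, flux}.

## Potential acid load and critical radius

PAL(r) = a_H·r^(b_H) + 2·a_N·r^(b_N), built from the throughfall H⁺
and NH₄⁺ flux fits (bulk available behind `radius_medium="bulk"` for
sensitivity). The factor 2 reflects nitrification: each deposited
NH₄⁺ yields one proton directly and releases the proton it neutralized
in the atmosphere. The critical radius solves PAL(r*) = CL, CL
defaulting to 2 keq ha⁻¹ yr⁻¹ — an upper bound on soil critical loads
of acidity in the humid subtropical region this package targets — by
bisection on [1, 10 000] km driven to floating-point convergence
(load matched far below 10⁻⁹ keq ha⁻¹ yr⁻¹; agrees with the
single-term closed form (a/CL)^(−1/b) to better than 10⁻⁶ km). Both
exponents must be negative for the curve to be monotone; PAL(1 km)
< CL means no island (radius 0, flagged, not an error), PAL(10⁴ km) ≥
CL means the crossing is outside any regionally meaningful bracket
(error). PAL(1 km) = CL exactly returns the 1 km floor.

## Island area

The acid-island area is the union of geodesic discs of radius r*
around the registry cities, clipped to the region polygon. Two
estimators cross-check each other:

* **projected_union** (default, deterministic): each disc boundary is
  traced with 256 points by the spherical direct-geodesy formula, and
  discs and region (edges densified to ≤ 0.05°) are projected to a
  spherical Lambert azimuthal equal-area plane centered on the region,
  where shapely unions, clips and measures. The 256-gon truncation
  biases a disc's area by ~10⁻⁴ relative; an unclipped disc matches
  the spherical-cap closed form 2πR²(1 − cos(r/R)) within 0.1%.
* **mc** (seeded): points uniform on the sphere within the region
  (uniform longitude × uniform sin latitude, rejected against the
  polygon); the hit fraction within r* of any city scales the region
  area. With the default 10⁶ points the binomial standard error on a
  ~0.3 fraction of a ~2.8 M km² region is ≈ 0.05% of the region. The
  two methods must agree within ~3 MC standard errors; tests enforce
  this on randomized configurations.

Region polygons are GeoJSON in lon/lat with lon/lat-straight edges;
the sampler and the projection define containment identically, so the
estimators target the same region.

## Emission and enrichment arithmetic

Acid equivalents of precursor emissions: SO₂ → 2·TgS/32.06, NOₓ and
NH₃ → TgN/14.007 (Teq yr⁻¹; molar masses standard atomic weights, two
protons per S). The acidification-capacity ratio is eq(SO₂)/eq(NOₓ)
and the NH₃ neutralization fraction eq(NH₃)/(eq(SO₂)+eq(NOₓ)); with
32 instead of 32.06 for sulfur both change by < 0.2%. Enrichment
ratios are throughfall/bulk ratios of geometric-mean fluxes per ion,
invariant to common rescaling.

## Synthetic generator

The generator emulates the study conditions the analysis assumes:
5 cities and 33 sites (each with a bulk and a throughfall row) in a
rectangular region spanning 100–121°E, 21–33°N (~2.77 M km², a
southern-China-scale domain); site–city distances log-uniform on
[2, 300] km (leverage across two decades of x, matching deposition
gradients observed out to a few hundred km); concentrations
a·x^b·exp(ε), ε ~ N(0, 0.3²); pH c + d·ln x + η, η ~ N(0, 0.25²),
clipped to (3, 9) with clips counted; precipitation uniform on
1200–2200 mm yr⁻¹ (humid subtropics), shared between a site's two
rows; throughfall = bulk × per-ion enrichment {SO₄ 1.82, NO₃ 1.56,
NH₄ 1.34} applied before noise so the enrichment oracle is exact in
expectation.

Ground-truth anchoring: amplitudes are set so each quantity's
geometric mean at the geometric-mean distance (√(2·300) ≈ 24.5 km)
equals region-typical levels — bulk pH 5.5, throughfall pH 5.8, bulk
SO₄/NO₃/NH₄ 101.2/19.1/47.6 μeq L⁻¹. Decay exponents are not pinned
down by those levels and are fixed at b = −0.40/−0.25/−0.35 (d = 0.30
for pH), nitrate flattest because road-traffic NOₓ blurs its urban
gradient. With this anchoring the true PAL curve crosses
2 keq ha⁻¹ yr⁻¹ at ≈ 31 km; the critical radius of a real network
depends on the fitted curves of that network, and published radii for
comparable regions (≈ 70 km) correspond to steeper, higher-amplitude
flux curves than the GM-anchored defaults — the generator prioritizes
matching the summary levels, which are the quantities its oracle
tests consume. Chemistry is generated from each site's *nearest-city*
distance (recomputed after placement), so noise-free data are exactly
recoverable (R² = 1) by the fitting stage; the written `distance_km`
column is left null to force the pipeline through the proximity stage.

What the generator does not emulate: atmospheric transport physics,
wind-direction anisotropy, spatially correlated residuals, multi-city
superposition of plumes, base-cation neutralization gradients, or
observation-period heterogeneity. Passing recovery tests therefore
show the estimators are consistent under the assumed error model, not
that the error model is true of any real network.

The packaged fixture (`acidisland/data/fixture_*`) is one generator
draw (seed 1234, defaults) committed for fast end-to-end tests and
docs; a test regenerates it from its config and asserts equality, so
it cannot drift from the generator.

## Problem sizes and numerical choices

Default study size is 33 sites × 2 media and 5 cities, the scale of a
regional literature synthesis; Monte Carlo area uses 10⁶ points;
recovery experiments in the tests use 500 fit replicates and 200
pipeline replicates with 199 bootstrap resamples. All stochastic
steps take explicit integer seeds; identical seeds give byte-identical
site tables and reports. Ties, floors, brackets: lexicographic city
tie-break, 1 km distance floor, [1, 10 000] km radius bracket,
bisection to float convergence, pH clip (3, 9).

## Known limitations

* Throughfall underestimates total deposition (canopy uptake of N and
  H⁺), so throughfall-based radii are conservative; the package
  reports the enrichment ratios that quantify this but does not
  correct for canopy exchange.
* One radius is applied to every city; population- or emission-scaled
  per-city radii are not modelled.
* The log-log OLS assumes independent homoscedastic log residuals;
  spatial correlation between nearby sites would shrink effective n
  and widen true intervals relative to the reported ones.
* The Monte Carlo sampler treats the GeoJSON polygon's lon/lat-straight
  edges as the region definition; for very large polygons with long
  edges this differs slightly from great-circle-edged regions.
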