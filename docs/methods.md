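# Methods

This note documents the models implemented in `tuces`, the choices made
where conventions diverge, and what the synthetic study design can and
cannot show.

## Synthetic basin generator

`SyntheticConfig` fixes the study conditions; the defaults describe a
semi-arid temperate basin at desk scale: a 60×60 grid of 25 km² cells
(300 × 300 km), 12 cities, observation years 2000/2010/2020, grassland-
dominated composition (42% grassland, 20% cropland, 18% barren, 12% forest,
5% construction, 3% water), mean precipitation 450 mm/yr rising ~40% toward
the east, and Hargreaves-derived potential evapotranspiration near
1000 mm/yr. Grid size and cell count were chosen so that a full pipeline
run, including permutation inference, completes in under a second while
every zonal statistic still averages hundreds of cells.

City zones are the Voronoi cells of seeded points, which yields contiguous,
irregular zones with a well-defined queen adjacency. Land use starts as an
i.i.d. multinomial draw from the configured class fractions and evolves by a
row-stochastic 6×6 Markov matrix per decade step; the default matrix has
strong diagonals with barren→grassland (revegetation) and
cropland→construction (urban expansion) as the dominant off-diagonal flows.
Construction growth is spatially clustered by a post-sampling relocation
step: with probability `construction_cluster`, a newly converted
construction cell swaps outcomes with a same-source-class cell adjacent to
existing construction. Because swaps act within a source class, all class
counts and empirical transition frequencies are preserved exactly; only the
spatial placement changes. The core `apply_transition_model` remains pure
per-cell row sampling, so its frequencies converge to the configured rates
at the binomial rate (tests check 3σ bands at ≥10⁴ cells per source class).

The indicator panel follows
`value = baseline_j · gradient_factor · trend_j^k · exp(ε)`,
ε ~ N(0, noise_sd²): lognormal noise keeps yearbook-like values strictly
positive and right-skewed. Positive-direction indicators scale with
`1 + g·easting`, the three industrial-pressure indicators (E1–E3) with
`1 + g·(1 − easting)`, so with zero noise every indicator is exactly
monotone (or antitone) in city easting. Per-decade trend factors grow
tourism fastest (×1.5–1.7), urbanization moderately, and shrink the
pressure indicators (×0.7–0.75), emulating improving environmental
governance. Each layer draws from an independently salted RNG stream, so
e.g. regenerating the panel never perturbs the land-use sequence.

What the generator does *not* emulate: real basin geometry and topographic
routing, spatial autocorrelation *within* climate noise (noise is white),
monthly seasonality (PET and precipitation are annual totals; whether the
source PET was summed monthly is unknowable, so annual totals are emitted
directly), indicator cross-correlations beyond the shared gradient, and
missing data. Passing tests therefore demonstrate correctness of the
*methods* under known conditions, not conclusions about any real basin.

## Ecosystem services

The four services use canonical InVEST-style formulations with every
constant exposed in `RunConfig`:

- **Water yield.** Budyko–Zhang with `ω = z·S/P + 1.25`; the
  plant-available storage is `S = min(AWC, root-restricting depth)` in mm.
  `z_param` defaults to 3 (mid-range of the 1–30 seasonality constant).
  Water bodies, construction and barren cells bypass the curve and lose
  `min(PET, P)`. Output is clamped to [0, P].
- **Soil conservation.** Local RUSLE retention `R·K·LS·(1 − C·P)` in
  t/ha/yr. Sediment routing (SDR) is deliberately omitted: reported values
  are per-area retention with no routing description to mirror. Any display
  rescaling (e.g. 10⁷ t/ha) is applied only at output, never in the math.
- **Habitat quality.** Degradation is the decay-kernel convolution of each
  threat's intensity raster, weighted by `w_r/Σw` and by per-class
  sensitivity, with linear or exponential decay zero beyond `d_max`
  (exact Euclidean cell-center distances inside the kernel; FFT convolution
  with clipping of ~1e-16 negatives). Normalizing threat weights by their
  sum keeps the degradation scale stable against `k_half` as threats are
  added. `Q = H·(1 − D^z/(D^z + k_half^z))`; `k_half` = 0.5 and
  `z_exp` = 2.5 by default, both configurable because the source convention
  is not recoverable. The pipeline's default threat is construction
  presence (d_max 10 km, linear decay).
- **Carbon storage.** Four-pool per-class lookup (t/ha); the bundled
  default biophysical table holds plausible semi-arid temperate values
  (forest densest at 170 t/ha, water zero).

Zonal aggregation excludes nodata and flags empty zones as missing (NaN),
never zero. Annualized change is `(ES_t1 − ES_t0)/span`. Trend
classification uses a two-sided Mann–Kendall test at α = 0.05 (tie-corrected
variance, continuity correction) when a series has ≥4 timepoints, with the
sign of the rate giving direction; with fewer points it falls back to a
|rate| ≤ threshold rule, since a 3-point series cannot support a
distributional significance claim.

## TU index

Min-max normalization is directional and pooled **globally** over all
city-years by default, which keeps scores comparable across years (per-year
pooling is available for sensitivity checks). Normalized values are
affinely mapped onto [ε, 1] with ε = 1e-4 so the entropy logarithm is
defined while ranks are untouched. The entropy `n` is the number of
city-year rows in the pooling window. Exactly uniform columns receive
weight 0; a panel in which *every* column is uniform raises a
zero-denominator error.

Subsystem scores renormalize weights within each subsystem by default so
each axis spans [0, 1] and the customary 0.2/0.4/0.6/0.8 level bands are
attainable; the unrenormalized variant (axes bounded by each subsystem's
global weight mass) is available by flag, since either convention is
defensible. Likewise the composite is reported both as the raw Euclidean
norm and rescaled by √3 onto [0, 1]; the rescaled value is the default `u`
input to the coupling stage.

## Coupling

`C = 2√(w·u)/(w+u)` is undefined (0/0) at `w = u = 0` and the package
raises rather than imputing 0. ES values are min-max normalized per service
pooled across all city-years (all services treated as benefits). Bands are
left-closed/right-open with the final band closed — a total, deterministic
rule for boundary values like D = 0.8. Both the five-band methods scale and
the four-band display scale (cuts 0.3/0.5/0.7) are emitted because the two
conventions coexist in practice and neither should be silently preferred.

## Spatial statistics

Queen contiguity counts any shared boundary point (a single corner
suffices); rook is available. Binary unstandardized weights are the default
so the explicit `S0` term of the statistic is meaningful; row
standardization is a flag. The permutation test reports
`p = (1 + #{I_perm ≥ I_obs})/(n_perm + 1)` for the upper tail and doubles
the smaller tail (capped at 1) for the two-sided default, which is exact
and slightly conservative. Island zones are flagged with a warning rather
than an error, matching how practitioners handle them.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.Generator` seeded from the
  config; per-layer streams are salted `SeedSequence`s, so outputs are
  bit-identical across reruns and insensitive to stage reordering.
- Constant indicator columns, constant ES series, zero-variance Moran
  inputs, all-nodata rasters and empty flow matrices raise typed errors
  naming the offender instead of producing NaNs.
- Transition matrices exclude cells that are nodata at either timepoint
  (nodata is not a pseudo-class).
- Shares are computed at full precision; rounding to the customary 2
  decimals happens only in display.

## Known limitations

- No sediment routing, no monthly water balance, no monetary valuation.
- Per-pixel trend significance from three timepoints is not attempted;
  Mann–Kendall requires ≥4 points and the package says so.
- The habitat-quality degradation scale depends on threat parameterization;
  comparisons across configurations require fixed `k_half`.
- Polygon-based contiguity is O(n²) pairwise; fine for city-scale zone
  counts, not for thousands of polygons.
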