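# tuces

Coupling-coordination analysis of **t**ourism **u**rbanization and
**ec**osystem **s**ervices, implemented as a tested, seed-reproducible
pipeline over synthetic landscapes.

Regional-sustainability studies increasingly ask how tourism-driven
urbanization and the supply of ecosystem services co-evolve across the cities
of a river basin. The standard workflow couples three ingredients: spatially
explicit ecosystem-service (ES) models in the InVEST tradition, an
entropy-weighted composite index of tourism urbanization (TU) built from
municipal yearbook indicators, and a coupling-coordination-degree (CCD) model
that scores how balanced the two systems are in each city and year. The
underlying yearbook panels and 30 m rasters are rarely redistributable, so
`tuces` ships a seeded synthetic-data generator that emulates their
statistical structure — a six-class Markov land-use mosaic with clustered
construction growth, strictly positive climate/soil layers, Voronoi city
zones, and a 22-indicator panel with an east-high/west-low development
gradient — making every stage of the analysis runnable and verifiable from a
single seed.

## The models

**Ecosystem services** (per cell, then averaged over city zones):

- *Water yield* (mm): Budyko–Zhang curve,
  `AET/P = 1 + PET/P − (1 + (PET/P)^ω)^(1/ω)` with `ω = z·S/P + 1.25`,
  storage `S = min(AWC, root depth)`; `WY = P − AET`. Water, construction and
  barren cells evaporate `min(PET, P)`.
- *Soil conservation* (t/ha/yr): RUSLE retention `R·K·LS·(1 − C·P)`.
- *Habitat quality* (0–1): `Q = H·(1 − D^z/(D^z + k^z))`, degradation `D`
  accumulated from threat sources with linear `1 − d/d_max` or exponential
  `exp(−2.99·d/d_max)` distance decay and per-class sensitivities.
- *Carbon storage* (t/ha): sum of above-/below-ground, soil and dead pools
  per land-use class.

**TU index**: directional min-max normalization of the 22 indicators onto
[ε, 1], entropy weights `ω_j = (1 − E_j)/Σ(1 − E_j)` with
`E_j = −(1/ln n)·Σ_i p_ij ln p_ij`, entropy-weighted subsystem scores
(tourism, urbanization, eco-environment), and the state-space composite
`TU = √(S_urban² + S_tourism² + S_eco²)` (rescaled by √3 onto [0, 1]).

**Coupling**: for normalized ES value `w` and TU value `u`,
`C = 2·√(w·u)/(w + u)`, `T = α·w + β·u` (α = β = 0.5),
`D = √(C·T)`, banded into five coordination levels (cuts 0.2/0.4/0.6/0.8)
and an alternative four-level display scale (0.3/0.5/0.7).

**Spatial statistics**: queen-contiguity weights from zone rasters or
polygons and global Moran's I
`I = (n/S0)·Σ w_ij (x_i−x̄)(x_j−x̄) / Σ(x_i−x̄)²` with permutation
inference (null expectation −1/(n−1)).

## Worked example

```python
from tuces import RunConfig, SyntheticConfig, run_pipeline

result = run_pipeline(RunConfig(synthetic=SyntheticConfig(seed=1)))
print(result.ccd_change.round(3).to_string(index=False))
```

prints, for the default 60×60-cell, 12-city, 2000/2010/2020 basin:

```
es_name  t0_year  t1_year  n_cities  share_declining_pct  mean_d_t0  sd_d_t0  mean_d_t1  sd_d_t1
     WY     2000     2020        12                8.333      0.536    0.214      0.647    0.266
     SC     2000     2020        12                0.000      0.529    0.254      0.711    0.223
     HQ     2000     2020        12               16.667      0.608    0.126      0.671    0.236
     CS     2000     2020        12                0.000      0.460    0.184      0.663    0.124
```

i.e. under the default synthetic growth conditions most cities *improve*
their coordination degree between 2000 and 2020, with habitat quality the
most frequently declining service (2 of 12 cities) — the service most
directly degraded by clustered construction growth. The same run yields
Moran's I = 0.472 (permutation p = 0.004) on the 2020 TU index: the imposed
east-west gradient produces significant spatial clustering of development.

The `examples/` directory holds one short script per capability (synthetic
basin, ES layers, TU index, coupling, spatial autocorrelation), and the
`tuces` CLI exposes the same stages (`tuces run --config cfg.yaml --seed 1
--out results/`; also `simulate`, `es`, `tu`, `ccd`, `spatial`, `validate`).

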