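# occuedge

Where within a species' geographic range do local extinctions fall — at the
range edge or in the core?  `occuedge` answers this from gridded,
opportunistically collected occurrence records.  It provides:

* an equal-area (Behrmann) grid with a **distance-to-range-edge metric**:
  per range cell, D0 is the geometric-mean great-circle distance to all
  other cells of the species' range and D' = D0 / max(D0) standardises it
  to (0, 1] with 1 = range edge;
* a **multispecies dynamic Bayesian occupancy-detection model** for two
  periods split at 1980.  Occupancy evolves by persistence and
  colonisation,

      E[z_ij2] = z_ij1 φ_ij + (1 − z_ij1) γ_i,
      logit φ_ij = α_ij + β_ij (D'_ij − 0.5),

  with realm × land-conversion composites
  α_ij = α0(1−R) + α1R + α2(1−R)C + α3RC + u_i (β likewise with v_i), and
  per-survey detection driven by list length (single / short / long
  species lists as an effort proxy),

      logit p_ik = δ_t + δ1_i + δ2_i·short_k + δ3_i·long_k,

  fitted by an adaptive Metropolis-within-Gibbs sampler on the
  analytically marginalised likelihood (a data-augmentation backend
  cross-checks it);
* **posterior products**: summary tables (mean, SD, 95% interval,
  Gelman–Rubin Rhat, sign-consistency f), extinction-rate-vs-D' curves by
  stratum, per-cell richness change with confidence, and per-species
  extinction-rate / edge-proneness / range-size tables;
* a **synthetic-data generator** that emulates opportunistic recording
  with known truth, used for end-to-end validation and parameter-recovery
  studies.

It is written for quantitative ecologists working with presence-only
historical compilations (museum records, atlases, trip reports) who need
extinction inferences that respect imperfect, effort-varying detection.

## Worked example

Simulate the built-in benchmark (30 species on a 20 × 20 two-realm grid),
fit, and inspect the persistence effects:

```python
from occuedge import DynamicOccupancyModel
from occuedge.pipeline import assemble
from occuedge.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig()                      # benchmark study conditions
records, species_cells, cell_attrs, truth = simulate_dataset(cfg, seed=1)
_, _, _, dataset = assemble(records, species_cells, cell_attrs, cfg.grid, 1980)
print(dataset.counts)
res = DynamicOccupancyModel(dataset).fit(seed=101)   # ~3-4 min, 3 chains
print(res.summary().loc[["alpha0", "alpha1", "beta0", "beta3"]])
print("max Rhat:", round(res.max_rhat(), 3))
```

which prints (truth: α0 = 3, α1 = 1.5, β0 = −3, β3 = 2):

```
{'cells_retained': 308, 'cells_only_period1': 36, 'cells_only_period2': 15,
 'species_retained': 29, 'species_dropped': 1, 'pairs': 1122,
 'surveys': 2011, 'binary_observations': 7571, 'period_boundary': 1980}
            mean     sd    q2.5   q97.5   rhat      f
parameter
alpha0     3.092  0.905   1.525   4.970  1.000  1.000
alpha1     1.063  0.346   0.403   1.765  1.006  0.999
beta0     -3.075  3.539 -10.161   3.683  1.000  0.810
beta3      5.973  5.384  -3.503  17.686  1.001  0.883
max Rhat: 1.042
```

Read: persistence is far higher in the R = 0 realm (α0 ≫ α1 on the logit
scale); the negative β0 posterior mean says extinctions in unconverted
R = 0 cells concentrate toward the range edge, the positive β3 that
converted R = 1 cells lose range cores — both signs match the simulated
truth, with f quantifying sign confidence.  Every 95% interval above
covers its true value.  Posterior products then follow from the same
object, e.g. `res.extinction_curves()`, `res.richness_change(seed=202)`,
`res.species_effects()`.

The same analysis runs from the shell on user data
(`occuedge all --config my.yaml --seed 1 --out results/`) given three
tables: records (species_id, lon, lat, year, period_flag, native), range
membership (species_id, cell_id) and cell attributes (cell_id, realm,
converted_fraction).

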