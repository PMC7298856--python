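# vectorenm

Ecological niche modelling of climate-driven range shifts for livestock
disease vectors — built around the cattle tick *Rhipicephalus
(Boophilus) microplus*, whose climatic suitability under present and
future conditions determines where cattle are exposed to tick-borne
disease.

The package is for vector ecologists and veterinary epidemiologists who
want the full calibration–selection–transfer protocol of
correlative niche modelling as a tested, scriptable library rather than
a chain of GUI tools: spatial thinning of occurrence records,
accessible-area (M) construction, collinearity filtering, exhaustive
candidate-model calibration, statistically grounded model selection,
bootstrap-median projection onto climate-model ensembles,
extrapolation-risk surfaces, and livestock-exposure tables.

## The model

The core is a presence–background maximum-entropy model. Over the
background cells *x* of the accessible area it estimates the Gibbs
distribution

```
P(x) = exp(λ·f(x)) / Z,     Z = Σ_background exp(λ·f(x)),
```

where `f(x)` are linear (l), quadratic (q), product (p), threshold (t)
and hinge (h) features of the environmental variables, scaled to [0, 1]
on the training background. The weights λ maximize the L1-penalized
log-likelihood

```
Σ_presences log P(xᵢ)  −  Σⱼ βⱼ |λⱼ|,
```

with per-feature penalties βⱼ following the standard class- and
sample-size-dependent defaults, all multiplied by the user-facing
regularization multiplier (RM). Suitability maps use the cloglog
transform `1 − exp(−e^H · P(x))` with `H` the entropy of the fitted
background distribution.

Candidates over a grid of variable sets × feature-class subsets × RM
values are screened in three stages: partial-ROC significance
(bootstrap AUC ratios restricted to sensitivity ≥ 1 − E, default
E = 0.05), omission rate of evaluation occurrences at the E-percentile
calibration threshold, and finally minimum AICc computed from the
raw-scale likelihood with k = number of non-zero weights. The selected
model is refitted as the per-cell median of bootstrap replicates,
projected onto every (GCM, RCP, period) future stack, binarized at the
common present-day threshold, and summarized as ensemble-agreement and
five-class change maps; overlaying those with cattle-abundance
categories and zoogeographic regions yields percent-modification
exposure tables.

A synthetic-data module generates environmental stacks with prescribed
cross-layer correlation, pseudo-GCM futures, a known truth suitability
surface inside the fitted model family, occurrence samples, and
cattle/region rasters, so the entire pipeline runs and is tested
offline.

## Worked example

```python
from vectorenm.grids import Grid
from vectorenm import synthetic as syn
from vectorenm.maxent import MaxentNiche

grid = Grid(60, 60, 0.2, -100, 10)        # 0.2° cells, 60×60
spec = syn.SyntheticSpec(grid=grid, seed=3)
stack = syn.gen_env_stack(spec)           # 7 correlated climate layers
truth = syn.make_truth(stack, spec)       # known suitability surface
occ = syn.sample_occurrences(truth, 300, seed=5)

model = MaxentNiche.from_stack(stack, occ[["longitude", "latitude"]].to_numpy(),
                               classes="lq")
result = model.fit(rm=1.0)
print(result.summary())
```

prints

```
Maximum-entropy niche model
============================================
presences:        300
background cells: 3600
feature classes:  lq
features:         14
nonzero weights:  14
regularization multiplier: 1.0
log partition:    16.174120
entropy H:        7.615670
training gain:    0.586040
converged:        True
--------------------------------------------
feature                            weight
bio1                             4.265239
bio4                             2.419773
...
```

The positive linear and negative quadratic weights recover the
hump-shaped responses the truth surface was built from; the Spearman
correlation between `result.predict(stack)` and the truth suitability
over all cells is 0.99. The training gain is the improvement of the
mean presence log-likelihood over a uniform model, and k = 14 non-zero
weights is the complexity that enters AICc.

The full pipeline runs from one config:

```bash
vectorenm run --demo --seed 1 --out demo_out
```

which simulates a world, thins (22 km) and splits (50/50) occurrences,
builds the 200 km accessible area, filters collinear variables
(|r| ≥ 0.80), calibrates and evaluates candidates, selects the best
model, projects it to pseudo-GCM futures, and writes MOP, agreement,
change-class and exposure-table outputs plus a manifest with per-stage
checksums. On the demo config all three candidates are significant and
the selected model's evaluation omission is 0.033 at E = 0.05.

## Layout

- `src/vectorenm/grids.py` — grids, layer stacks, haversine, ASCII raster I/O
- `src/vectorenm/synthetic.py` — synthetic landscapes, truth surfaces, pseudo-GCMs
- `src/vectorenm/occurrences.py` — loading, thinning, splitting, accessible area
- `src/vectorenm/envlayers.py` — collinearity filter, variable sets, delta downscaling
- `src/vectorenm/maxent.py` — `MaxentNiche` / `MaxentResults` (the model core)
- `src/vectorenm/selection.py` — partial ROC, omission, AICc, candidate selection
- `src/vectorenm/transfer.py` — bootstrap median, MOP, binarization, ensembles
- `src/vectorenm/exposure.py` — cattle categories, exposure tables
- `src/vectorenm/pipeline.py`, `cli.py` — orchestration and the `vectorenm` CLI

See `docs/methods.md` for the modelling assumptions, parameter
defaults, and known limitations.
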