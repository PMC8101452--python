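# climniche

Climate-niche modelling of ecosystem-service change under future climate
scenarios, with bootstrap uncertainty propagation.

## The problem

High-mountain ecosystems provide ecosystem services — water regulation,
medicinal plants, food, materials — through the plant species that grow
there. Warming and increasing climate seasonality are expected to shift the
set of locations whose climate can support each species, and with it the
spatial basis of every service those species provide. `climniche` implements
a reproducible pipeline for quantifying that change from presence-only
occurrence records and gridded bioclimatic data, for ecologists and
conservation analysts who need uncertainty-aware, service-level summaries
rather than single-species point estimates.

## The model

1. **Environmental space.** The 19 bioclimatic variables (BIO1–BIO19) are
   highly collinear, so a PCA is fitted on the current-climate cells of the
   study area: rainfall-derived variables are log-transformed, all variables
   are z-scored, and the first *k* = 3 principal components define the
   environmental space **E** ⊂ ℝᵏ. Future climate grids are projected with
   the *same* transform, so current and future conditions are comparable.
2. **Fundamental niche.** For a species with occurrence scores
   x₁,…,xₙ ∈ ℝᵏ (one per climate cell), the niche is the ellipsoid defined
   by the sample mean μ̂ and covariance Σ̂. For any climate point x the
   squared Mahalanobis distance D²(x) = (x−μ̂)ᵀ Σ̂⁻¹ (x−μ̂) is referred to a
   χ²ₖ distribution: p(x) = P(χ²ₖ ≥ D²(x)) is the probability that x lies
   within the fundamental niche (1 at the centroid, nested ellipsoids at
   p ≥ 0.9, 0.5, 0.1).
3. **Bootstrap uncertainty.** B = 1,000 with-replacement resamples of the
   occurrence set each yield their own (μ̂ᵦ, Σ̂ᵦ), propagating sampling
   uncertainty into everything downstream.
4. **Potential niche area.** Each bootstrap niche is intersected with the
   realized climate of the study area: the potential-niche area under a
   climate grid is Σ_cells p(x_cell) × cell-area (km²), also expressed as a
   percentage of the study area. For each future (period × RCP) scenario one
   GCM is drawn uniformly at random per bootstrap, folding climate-model
   disagreement into the area distribution; the same bootstrap model is used
   for its own current and future areas (paired design).
5. **Service aggregation.** Each species maps to one or more level-2
   ecosystem services (ES2), nested in four level-1 categories (cultural,
   provisioning, regulating, supporting). Per service, the change
   distribution pools the per-bootstrap changes (future − current, in
   percentage points of study area) over all member species — a species
   contributes once per service it provides — and is visualised as
   beanplots.

A synthetic-data module generates coherent bioclim stacks, controlled
warming ensembles, virtual species with known ellipsoidal niches, and
service catalogues, so the entire pipeline is testable end to end with
known ground truth.

## Worked example

```python
import numpy as np
from climniche import (GridSpec, fit_climate_transform, to_env_space,
                       bootstrap_niches, scenario_area_table, area_percentages)
from climniche.synthetic import (generate_current_climate, generate_future_ensemble,
                                 generate_virtual_species, FutureDeltaSpec, TrueNiche)

# 1. simulate a current climate and a warmed 2070/RCP8.5 ensemble
grid = GridSpec(n_rows=40, n_cols=40, cell_area=1.0)
current = generate_current_climate(grid, seed=42)
futures = generate_future_ensemble(
    current, FutureDeltaSpec(periods=(2070,), rcps=(8.5,), n_gcms=3), seed=42)

# 2. PCA environmental space fitted on current climate only
transform = fit_climate_transform(current, k=3)
env_now = to_env_space(current, transform)
print(f"top-3 variance fraction: {transform.cumulative_fraction:.1%}")

# 3. a virtual species centred on the current climate, 150 occurrences
mu = env_now.scores().mean(axis=0)
sigma = np.cov(env_now.scores(), rowvar=False) * 0.25
sp = TrueNiche("sp1", tuple(mu), tuple(map(tuple, sigma)), n_occurrences=150)
occ = generate_virtual_species(env_now, [sp], seed=42)
rows, cols, _ = grid.locate(occ["decimalLongitude"], occ["decimalLatitude"])
points = env_now.data[:, rows, cols].T

# 4. bootstrap Mahalanobis niches and scenario areas
ens = bootstrap_niches(points, B=200, seed=42, species_id="sp1")
env_fut = {k: to_env_space(s, transform) for k, s in futures.items()}
areas, _ = scenario_area_table(ens, env_now, env_fut, seed=42)
areas = area_percentages(areas, study_area=env_now.n_valid * grid.cell_area)
piv = areas.pivot(index="bootstrap_id", columns="scenario", values="pct")
delta = piv["2070_rcp8.5"] - piv["current"]
print(f"current potential-niche area: {piv['current'].median():.1f}% of study area")
print(f"2070 RCP8.5 change: median {delta.median():+.1f} pp "
      f"(2.5-97.5%: {delta.quantile(0.025):+.1f} to {delta.quantile(0.975):+.1f} pp)")
print(f"bootstraps losing area: {(delta < 0).mean():.0%}")
```

Output:

```
top-3 variance fraction: 95.8%
current potential-niche area: 19.0% of study area
2070 RCP8.5 change: median -9.0 pp (2.5-97.5%: -10.9 to -7.2 pp)
bootstraps losing area: 100%
```

Read: the first three PCs capture 95.8% of the synthetic climate's
variance; the species' climate could support it over ~19% of the study
area today; under the warmed 2070 scenario every bootstrap resample agrees
it loses area, with a median loss of 9 percentage points of the study area.

The same analysis is available from the shell via a declarative YAML config:

```bash
climniche run-all --config config.yaml     # or stage by stage:
climniche simulate --config config.yaml
climniche prep-climate --config config.yaml
# ... clean-occ, fit, project, aggregate, report
```

Every run writes its tables (CSV), figures (beanplots + plotted-data CSV),
a log, and a `manifest.json` with the seed and SHA-256 hashes of all
outputs; re-running with the same config and seed reproduces every table
bit-for-bit.

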