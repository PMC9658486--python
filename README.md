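# shrubvol

Volume-based allometric biomass and nutrient-pool models for shrub-like,
multi-stemmed invasive trees, developed around the *Acacia longifolia*
destructive-harvest campaign in SW Portugal (37 single trees; 11 clear-cut
25 m² stand plots surveyed by UAV photogrammetry).

Conventional allometry predicts tree mass from the stem diameter at breast
height, which is useless for shrub-like invaders with dozens of stems.
This package implements the volume-based alternative end to end, for
researchers modelling invasion impact and for managers who need to know how
many tonnes — and of what C/N quality — a clearing action will yield:

* **Geometry** — canopy area as a circle from the mean of the two canopy
  radii, crown volume as the cone `V = A·H/3`; and the remote-sensing
  equivalents from a canopy height model (surface volume, vegetated cover
  above 30 cm, mean canopy height), with plain-text xyz / ESRI-ASCII IO.
* **Allometric model zoo** — three families (`Y = a + Σbᵢxᵢ`,
  `Y = a + Σbᵢ ln xᵢ`, `Y = a + Σbᵢxᵢ^cᵢ`) over all predictor subsets,
  ranked by `BIC = n·ln(RSS/n) + k·ln(n)`; the *best* model is the global
  BIC minimum and the *most parsimonious* model is the BIC minimum at the
  smallest predictor count within ΔBIC ≤ 10 of it. The pooled simplified
  model `BM ~ a + b·Vol` links biomass directly to UAV-derived volume.
* **Segmented regression** — the continuous hinge
  `y = β₀ + β₁x + β₂(x−ψ)₊` fitted by profiling the RSS over ψ, with
  Davies' bound for the significance of a slope change at an unknown
  breakpoint. Used for the decline-then-plateau of the foliage+branch mass
  fraction (FBMF) at ≈ 0.3 of total biomass.
* **Height subsampling** — the Monte-Carlo experiment answering "how many
  manual height measurements per 100 m² still predict biomass": sample *n*
  heights per plot, correlate per-plot mean height with harvested biomass,
  average Pearson's *r* over thousands of repetitions, and locate the
  breakpoint of the r-vs-n curve.
* **Nutrient pools** — C/N/P totals from compartment masses × tissue
  concentrations, C/N ratios (compost vs fuelwood suitability), and the
  partitioning fit `FB ~ a + b·BM^c` against the theoretical c = 0.75.
* **Synthetic campaign generator** — correlated lognormal tree dimensions,
  power-law masses, rasterised cone-crown stand plots and tissue chemistry,
  calibrated to the published campaign envelopes so the whole pipeline is
  testable without the (undeposited) field data.

## Worked example

```python
from shrubvol import (GeneratorConfig, generate_trees, generate_stands,
                      fit_combined_volume_model, fit_segmented, format_equation)

cfg = GeneratorConfig(seed=42, n_trees=300)
trees = generate_trees(cfg)
stands, grids = generate_stands(GeneratorConfig(seed=42))

comb = fit_combined_volume_model(trees, stands)
print(format_equation(comb))         # Y ~ 6.66 + 1.01*V
print(round(comb.rmse, 2))           # 4.03

fbmf = trees.fb_dry / trees.total_dry
seg = fit_segmented(trees.total_dry.to_numpy(), fbmf.to_numpy())
print(round(seg.y_at_breakpoint, 3), f"{seg.davies_p:.2g}")   # 0.296 1.3e-82
```

The first two lines fit and print the pooled volumetric model on a
synthetic campaign: biomass in kg rises by ≈ 1.0 kg per m³ of crown
volume, with a ~4 kg root-mean-square error. The segmented fit finds the
FBMF hinge at a fraction of 0.296 — the level below which extra growth goes
to the trunk, not to foliage and branches — with Davies' test rejecting a
straight line outright.

Applying the published field coefficients to the campaign's whole-plot
validation (31,711 m³ of cut stand, 52,847 kg fresh ≙ 31,869 kg dry):

```bash
$ shrubvol validate
{
  "predicted_kg": 31146.5,
  "measured_dry_kg": 31872.0,
  "deviation_kg": 725.5,
  "deviation_pct": 2.3
}
```

A thin CLI (`shrubvol generate|run|segment|heightcurve|predict|validate`)
wraps the library for shell use; `examples/` holds one short narrative
script per capability.

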