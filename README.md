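# gxesim

**Data-driven simulation of cultivar performance under uncertain weather.**

`gxesim` is for quantitative geneticists and breeders working with
multi-environment trial (MET) networks — yield records indexed by year,
location and cultivar, linked to SNP genotypes and daily weather. It answers
the question MET data alone cannot: *how is this cultivar expected to perform
at this location across the weather conditions that actually occur there?*

The approach:

1. **Learn G×E patterns** with Bayesian reaction-norm models. The full model
   for yield y_ijk is

   y_ijk = μ + Y_i + L_j + YL_ij + V_k + w_ijk + VW_ijk + ε_ijk

   with **V** ~ MVN(0, **G**σ²_V), **G** = XX′/p the genomic relationship
   from standardized SNP dosages; **w** ~ MVN(0, **Ω**σ²_EC),
   **Ω** = WW′/q from standardized environmental covariates (ECs — per-phase
   weather summaries from a wheat phenology model); and
   **VW** ~ MVN(0, (Z_g**G**Z_g′)#**Ω** σ²_V×EC), the Hadamard-product kernel
   that encodes SNP-by-EC interactions. Sub-models (TL, GW, GW-G×W, TGW) drop
   terms. A blocked Gibbs sampler with scaled-inverse-χ² variance updates
   returns the full posterior.

2. **Simulate forward**: for target locations × historical weather years ×
   candidate cultivars, evaluate per posterior sample s

   f(i, j, k, θ_s) = μ(s) + L_j(s) + V_k(s) + w_ijk(s) + VW_ijk(s)

   (year and year-location effects excluded — they are unknowable for future
   seasons; historical weather variation takes their place). Summaries over
   years × samples give per cultivar–location means, medians and quantiles.

3. **Analyze downstream**: leave-trial-out cross-validation with Fisher-z
   paired model comparison, Finlay–Wilkinson mean-stability regression with
   genomic covariance on intercepts and slopes, SREG biplots, clustered
   heatmaps.

Because real MET networks of this kind are proprietary, the package ships a
first-class synthetic-data module that emulates one (un-replicated trials,
partial connectivity via shared cultivars, inbred-line SNPs, generated daily
weather, phenology-derived ECs) with generating variances on the scale of a
real national wheat network.

## Worked example

```python
import pandas as pd
from gxesim import (GeneratorConfig, generate_dataset, SimulationGrid,
                    build_model, default_priors, gibbs_fit,
                    simulate_performance, summarize_simulation)

sd = generate_dataset(GeneratorConfig(years=5, locations=6, cultivars=25,
                                      snps=150, presence_prob=0.35, seed=5))
grid = SimulationGrid(years=sd.dataset.years,
                      locations=sd.dataset.locations[:4],
                      cultivars=sd.dataset.cultivars[:10])
records = pd.concat([sd.dataset.records, grid.grid_records()],
                    ignore_index=True).drop_duplicates(
                    ["year", "location", "cultivar"], keep="first")
design = build_model("TGW-GxW", records, G=sd.G, Om=sd.Om)
ps = gibbs_fit(design, default_priors(design),
               n_iter=2000, burn_in=500, thin=5, seed=5)
sp = simulate_performance(ps, grid)
print(summarize_simulation(sp).head())
```

prints (`examples/05_simulate_performance.py`):

```
simulated 60,000 values (5 years x 4 locations x 10 cultivars x 300 posterior samples)

40 cultivar-location rows; first 5:
cultivar location  mean  median  q25   q75
    C000      L00  9.59    9.56 8.95 10.22
    C001      L00  8.91    8.92 8.36  9.42
    C002      L00  8.94    8.93 8.40  9.48
    C003      L00  8.39    8.37 7.78  8.97
    C004      L00  9.43    9.41 8.89  9.94
```

Each row is one cultivar at one location; `mean` is its expected yield (t/ha)
averaged over historical weather years and posterior parameter draws, and the
quartiles describe the spread attributable to weather and parameter
uncertainty — not residual plot noise, which is never added. The
`examples/` directory has one short narrative script per capability
(synthetic network, phenology/ECs, model fitting, cross-validation,
simulation, stability analysis); a thin CLI (`gxesim all --config cfg.yaml`)
drives the same pipeline from a shell.

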