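# Methods

## The problem and the modeling strategy

Multi-environment wheat trials confound three things a breeder wants to
separate: genetics, environment, and their interaction (G×E). A large share of
the environmental (and interaction) variance sits in year and year–location
effects — weather, essentially — which makes forecasts for future seasons at a
location intrinsically uncertain. `gxesim` implements a data-driven answer:
learn how cultivars react to measurable environmental covariates (ECs) from a
trial network, then Monte-Carlo-simulate each cultivar's yield at target
locations across many historical weather years, propagating full posterior
uncertainty about the model parameters.

The statistical core is a family of Gaussian reaction-norm models for yield
records y_ijk (year i, location j, cultivar k):

- **TL** (baseline): y = μ + Y_i + L_j + YL_ij + V_k + ε, all effects IID
  normal.
- **GW**: y = μ + V_k + w_ijk + ε with V ~ MVN(0, G σ²_V), G = XX′/p from
  centered/scaled SNP dosages, and w ~ MVN(0, Ω σ²_EC), Ω = WW′/q from
  centered/scaled ECs.
- **GW-G×W**: adds VW ~ MVN(0, (Z_g G Z_g′)#Ω σ²_V×EC), the Hadamard
  (cell-by-cell) product kernel that encodes all SNP-by-EC interactions
  implicitly.
- **TGW** and **TGW-G×W**: GW(-G×W) plus the year/location/year-location
  terms, because ECs capture only part of the between-trial variance.

The simulation engine evaluates, for each posterior sample θ_s,

    f(i, j, k, θ_s) = μ(s) + L_j(s) + V_k(s) + w_ijk(s) + VW_ijk(s)

over the grid of target locations × historical weather years × cultivars.
Year and year–location effects are deliberately excluded: they are
unpredictable for future seasons; variability across historical weather years
(through w and VW) takes their place. Averages of f over years and samples are
therefore smoother than raw trial means, which is the point: they estimate the
expected performance at a location under the local weather climate rather than
under the particular seasons a cultivar happened to be tested in.

## Gibbs sampler

Every random term is carried as a factor B with covariance K = BB′: an
incidence matrix for IID terms, Z·U·Λ^{1/2} from the truncated
eigendecomposition (relative cutoff 1e-10) for kernel terms. The effect is
u = Bδ with δ ~ N(0, I σ²_t). At setup, the observed-row block of B gets one
SVD, P S Q′; in the rotated coordinates γ = Q′δ the full conditional is
diagonal, so each term updates as one vectorized block at matrix–vector cost
per iteration. This is numerically identical to the classical eigen-trick for
Gaussian kernel regressions but updates whole blocks rather than scalar
coordinates.

Directions of δ outside the row space of the observed block (e.g. kernel
structure only expressed at prediction rows) carry no likelihood; at each
saved sample they are drawn from their prior N(0, σ²_t) and added after
projection off the identified subspace. This is exactly how prediction works:
**new year–location–cultivar rows are appended to the design with missing
responses**, contribute no likelihood, and their per-sample effect values are
conditional draws given everything observed — kriging, sample by sample. The
simulation grid, leave-trial-out CV and leave-cultivar-out CV all use this one
mechanism.

Variances get scaled-inverse-χ² full conditionals. Convention: a draw is
σ² = (S0 + SS)/χ²_{df0+n}, so S0 is scale×df and the prior mode is
S0/(df0+2). Default priors split var(y) between signal and noise by an R²
parameter (default 0.5): residual S0 = var(y)(1−R²)(df0+2); each of the m
terms gets S0 = var(y)·R²/m·(df0+2)/mean-diag(K), with df0 = 5 throughout.
The intercept has a flat prior and a Gaussian conditional. Chains are
initialized at prior modes with μ = mean(y); default test-scale chains are
6,000 iterations (1,000 burn-in, thin 5); production-scale settings
(100,000 kept iterations thinned by 5 → 20,000 samples) are plain
configuration. Non-finite conditional variances abort with the iteration and
term named.

## Phenology and environmental covariates

The crop model turns daily weather into Zadoks growth-stage dates per
cultivar:

- Thermal time: piece-wise linear in daily mean temperature with cardinal
  temperatures 0/24/35 °C (peak increment 24 °C-days at 24 °C, zero outside);
  base 3.5 °C between GS30 and GS55.
- Emergence (GS10) at 150 unmodified °C-days from sowing; the sowing day
  itself does not accumulate.
- GS10→GS30 accumulation is multiplied by min(PF, VF), where
  PF = clamp((P_H − 6.3)/(20 − 6.3)) from astronomical daylength and
  VF = clamp(VDD/45) from vernalizing days (piece-wise linear in Tmean with
  cardinals −1/6/17 °C). The combination rule is not fixed by convention;
  min() is the common choice in wheat models (the most limiting factor gates
  development) and is what this package uses.
- GS30→GS55 uses PF only, with P_base 7.7 h.
- GS39 is back-calculated as GS55 − 1.2·Phyll in °C-days since sowing; the
  phyllotherm formula is evaluated literally as printed in its source
  (including the +1.0104 inside the inner denominator) and clamped to
  [66, 120] °C-days — realistic autumn sowings (daylength decreasing between
  sowing and emergence) often land on a bound, which the clamp makes benign.
- After GS55 only temperature matters: GS65 = GS55 + 0.05899(1.596·GS55 −
  93.61); GS75/GS92 at +430/+770 °C-days from GS55 (these offsets are
  interpreted as degree-days, consistent with all other stage arithmetic).

ECs are per-phase weather summaries: 13 statistics (mean Tmin/Tmax/Tmean,
°C-day sum, heat-day counts >25/>30 °C, frost-day count, radiation sum and
mean, rain sum, rain-day count, a climatic water balance rain − 0.4·Rg/1000
as a radiation-scaled evapotranspiration proxy, and maximum dry-spell length)
over 8 phases (the 7 stage intervals plus the whole cycle) = 104 columns —
the same structure as operational EC catalogues of ~106 covariates, with the
schema fully configurable (YAML). Columns are centered and scaled; zero-
variance columns (e.g. frost days in summer phases) are dropped with a
warning, so q is typically ~85–100 on synthetic data. ECs default to
trial-level (one row per year–location, computed with reference phenology
parameters); cultivar-specific ECs are possible by supplying per-cultivar
schedules but are not the default.

## Synthetic data: what it emulates and what it does not

Real post-registration trial data of this kind are proprietary, so the
generator is a first-class module. It emulates: un-replicated trials (one
record per year–location–cultivar), a common check in every trial plus a
random subset of the roster (configurable presence probability) giving
partial connectivity; inbred-line SNP genotypes (dosage 2·Bernoulli(freq),
freq ~ U(0.1, 0.9), 3% residual heterozygosity, 2% missing calls — passing
the MAF > 0.05, call-rate > 0.8, het < 10% QC by construction); daily weather
from seasonal sinusoids with AR(1) anomalies and Markov-gamma rainfall at
latitudes 43.5–49.5°; ECs through the phenology model; and phenotypes from
the full TGW-G×W equation. Default generating variances are the full-model
posterior means from the motivating wheat network — Y 0.175, L 0.525,
YL 0.916, V 0.184, EC 0.140, V×EC 0.054, ε 0.170 (t/ha)², around μ = 9.49
t/ha — so synthetic yields live on the real scale. The interaction is drawn
exactly from the Hadamard kernel via its Khatri–Rao factorization
(VW_i = Fg[k_i]′ H Fo[env_i], H ~ N(0, σ²I)), which avoids any n×n
factorization at generation time.

Deliberately not emulated: spatial field trends and blocking, soil and
management covariates, cultivar turnover over years, selection of which
cultivars enter which trials (presence is random), pedigree/LD structure
beyond random allele frequencies, and weather-station idiosyncrasies. Tests
passing on this generator therefore demonstrate internal correctness of the
machinery and recoverability under the model's own assumptions — not
real-data predictive accuracy, whose published values depend on a specific
proprietary network.

One master seed fans out into named child streams (weather, genotypes,
network, effects, folds, chain) so components are independently reproducible.

## Validation machinery

Leave-trial-out CV assigns whole year–locations to k folds (leave-cultivar-out
assigns cultivars); each fold is refitted with the left-out rows as missing
responses and scored by the within-trial Pearson correlation between
posterior-mean predictions and observations. Trials with fewer than 3 test
records are dropped (a correlation on 2 points is meaningless; the Fisher
transform z = (√(n−3)/2)·log((1+r)/(1−r)) gives n = 3 zero weight anyway).
Models are compared with paired t-tests on z over the common trials and
summarized by a compact letter display (models sharing a letter differ with
p > α; α defaults to 0.05). EC predictiveness is validated by regressing
two-way (trial + cultivar) BLUEs of trial means on Ω with kernel ridge
(default ridge 0.5) over repeated 80/20 trial holdouts.

## Downstream analytics

Finlay–Wilkinson runs in two steps, both on the same Gibbs machinery:
(1) a random-effects additive fit estimates environment means Ẽ_j;
(2) M_jk − Ẽ_j = μ + b0_k + Ẽ_j·b1_k + δ with genomic covariance G on both
coefficient vectors (identity if no G is supplied). b1_k is the deviation
from the common regression, so the total FW slope is 1 + b1_k; both are
reported, with posterior SDs. Cultivar-level coefficient draws are exposed by
appending one missing-response pseudo-row per cultivar whose design row has a
unit environment covariate — the same augmentation trick the sampler already
uses for prediction. Slope-stability CV splits each cultivar's cells into two
folds (both ≥ 2 cells, bounded resplits), refits FW per fold, and correlates
fold slopes; inputs (raw/BLUE/simulated means) are compared by paired t-tests
with Holm adjustment. SREG is the SVD of the location-centered means matrix
(variance fractions λ²/Σλ²); clustering is average-linkage on Euclidean
distances, for heatmap margin ordering.

## Numerical choices and problem sizes

- Eigenvalue truncation at 1e-10 relative; SVD truncation of observed blocks
  at 1e-12 relative. Kernel asymmetry beyond 1e-8 relative is an error.
- SNP and EC columns are scaled by the sample standard deviation (ddof = 1);
  with that convention mean diag(G) = (n−1)/n exactly.
- The recovery experiment in the test/acceptance suites uses the generator
  defaults (10 years × 30 locations, 100 cultivars, 1,000 SNPs, ~2,900
  records) with one 6,000-iteration chain — large enough that σ²_ε and σ²_YL
  are well identified, small enough to fit in a desk-scale run.
- The model-ranking experiment uses 12 years × 12 locations with 150
  sparsely-tested cultivars (presence 0.045, ~1,100 records, ~6 per
  cultivar) and 3-fold leave-trial-out CV: sparse testing is what gives the
  genomic kernel its pooling advantage over the IID cultivar baseline, and
  144 trials with shared regional/interannual weather structure give the
  interaction kernel enough correlated environmental signal to transfer to
  left-out trials. Denser, smaller, or spatially unstructured networks blur
  both contrasts.
- The production-scale simulation grid (16 locations × 16 years × 28 cultivars ×
  20,000 samples ≈ 143.4 M values) is validated by the engine's exact count
  accounting plus a complete streamed evaluation at a reduced scale; the full
  array is never materialized (evaluation streams over sample chunks).

## Known limitations

- Trial-level Ω means w_ijk cannot contribute to within-trial rankings; only
  V and VW can. This matches the model's own structure but means the EC term
  is validated through between-trial prediction.
- Year and location effects for locations absent from the training network
  are unidentified; the simulation grid must use training locations (the
  platform interpolates, it does not extrapolate).
- The L vs w decomposition is only weakly identified when locations are few:
  both are location-structured. σ²_L and σ²_EC posteriors are correspondingly
  wide at desk scale.
- FW slopes for cultivars observed in a single location are flagged
  unidentifiable rather than dropped.
- The weather generator has no trends, no extremes beyond AR(1)+gamma tails,
  and a fixed diurnal range; it is a study-condition generator, not a
  climate model.
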