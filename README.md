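# lyschase

Bayesian protein-turnover analysis for in vivo dynamic SILAC pulse–chase
experiments, with correction for free heavy-lysine recycling, organ growth
dilution and protein abundance change.

## The problem

In a mouse pulse–chase experiment, animals are fully labelled with
¹³C₆-lysine in utero (pulse) and switched to light chow at birth or at
weaning (chase). For every protein, MS1 quantification yields heavy (H,
¹³C₆-Lys) and light (L, ¹²C₆-Lys) intensities across ages, and the decay
of the heavy signal reports protein turnover. Three confounders stand
between the raw ratios and a degradation rate:

* **recycling** — free ¹³C₆-lysine liberated by degradation is
  re-incorporated into new protein, so the heavy signal decays slower than
  degradation alone (an apparent synthesis rate *k*on driven by the free
  heavy-lysine pool *p(t)*);
* **growth** — a juvenile organ such as the ovary grows enormously during
  the chase, diluting the heavy *fraction* without destroying heavy
  protein;
* **abundance change** — individual protein concentrations drift with age
  (measured by DIA-MS).

`lyschase` implements the full chain from quantification tables to
half-life estimates, longevity clusters, aging abundance clusters and
pathway over-representation, for researchers analysing tissue pulse–chase
SILAC time courses.

## Model

For protein *i* with degradation rate *k*, total amount
*P(t) = V(t)·c(t)* (organ volume × relative concentration, both
log-linearly interpolated between measurements), the heavy fraction
*F = H/(H+L)* obeys

    dF/dt = (g(t) + k) · (p(t) − F),        g = d log P / dt,

where the free-pool heavy fraction *p(t) = p₀·exp(−λ·(t − t₀))* is
estimated from missed-cleavage 2-lysine peptides: newly made 2Lys peptides
are HH/HL/LL in binomial proportions (p², 2p(1−p), (1−p)²), inverted as
p̂ = 2·HH/(2·HH + HL). The synthesis flux implied by growth is clamped at
zero when the total amount shrinks faster than degradation. Because *g* is
piecewise constant and *p* piecewise exponential, trajectories are exact
closed forms per segment — no numerical ODE solver.

The fitted observable is R = ln(L/H + 1) = −ln F per timepoint and
biological replicate, with Gaussian error whose scale follows the
first-order propagation of multiplicative intensity noise
(s.d. ∝ 1 − F). Per protein, an adaptive random-walk Metropolis sampler
(4 chains) draws from the posterior of (log₁₀k, F₀ at weaning, noise
scale) plus free-pool and growth nuisance parameters with priors at their
regression estimates; heavy-undetected timepoints enter as one-sided
censored observations. The half-life H₁/₂ = ln2/k (censored above
10 000 d) is the decay clock of the molecules present at chase start:
growth cancels from the labelled amount and recycling only creates new
molecules, but both must be modelled to estimate *k* — ignoring recycling
biases *k* down and H₁/₂ up.

Downstream: Ward-linkage clustering of modelled %¹³C₆-Lys retention
(3 longevity groups) and of z-scored aging DIA profiles (6 trend groups),
and hypergeometric over-representation analysis with Benjamini–Hochberg
adjustment. Spearman comparisons of half-life sets use AS 89 p-values
(exact for n ≤ 9, Edgeworth above).

## Worked example

Simulate a 40-protein cohort under the study design (11 chase-from-birth
timepoints from 24 h to 65 weeks, 6 chase-from-weaning timepoints, 3
biological replicates, 98.7% initial labelling, 10% CV intensity noise)
and fit it:

```python
import numpy as np
from lyschase.synthetic import CohortConfig, generate_cohort
from lyschase.preprocess import aggregate_technical
from lyschase.pipeline import fit_pools
from lyschase.growth import fit_growth_curve
from lyschase.inference import FitConfig, fit_cohort, fits_to_frame

cfg = CohortConfig(n_proteins=40)
sim = generate_cohort(cfg, seed=1)
agg = aggregate_technical(sim.quant, n_tech=1)
pools = fit_pools(sim.two_lys)                       # free-lysine pool from 2Lys peptides
growth = fit_growth_curve(sim.volume, sim.abundance) # organ growth + abundance drift
fits = fit_cohort(agg, pools, growth,
                  FitConfig(detection_limit=cfg.detection_limit), seed=1)
table = fits_to_frame(fits).set_index("protein_id")
pool = pools["chase_from_birth"]
print(f"free pool: p0 = {pool.p0:.3f}, decay = {pool.lambda_free:.3f}/day")
print(table[["k_median", "halflife_median", "halflife_q5",
             "halflife_q95", "censored"]].head(6).round(3))
truth = sim.truth.set_index("protein_id")
err = (table.k_median - truth.true_k).abs() / truth.true_k
print(f"median |k error|: {100 * err.median():.1f}%")
```

prints

```
free pool: p0 = 1.000, decay = 0.154/day
            k_median  halflife_median  halflife_q5  halflife_q95  censored
protein_id
P0001          0.094            7.341        6.913         7.887     False
P0002          0.074            9.395        9.018         9.775     False
P0003          0.070            9.899        9.214        10.550     False
P0004          0.246            2.814        2.343         3.477     False
P0005          0.051           13.533       12.068        15.317     False
P0006          0.264            2.625        2.357         2.944     False
median |k error|: 6.0%
```

The recovered pool decay (0.154/day vs. 0.15 simulated) and the 6% median
rate error are estimated against the generator's ground truth.
`halflife_median/q5/q95` are posterior quantiles in days; `censored`
marks proteins whose label never measurably leaves (reported as
">10000 d" in the atlas).

The same pipeline is available from the shell:

```sh
lyschase simulate -o sim --seed 1
lyschase fit -i sim -o out --seed 1            # fits.tsv, clusters.tsv, atlas.tsv
lyschase cluster -i out -o clusters.tsv --scheme longevity
lyschase enrich --hits hits.txt --universe universe.txt --gmt sets.gmt -o ora.tsv
```

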