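# Methods

## Observable and replicate rules

The quantity fitted per protein, age and biological replicate is
R = ln(L/H + 1) = −ln F, where H and L are MS1 intensities of the
heavy- and light-lysine forms and F = H/(H+L) is the heavy fraction.
Channel medians are taken over technical replicates only when the channel
was detected (present and > 0) in at least two of them (pass-through for
a single technical replicate); a zero intensity is a measurement, not a
detection. A protein is *heavy only* when heavy passes that rule in at
least one biological replicate while light shows no signal in any
technical replicate of any biological replicate (*light only* symmetric);
*both* when each channel passes somewhere; otherwise *undetected*. The
mean and s.d. (ddof = 1) of F are reported whenever at least one
biological replicate has an F; heavy-passing replicates with no light
signal contribute F = 1.

Timepoints where heavy fell below detection while light persisted are not
dropped: with a known detection limit *d* they enter the likelihood as
one-sided observations R ≥ ln(L/d + 1). Dropping them would
preferentially remove fast-turnover evidence and bias half-lives up.
Conversely, points where light is undetected while heavy passes are
scored as F = 1 (policy `light_missing="zero"`, switchable to `"drop"`):
the absolute R error this introduces is bounded by ln(d/H + 1), small
whenever heavy is well above the limit.

Proteins whose heavy channel never passes detection at any chase
timepoint ≥ 42 days in *any* pulse design while light persists degrade
too fast to model; they are flagged and excluded from inference. Both the
cutoff age and the all-designs conjunction are arguments, because the
underlying exclusion is operational rather than mechanistic.

## Free-lysine pool

Missed-cleavage peptides carrying two lysines are HH, HL or LL. Newly
synthesized 2Lys peptides draw both lysines from the free pool with heavy
fraction p, giving binomial proportions (p², 2p(1−p), (1−p)²). The
estimator p̂ = 2·HH/(2·HH + HL) uses only the heavy-containing species:
pre-pulse protein contributes almost exclusively LL, which would otherwise
mix old protein into the pool estimate, while pure-HH peptides essentially
cannot arise except from a charged heavy pool. p̂ inverts the proportions
exactly, and under multinomial sampling of 10⁴ peptides its error stays
within 0.02 over p ∈ [0.1, 0.95].

The pool is modelled as a single exponential after the chase starts,
p(t) = p₀·exp(−λ·(t − t₀)), and as the labelling plateau (0.987, the
measured parental labelling of the fully labelled line) before it. A
single exponential is the simplest monotone family compatible with a pool
that is strongly depleted by 3–6 weeks; a bi-exponential could be added
behind the same interface if residuals demanded it. Both pulse designs
share one (p₀, λ): the pool kinetics are a property of the animal's
lysine metabolism, not of when the diet switched, so the regression pools
records from both designs on time-since-own-chase-start. This matters in
practice because the weaning arm starts sampling after the pool has
largely emptied and rarely supports a fit alone. The OLS standard errors
and slope–intercept correlation of the regression are retained on the
model object and consumed by the inference stage (below).

## Growth and abundance

Total protein amount is P_i(t) = V(t)·c_i(t). Organ volumes (v = lwh for
whole ovaries, v = 4/3·π·r³ for oocytes) are averaged in log space per
age and interpolated log-linearly, which guarantees positivity and a
piecewise-constant growth rate g(t) = d log P/dt that the turnover
equation integrates exactly. Per-protein DIA concentrations are treated
the same way on their own age grid; a protein missing an age borrows the
nearest observed one (recorded on the model). Outside the measured range
V and c are held constant (g = 0) — growth has plateaued at late ages —
with an opt-in strict policy that raises instead. The replicate scatter
of the first and last log-volume knots defines a standard error for the
total log growth amplitude, also consumed by inference.

## Turnover model

From amount dynamics dH/dt = s(t)·p(t) − k·H with synthesis flux
s = P′ + kP (the flux required to realize the measured P under
degradation k), the heavy fraction obeys

    dF/dt = (g + k)(p − F).

The term s·p is the recycling inflow: the more heavy lysine remains free,
the more heavy protein is still being made during the chase. When P
shrinks faster than degradation alone would allow (g + k < 0) the implied
flux would be negative; it is clamped at zero, giving dF/dt = −(k + g)F.
Segments between growth knots have constant g and exponential p, so the
trajectory is advanced by exact per-segment formulas; the three analytic
limits (pure decay exp(−kt); growth-only dilution V₀/V(t); fixed point
F → p₀ for a constant pool) hold to machine precision.

**Half-life.** H₁/₂ is the decay clock of the molecules present at chase
start: growth dilutes the heavy *fraction* but destroys no heavy protein
(it cancels from the labelled amount), and recycling creates only new
molecules. Hence H₁/₂ = ln2/k, censored at 10 000 days, and the recycling
and growth corrections act through the *estimation* of k. The alternatives
were considered and rejected: a fraction-halving time is dominated by
dilution in a rapidly growing organ (every protein would halve within
days regardless of k, and half-lives would not be comparable across
tissues), while an amount-halving time that includes recycling inflow
inherits the early heavy-synthesis burst of a charged pool and inverts
the sign of the no-recycling bias, breaking the very comparison the
variants exist for. For the same reason the %¹³C₆-Lys retention matrix
used for longevity clustering is the labelled-cohort survival
100·exp(−k̂t).

**Variants.** `no_recycling` forces p ≡ 0 (the k_on = 0 model);
`late_only_3w`/`late_only_6w` additionally restrict to chase ages ≥ 21 or
42 days, where the pool is depleted and growth has slowed;
`peptide_2lys` fits the decay of pure-HH 2Lys peptide intensities of
abundant proteins by log-linear least squares with the known dilution
added back — HH peptides are essentially never re-made during the chase,
so the pool drops out.

## Inference

Per protein: likelihood R_obs ~ Normal(R_model, σ·w) with
w = (1 − F_model) + 0.05, the first-order propagation of multiplicative
intensity noise to the log-ratio scale (an early point with F ≈ 0.99
carries far less R noise than a late point with F ≈ 0.05; the floor keeps
the likelihood proper as F → 1). Priors: log₁₀k uniform on [−4, 1]; the
chase-start heavy fraction fixed to the labelling plateau for the
chase-from-birth design and uniform on [0.5, 1] for chase-from-weaning
(its pulse phase is not modelled); log σ uniform on [ln 10⁻³, ln 3].
Biological replicates are independent observations — three replicates
cannot support a replicate hierarchy.

The fitted pool (λ, log p₀) and the growth amplitude are estimates, and
treating them as exact makes every protein's interval share one coherent
input error. They are therefore sampled per protein as nuisance
parameters with Gaussian priors at the regression estimates (bivariate
with the fitted slope–intercept correlation for the pool; a single
amplitude-scaling factor for growth). On synthetic recovery cohorts this
moves central 90% interval coverage from ~0.4–0.6 to ~0.85. The nuisances
are active for the full model only: a reduced variant given a growth
nuisance re-attributes the recycling signal it cannot model to "less
growth" (the saturating growth shape mimics the recycling offset), which
would destroy the interpretability of the variant comparison. Variants
are fit with inputs fixed so their biases are attributable to the dropped
mechanism.

Sampling is adaptive random-walk Metropolis: 4 chains, 400 warmup
iterations with a Robbins–Monro global proposal scale targeting 30%
acceptance (frozen afterwards, so the kept chain is a fixed-kernel MCMC),
500 kept draws per chain, proposals reflected at the prior bounds, chains
initialized from a 61-point profile scan over log₁₀k. All chains of all
proteins advance in one vectorized pass, so a 200-protein cohort fits in
a few seconds on one core and summaries are bit-reproducible from the
seed. Effective sample size (Geyer initial positive sequence, summed over
chains) below 50 flags `low_ess`. H₁/₂ quantiles are the mapped reversed
k quantiles (H₁/₂ is monotone decreasing in k). A posterior whose 5%
quantile sits on the lower prior bound means the data never saw the label
leave; such fits are reported censored at the cap, keeping only the lower
H₁/₂ bound. Both parameter intervals (reported) and the posterior
predictive (available from the kept samples) are defined; the tabulated
Q5/Q95 are parameter quantiles.

## Clustering and enrichment

Both schemes use agglomerative clustering with Ward linkage on Euclidean
distances — the minimize-within-variance criterion — and a fixed-count
cut: k = 3 for longevity (on modelled retention at ages ≥ 6 weeks,
labels high/intermediate/low by descending cluster mean) and k = 6 for
aging abundance (on per-protein z-scored, replicate-averaged DIA profiles
at 9/12/50 weeks; population s.d.; constant rows dropped with a warning;
numeric labels ordered by the late-timepoint mean). A fixed-k cut was
chosen over a height cut because the group counts are part of the
analysis design; both are parameters. Ties in degenerate inputs
(all-identical rows) break by first protein index.

Over-representation uses the upper hypergeometric tail
P(X ≥ x | N, m, n) with the universe defined as the proteins quantified
in the relevant experiment — the standard ORA choice; a whole-genome
universe would overstate enrichment of anything detectable by MS. Gene
symbols match case-insensitively. "Percent of set detected" is the
hit-list overlap over the set's universe members. Adjustment is
Benjamini–Hochberg. Spearman comparisons report AS 89 p-values: exact
enumeration of the S = Σd² null for n ≤ 9, the Edgeworth series above
(validated to machine precision against R's `cor.test`), two-sided as
2·min(tails); ties fall back to the t approximation and are flagged.

## Synthetic cohorts

The generator reproduces the deposited study design: chase-from-birth
sampling at 1, 2, 7, 14, 21, 42, 63, 84, 210, 350 and 455 days;
chase-from-weaning at 42–455 days; three biological replicates (optional
technical quadruplicates); initial labelling 0.987. Degradation rates
come from a three-component log-uniform mixture with weights
0.13/0.27/0.60 (slow/medium/fast, following the observed longevity
cluster proportions) over ranges 7·10⁻⁴–3·10⁻³, 0.03–0.09 and
0.07–0.35 /day, i.e. half-lives of hundreds of days, ~1–3 weeks and ~2–10
days; explicit rate vectors override the mixture for recovery studies.
The free pool decays at λ = 0.15/day (a ~4.6-day pool half-life — charged
in the first week, gone by 3–6 weeks). Organ volume follows a Hill-type
rise 0.1 → 20 mm³ (t₅₀ = 70 d, coefficient 2), a ~200-fold increase that
plateaus at late ages; volume tables carry 5% CV replicate noise.
Intensities are F·scale and (1−F)·scale with per-protein scales
lognormal around 10⁶ (0.5 dex s.d.), i.i.d. lognormal noise at 10% CV per
channel and replicate, and a hard detection limit of 10⁴ producing
intensity-dependent missingness. 2Lys species follow the binomial
proportions at p(t) on a 10⁸ summed scale with the same noise and limit.

What the generator does **not** emulate: peptide-to-protein roll-up and
shared peptides, correlated (batch or run-level) noise, ratio compression,
per-protein pool differences, cell-type heterogeneity (rates are
organ-level averages, as in the underlying experiment), or abundance
trends during the turnover window (concentrations are constant by
default). Passing recovery tests therefore demonstrates the correctness
and calibration of the estimator under the stated noise and missingness
mechanisms, not robustness to every artefact of real MS data.

The aging-abundance generator plants six trend archetypes (up, down,
late-drop, late-rise, mid-peak, mid-dip) at 9/12/50 weeks. A strictly
flat archetype is not plantable: the pipeline's own per-protein z-scoring
annihilates constant profiles, turning them into pure noise directions,
so no clustering method could recover them — all six planted trends are
non-degenerate by design. The longevity-profile generator plants
~90%/~40%/~5% retention trajectories with 3-percentage-point Gaussian
noise.

## Problem sizes and numerical choices

The recovery study uses 200 proteins with log-spaced rates in
[0.002, 0.7]/day — spanning censored-adjacent to rapid-degrader-adjacent
— and the full two-design replicate structure; it runs in seconds, so the
same conditions are used in the test suite and the acceptance script.
End-to-end determinism is checked on a 30-protein cohort with a shortened
chain (200 warmup/250 kept), which exercises every pipeline stage.
Trajectory arithmetic is exact per segment; the only tolerances in the
core are the 10⁻¹⁰ guard for the a ≈ λ degenerate segment formula and
the F ∈ [0, 1] clamp. Atlas files round-trip bit-exactly (censored
half-lives as a ">cap" sentinel); reruns with the same seed are
byte-identical because every stage draws from one seed-split generator.

## Limitations

Rates are organ-level averages over cell types. The weaning design's
pulse phase is summarized by a free F₀ rather than modelled. The
censored-observation bound requires a known detection limit; without one,
censored points are dropped and very fast degraders lose information.
Pool and growth nuisance marginalization covers amplitude-level input
error but not shape error in the growth curve between knots. BH
adjustment assumes the usual PRDS conditions across gene sets.
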