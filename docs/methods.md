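# Methods

This note documents the models, estimators and numerical choices behind
`triqtl`, and what the simulation study does and does not demonstrate.

## Data model

A biparental doubled-haploid (DH) population is fully homozygous: each line
carries one of the two parental alleles at every locus, coded −1/+1. The
simulator produces gametes by a Markov crossover process along the ordered
markers of each chromosome, with switch probability between adjacent markers
given by the Haldane map function `r(d) = (1 − e^(−2d/100))/2` (map distance
`d` in cM, no crossover interference); chromosomes segregate independently
and doubling fixes the gamete, so the line genotype equals the gamete
haplotype. Haldane is the minimal standard choice when only map geometry is
specified; with interference the short-range correlation between markers
would be slightly higher, which mildly affects how often adjacent markers
are interchangeable proxies, but none of the estimator definitions.

Line means follow

```
y_i = μ + Σ_l β_l x_il + Σ_(a,b) γ_ab x_ia x_ib + Σ_(a,b,c) δ_abc x_ia x_ib x_ic + e_i
```

with ±1 genotype codes `x`. The default architecture is fixed: intercept
μ = 100 trait units; 14 QTLs (Q1 on chromosome 1; Q2–Q3 on 3; Q4–Q5 on 5;
Q6–Q8 on 7; Q9–Q11 on 9; Q12–Q14 on 10), each with additive effect β = 2;
five epistatic pairs {Q1–Q2, Q4–Q5, Q6–Q7, Q8–Q11, Q1–Q14} with common
effect γ ∈ {2, 0}; and a triple layout from the catalog C01–C12 whose aaa
effects δ always sum to 15 (equal split, or one dominant triple: 10/5,
9/3/3, 7/2/2/2/2). Each QTL coincides exactly with the marker at its
position (perfect marking), so QTLs are addressed as marker columns.

Two conventions are deliberate and documented rather than "corrected":

- **Within-chromosome QTL positions** are free parameters of the design;
  the package fixes defaults (Q1 at 50 cM; pairs at 33/66 cM; triples at
  25/50/75 cM) so that linked and unlinked layouts are clearly distinct.
  They are constructor arguments for sensitivity analyses.
- **Error placement.** The error variance σ² ∈ {5, 10} is defined at the
  line-mean level: each of the 10 plants per line gets noise of variance
  10·σ², so the line mean has variance σ² and the per-line sample variance
  of plants (an estimate of 10·σ²) supplies the weights `w_ii` for weighted
  regression. A `plant` error level is available as an option. Since all
  lines share the same σ², the weights differ only through sampling noise —
  precisely the regime in which the weighted and unweighted estimators are
  being compared.
- **Population mean vs intercept.** μ = 100 is the model intercept. With
  epistasis present, linked pairs have E[x_a x_b] = 1 − 2r > 0, so the
  population mean exceeds 100; with epistasis absent, every genetic term is
  odd under the global sign-flip symmetry of DH genotypes and the expected
  line mean is exactly 100. The latter is one of the acceptance checks.

## Estimators

**Phenotypic (extreme lines).** `aaa_p = (L_max + L_min)/2 − L̄` (default,
location-invariant "centered" form; the alternative parenthesization
`(L_max + L_min − L̄)/2` is available as `form="literal"`). The effective
factor count is `K̂ = (L_max − L_min)²/(4·V_L)` with `V_L` the sample
variance of line means (divisor n−1). Under the ±1 product coding used by
this generator, the triple products of the extreme lines do not line up with
their additive contributions, so `aaa_p` is *not* centered on the generating
total of 15 (it typically reads 2–8 under the default conditions): the
centered form responds to even-order interaction structure at the extremes.
The estimator is implemented exactly as defined; its behaviour under this
generator is reported by the Monte Carlo harness rather than assumed.

**Genotypic.** `G = [1 | A | E | T]` as in the README; fitting is by QR
decomposition, algebraically equal to `(G'G)⁻¹G'y` (OLS) and
`(G'W⁻¹G)⁻¹G'W⁻¹y` (WLS, implemented by rescaling rows with `1/√w_ii`).
`aaa_g` is the sum of the fitted triple coefficients; R² is `1 − SSE/SST`
about the (weighted) mean, clipped to [0, 1].

## Marker selection

Selection is a staged stepwise search by the Gaussian AIC
(`n·log(SSE/n) + 2k`, `k` = number of columns), with forward steps taken
while the AIC improves and backward elimination evaluated whenever no
addition improves it (dropping column j raises the SSE by
`β̂_j²/[(X'X)⁻¹]_jj`, so drops are evaluated in closed form):

1. **Stage A** — additive terms within each chromosome, with *backfitting*:
   chromosomes are re-scanned (up to three cycles) conditioning on the
   current selections of the other chromosomes, so a scan is not drowned by
   genetic variance segregating elsewhere.
2. **Stage B** — survivors pooled, re-selected, then screened at an
   unadjusted 5% t-test. The AIC alone admits any marker worth ~2 deviance
   units; with hundreds of correlated candidates this leaves a tail of weak
   proxies that would make the interaction pools (all pairs/triples of
   selected markers) intractably large and noisy.
3. **Stage C** — all pair products of the selected markers, stepwise, then
   immediately Bonferroni-screened (α/m, m = pool size): spurious pair
   products would otherwise soak up genuine three-way signal before stage D.
4. **Stage D** — all triple products of the selected markers, stepwise.
5. **Refinement sweep.** Unmodelled triple variance biases stage A: a
   marker `m` on the triple's chromosome has
   `E[x_m · x_a x_b x_c] = (1−2r)(1−2r') ≠ 0` (a four-point linkage
   moment), which drags selected markers away from the QTL positions and
   can exclude the loci needed to form the true triple product. After a
   first full pass, triples surviving a Bonferroni screen are locked into
   the base model and the additive and pair stages are re-run once; the
   loci of locked triples are kept in the additive set (marginality), and
   the triple stage is then rebuilt from the refined markers.
6. **Final screen.** On the joint model, each term class is
   Bonferroni-screened at α = 0.05 over the size of the pool it was scanned
   from (additive: all q markers; pairs/triples: their candidate counts),
   iteratively dropping the weakest term and refitting. Additive terms that
   participate in a retained interaction are exempt (dropping them would
   silently delete an interaction that passed its own screen); dropping an
   additive term cascades to interactions referencing it.

Weighting variants: `gu` runs every stage by OLS; `gw1` ("weighted triple
interaction effects only") reuses the OLS additive/pair selection and runs
the triple stage and the final joint fit by WLS; `gw2` runs every stage by
WLS. An empty selection is a valid outcome and yields a zero genotypic
estimate (flagged) in the harness.

Numerical guards: candidate columns whose residual against the current
model falls below 10⁻⁸ of their norm are skipped; rank-deficient final
designs drop exactly the dependent columns identified by a pivoted QR
(highest-order terms first); weights are floored at
`max(10⁻⁶·median(w), 10⁻¹²)` so nearly-identical plants cannot blow up a
line's weight (and noise-free data degrade gracefully to OLS); the SSE is
floored at 10⁻¹² inside the AIC logarithm so exact fits terminate cleanly;
a per-stage addition cap (default 30) guards against runaway AIC selection
on large pools.

These selection details — screen placement, backfitting, the refinement
sweep, the cap — are design choices in territory a two-stage "group then
pool" stepwise-AIC description leaves open (stepwise direction, Bonferroni
target and stage structure). They were
settled by inspecting selection behaviour on pilot replicates: the
alternatives (Bonferroni directly after the additive stage; no refinement
sweep) measurably discard true QTLs whose t-statistics are deflated by
then-unmodelled interaction variance, or mislocalize the markers from which
interaction products are built.

## Monte Carlo harness

The 84 conditions are the full factorial {C01..C12} × σ² {5, 10} ×
epistasis {present, absent} × effect mode {equal, different}, with the
different mode undefined for single-triple layouts. Replicate streams are
seeded per (base seed, condition key, replicate), so any subset of
conditions or replicates reproduces exactly the numbers of a full run and
conditions can be distributed across processes.

Per condition the harness reports the mean of each estimator, its **mean
squared error defined as dispersion about the Monte Carlo mean**
(`Σ(est_j − est̄)²/R`), and mean R² per genotypic method. The
deviation-from-truth definition is available (`mse_mode="truth"`); the
dispersion form is the default: it measures the estimator's Monte Carlo
precision on a scale that does not conflate bias with variance. The qualitative ordering
`aaa_p ≥ aaa_gw1 ≥ aaa_gw2 ≥ aaa_gu` is computed as a diagnostic fraction
over conditions, not asserted, since exceptions are expected.

Default desk-scale study size is 200 replicates per condition (the
configuration accepts any count; estimator means stabilize to within a few
hundredths of a trait unit by 200, while full-precision table
reproduction would need orders of magnitude more). The acceptance script
uses 30 replicates per condition on a six-condition grid for the variance-
explained summary and 200 replicate populations for the trait-centering
check, sizes at which the Monte Carlo standard errors are comfortably
inside the tolerances being checked.

## What the simulations do and do not show

The generator reproduces the study's design constants exactly (map
geometry, QTL architecture, effect totals, error variances, grid
combinatorics) and its estimator pipeline end-to-end. It does **not**
emulate features of real DH data — missing or erroneous genotypes,
segregation distortion, heteroscedastic line variances with structure,
QTL-by-environment interaction, markers not coincident with QTLs — so
passing tests certify the estimators' behaviour under the stated model, not
their robustness in field data. A further caveat: under the literal ±1 product
coding of the model equation the extreme-line estimator is not centered on
the generating total (see above); comparisons between the phenotypic and
genotypic routes therefore describe this generator, and the package anchors
its checks on oracle identities, invariants and bounded stochastic
properties rather than on any particular historical figures.

## Known limitations

- Stepwise selection is greedy; with 1 cM marker spacing, adjacent markers
  are near-interchangeable and the selected marker for a QTL is frequently
  a 1–3 cM neighbour. Totals of triple coefficients are then mildly
  attenuated (products of three proxy columns), which is visible as
  downward drift of `aaa_gu` for within-chromosome triple layouts.
- Interaction pools grow as C(p, 3); pools beyond 10⁴ candidates are
  truncated with a logged warning.
- No interval mapping, dominance (meaningless for DH), mixed models,
  permutation thresholds, or association-mapping extensions.
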