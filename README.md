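# triqtl

Estimation of **additive × additive × additive (aaa)** — three-way
QTL × QTL × QTL — interaction effects in biparental doubled-haploid (DH)
mapping populations, together with a simulator and a Monte Carlo harness for
comparing estimators.

Breeding programs care about more than single-locus additive effects:
epistatic (QTL × QTL) and higher-order (QTL × QTL × QTL) interactions shape
which crosses produce transgressive homozygous lines. `triqtl` is aimed at
quantitative geneticists who want to (a) estimate the **total aaa effect** of
a trait from DH line data, phenotypically or from marker regression, and
(b) study the behaviour of those estimators under controlled simulation.

## The model

For `n` DH lines with line-mean phenotypes `y` and marker genotypes coded
−1/+1, the trait model is

```
y = 1·μ + A·β + E·γ + T·δ + e,        G = [1 | A | E | T]
```

where `A` holds the genotype codes of the selected markers, columns of `E`
are products of two columns of `A` (additive×additive epistasis, γ) and
columns of `T` are products of three columns of `A` (aaa interaction, δ).
Four estimators of the total aaa effect are provided:

- **aaa_p** (phenotypic, extreme lines): `(L_max + L_min)/2 − L̄`, with
  `L_max`, `L_min` the best/worst line means and `L̄` the overall mean; plus
  the effective-factor count `K̂ = (L_max − L_min)² / (4 V_L)`.
- **aaa_gu** (genotypic, unweighted): staged stepwise AIC marker selection
  (per-chromosome, pooled, then pair and triple products restricted to the
  selected markers) with Bonferroni-corrected t-test screening, fitted by
  OLS `α̂ = (G'G)⁻¹G'y`; aaa_gu = Σ δ̂.
- **aaa_gw1** (weighted, variant i): same selection for additive and pair
  terms; the triple stage and the final joint fit use weighted least squares
  `α̂ = (G'W⁻¹G)⁻¹G'W⁻¹y` with `W = diag(w_ii)`, `w_ii` the empirical
  variance of the i-th line's plants.
- **aaa_gw2** (weighted, variant ii): every stage weighted.

The simulator generates DH genotypes by Haldane-model meiosis
(`r = (1 − e^(−2d/100))/2`, no interference) on 10 chromosomes of 100 cM with
1000 markers at 1 cM, and phenotypes from a fixed architecture: 14 QTLs of
additive effect 2, five epistatic pairs (effect 2 or 0), and 1–5 QTL triples
whose aaa effects always total 15, around an intercept of 100, for 500 lines
× 10 plants. Twelve cataloged triple layouts (C01–C12) × error variance
{5, 10} × epistasis {present, absent} × triple effects {equal, different}
give an 84-condition study grid.

## Worked example

```python
import numpy as np
from triqtl import genome, popsim, phenoest, regest

gmap = genome.default_map()
arch = genome.build_architecture("C01", epistasis_on=True, error_variance=5.0, gmap=gmap)
pop = popsim.simulate_population(gmap, arch, n_lines=500, n_plants=10,
                                 rng=np.random.default_rng(2))

print("aaa_p :", round(phenoest.aaa_phenotypic(pop.line_means), 2))
fits = regest.estimate_all(pop, gmap=gmap)
for name in ("gu", "gw1", "gw2"):
    fit = fits[name]
    print(f"aaa_{name}: {regest.total_aaa(fit):.2f}  (R^2 = {fit.r_squared:.3f})")
```

prints

```
aaa_p : 1.5
aaa_gu: 15.16  (R^2 = 0.983)
aaa_gw1: 15.04  (R^2 = 0.982)
aaa_gw2: 15.16  (R^2 = 0.975)
```

The condition C01 hides a single triple of total effect 15 on one
chromosome: the genotypic estimators recover it closely from the markers and
the fitted model explains ~97% of the line-mean variance. The phenotypic
estimate reads the interaction signal off the two extreme lines only; under
this generator's ±1 product coding it is not centered on the generating
total (see `docs/methods.md`).

The same pipeline runs from the shell:

```
triqtl simulate --variant C01 --seed 7 --out sim/
triqtl estimate --genotypes sim/genotypes.csv --map sim/map.tsv \
                --phenotypes sim/phenotypes.csv --out est/
triqtl mc --variant C07 --sigma2 10 --reps 10 --seed 1
triqtl study --reps 200 --seed 1 --out results/
```

`triqtl study` writes one CSV panel per (error variance × epistasis × effect
mode) cell with per-variant means, mean squared errors (dispersion about the
Monte Carlo mean by default) and mean coefficients of determination.

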