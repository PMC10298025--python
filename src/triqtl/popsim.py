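"""Simulation of DH-line genotypes and plant-level phenotypes.

Meiosis follows a Markov crossover process along the ordered markers of each
chromosome with Haldane recombination fractions (no interference),
``r = (1 - exp(-2 d / 100)) / 2`` for a map distance ``d`` in cM.  A doubled
haploid fixes a single gamete, so the line genotype equals the gamete
haplotype, coded -1/+1 for the two parental alleles.

Phenotypes follow the linear model ``y = mu + A beta + E gamma + T delta + e``
evaluated at the true architecture, with Gaussian error.  The study's error
variance is defined at the line-mean level: each line is represented by
``n_plants`` plants whose individual errors have variance
``n_plants * sigma^2``, so the mean of the plants has error variance
``sigma^2`` and the per-line sample variance of plants is available as the
weight source for weighted regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GeneticMap, TraitArchitecture

__all__ = [
    "DHPopulation",
    "haldane_recombination_fraction",
    "simulate_dh_genotypes",
    "genetic_values",
    "simulate_phenotypes",
    "simulate_population",
]


def haldane_recombination_fraction(distance_cm) -> np.ndarray:
    """Haldane map function: r = (1 - exp(-2d/100)) / 2 for d in cM."""
    d = np.asarray(distance_cm, dtype=np.float64)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


@dataclass(eq=False)
class DHPopulation:
    """A simulated (or loaded) DH mapping population.

    ``genotypes`` holds -1/+1 codes, one row per line and one column per
    marker of ``map_ref``.  ``plant_values`` is the plant-level phenotype
    matrix (``None`` when only line means are available), ``line_means`` the
    per-line phenotypic means and ``line_variances`` the per-line sample
    variances of the plants (the w_ii used as weights in weighted fits).
    """

    genotypes: np.ndarray
    line_means: np.ndarray
    line_variances: np.ndarray
    plant_values: np.ndarray | None = None
    map_ref: GeneticMap | None = None
    line_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        geno = np.asarray(self.genotypes)
        if geno.ndim != 2:
            raise ValueError("genotypes must be a 2-D (lines x markers) matrix")
        if not np.isin(geno, (-1, 1)).all():
            raise ValueError("genotype entries must all be -1 or +1")
        self.genotypes = geno.astype(np.int8, copy=False)
        self.line_means = np.asarray(self.line_means, dtype=np.float64)
        self.line_variances = np.asarray(self.line_variances, dtype=np.float64)
        n = geno.shape[0]
        if self.line_means.shape != (n,) or self.line_variances.shape != (n,):
            raise ValueError("line_means/line_variances must have one entry per line")
        if np.any(self.line_variances < 0):
            raise ValueError("line_variances must be >= 0")
        if self.plant_values is not None:
            pv = np.asarray(self.plant_values, dtype=np.float64)
            if pv.ndim != 2 or pv.shape[0] != n:
                raise ValueError("plant_values must be (n_lines x n_plants)")
            if not np.allclose(pv.mean(axis=1), self.line_means, atol=1e-9, rtol=0):
                raise ValueError("line_means must equal the row means of plant_values")
            self.plant_values = pv
        if self.map_ref is not None and self.map_ref.n_markers != geno.shape[1]:
            raise ValueError("genotype columns do not match the map's marker count")
        if self.line_ids is not None and len(self.line_ids) != n:
            raise ValueError("line_ids must have one entry per line")

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_plants(self) -> int | None:
        return None if self.plant_values is None else self.plant_values.shape[1]

    @classmethod
    def from_line_means(
        cls,
        genotypes: np.ndarray,
        line_means: np.ndarray,
        map_ref: GeneticMap | None = None,
        line_variances: np.ndarray | None = None,
        line_ids: tuple[str, ...] | None = None,
    ) -> "DHPopulation":
        """Wrap pre-aggregated data (no plant-level records).

        When ``line_variances`` is omitted the lines are treated as
        homoscedastic with unit variance, which makes weighted fits collapse
        to ordinary least squares.
        """
        means = np.asarray(line_means, dtype=np.float64)
        if line_variances is None:
            line_variances = np.ones_like(means)
        return cls(
            genotypes=np.asarray(genotypes),
            line_means=means,
            line_variances=np.asarray(line_variances, dtype=np.float64),
            plant_values=None,
            map_ref=map_ref,
            line_ids=line_ids,
        )


def simulate_dh_genotypes(
    gmap: GeneticMap, n_lines: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate -1/+1 marker genotypes for ``n_lines`` DH lines.

    Per chromosome, the first marker allele is -1/+1 with probability 1/2;
    between adjacent markers the allele switches with the Haldane
    recombination fraction for their spacing; chromosomes segregate
    independently.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2 (extreme-line estimation needs two lines)")
    geno = np.empty((n_lines, gmap.n_markers), dtype=np.int8)
    for chrom in gmap.chromosomes:
        idx = gmap.chromosome_index(chrom)
        pos = gmap.position_cm[idx]
        r = haldane_recombination_fraction(np.diff(pos))
        first = (rng.integers(0, 2, size=n_lines) * 2 - 1).astype(np.int8)
        if idx.size == 1:
            geno[:, idx[0]] = first
            continue
        switches = rng.random((n_lines, idx.size - 1)) < r
        parity = np.cumsum(switches, axis=1) & 1  # odd number of switches flips
        block = np.empty((n_lines, idx.size), dtype=np.int8)
        block[:, 0] = first
        block[:, 1:] = first[:, None] * (1 - 2 * parity)
        geno[:, idx] = block
    return geno


def genetic_values(genotypes: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Noise-free genotypic values mu + A beta + E gamma + T delta per line."""
    x = np.asarray(genotypes, dtype=np.float64)
    q = x.shape[1]
    for m in arch.qtl_markers:
        if not 0 <= m < q:
            raise IndexError(f"QTL marker index {m} outside genotype matrix with {q} markers")
    g = np.full(x.shape[0], float(arch.intercept))
    for m, beta in zip(arch.qtl_markers, arch.additive_effects):
        g += beta * x[:, m]
    for a, b, gamma in arch.epistatic_pairs:
        if gamma != 0.0:
            g += gamma * x[:, a] * x[:, b]
    for a, b, c, delta in arch.triples:
        if delta != 0.0:
            g += delta * x[:, a] * x[:, b] * x[:, c]
    return g


def simulate_phenotypes(
    genetic_values: np.ndarray,
    error_variance: float,
    n_plants: int,
    rng: np.random.Generator,
    error_level: str = "line_mean",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate plant-level phenotypes around the line genotypic values.

    Returns ``(plant_values, line_means, line_variances)``.  With the default
    ``error_level='line_mean'`` each plant error has variance
    ``n_plants * error_variance`` so that the line mean has error variance
    ``error_variance``; with ``'plant'`` the plant errors have variance
    ``error_variance`` directly.
    """
    if error_variance < 0:
        raise ValueError("error_variance must be >= 0")
    if n_plants < 2:
        raise ValueError("n_plants must be >= 2 (per-line variance needs two plants)")
    if error_level not in ("line_mean", "plant"):
        raise ValueError("error_level must be 'line_mean' or 'plant'")
    g = np.asarray(genetic_values, dtype=np.float64)
    plant_var = error_variance * n_plants if error_level == "line_mean" else error_variance
    noise = rng.normal(0.0, np.sqrt(plant_var), size=(g.size, n_plants))
    plants = g[:, None] + noise
    means = plants.mean(axis=1)
    variances = plants.var(axis=1, ddof=1)
    return plants, means, variances


def simulate_population(
    gmap: GeneticMap,
    arch: TraitArchitecture,
    n_lines: int = 500,
    n_plants: int = 10,
    rng: np.random.Generator | None = None,
    error_level: str = "line_mean",
) -> DHPopulation:
    """Simulate a complete DH population under one architecture."""
    if rng is None:
        rng = np.random.default_rng()
    geno = simulate_dh_genotypes(gmap, n_lines, rng)
    g = genetic_values(geno, arch)
    plants, means, variances = simulate_phenotypes(
        g, arch.error_variance, n_plants, rng, error_level=error_level
    )
    return DHPopulation(
        genotypes=geno,
        line_means=means,
        line_variances=variances,
        plant_values=plants,
        map_ref=gmap,
        line_ids=tuple(f"L{i + 1:04d}" for i in range(n_lines)),
    )
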