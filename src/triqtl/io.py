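"""File formats, configuration and deterministic test fixtures.

All interchange formats are plain text: the genetic map as TSV
(``marker  chrom  pos_cM``), genotypes as CSV (first column ``line``, then
one -1/1 column per marker), plant phenotypes as long-format CSV
(``line, plant, value``), and study results / estimation reports as CSV.
Study configuration is YAML or JSON with a strict schema.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genome, popsim, regest
from .genome import GeneticMap, TraitArchitecture
from .popsim import DHPopulation

__all__ = [
    "read_map_tsv",
    "write_map_tsv",
    "read_genotypes_csv",
    "write_genotypes_csv",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
    "write_report_csv",
    "write_variant_catalog_csv",
    "StudyConfig",
    "load_config",
    "make_fixture",
]


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


def write_map_tsv(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    expected = ["marker", "chrom", "pos_cM"]
    if list(df.columns) != expected:
        raise ValueError(f"map file must have columns {expected}, found {list(df.columns)}")
    return GeneticMap(
        tuple(df["marker"].astype(str)),
        df["chrom"].to_numpy(dtype=np.int64),
        df["pos_cM"].to_numpy(dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def write_genotypes_csv(pop: DHPopulation, path) -> None:
    if pop.map_ref is None:
        raise ValueError("population has no map; marker column names unavailable")
    ids = pop.line_ids or tuple(f"L{i + 1:04d}" for i in range(pop.n_lines))
    df = pd.DataFrame(pop.genotypes, columns=list(pop.map_ref.marker_ids))
    df.insert(0, "line", list(ids))
    df.to_csv(path, index=False)


def read_genotypes_csv(path, gmap: GeneticMap | None = None):
    """Read a genotype CSV; returns ``(genotypes, line_ids, marker_ids)``.

    Entries other than -1/1 are rejected with the offending cell named; when
    a map is given, the marker columns must match its marker ids exactly.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "line":
        raise ValueError("first column of a genotype CSV must be 'line'")
    line_ids = tuple(df["line"].astype(str))
    marker_ids = tuple(df.columns[1:])
    if gmap is not None and marker_ids != gmap.marker_ids:
        raise ValueError("genotype file marker columns do not match the map's marker ids")
    geno = df.iloc[:, 1:].to_numpy()
    bad = ~np.isin(geno, (-1, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype {geno[r, c]!r} for line {line_ids[r]!r}, "
            f"marker {marker_ids[c]!r} (entries must be -1 or 1)"
        )
    return geno.astype(np.int8), line_ids, marker_ids


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def write_phenotypes_csv(pop: DHPopulation, path) -> None:
    if pop.plant_values is None:
        raise ValueError("population has no plant-level phenotypes")
    ids = pop.line_ids or tuple(f"L{i + 1:04d}" for i in range(pop.n_lines))
    n, m = pop.plant_values.shape
    df = pd.DataFrame(
        {
            "line": np.repeat(list(ids), m),
            "plant": np.tile(np.arange(1, m + 1), n),
            "value": pop.plant_values.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_phenotypes_csv(path):
    """Read long-format plant phenotypes; returns ``(plant_values, line_ids)``.

    Lines must all have the same number of plants; line order follows first
    appearance in the file.
    """
    df = pd.read_csv(path)
    expected = ["line", "plant", "value"]
    if list(df.columns) != expected:
        raise ValueError(f"phenotype file must have columns {expected}")
    counts = df.groupby("line", sort=False).size()
    if counts.nunique() != 1:
        raise ValueError("all lines must have the same number of plants")
    line_ids = tuple(str(x) for x in counts.index)
    m = int(counts.iloc[0])
    values = df["value"].to_numpy(dtype=np.float64).reshape(len(line_ids), m)
    return values, line_ids


# ---------------------------------------------------------------------------
# estimation report
# ---------------------------------------------------------------------------


def report_frame(fit: regest.FitResult, gmap: GeneticMap | None = None) -> pd.DataFrame:
    """One row per fitted term plus a summary row with the aaa total and R^2."""

    def name(i: int) -> str:
        return gmap.marker_ids[i] if gmap is not None else f"m{i}"

    spec = fit.spec
    rows = [
        {
            "term_type": "intercept",
            "markers": "",
            "estimate": fit.mu_hat,
            "p_value": fit.p_values[0] if fit.p_values is not None else np.nan,
        }
    ]
    terms = (
        [("additive", (i,)) for i in spec.additive]
        + [("pair", p) for p in spec.pairs]
        + [("triple", t) for t in spec.triples]
    )
    coefs = np.concatenate([fit.beta_hat, fit.gamma_hat, fit.delta_hat])
    pv = fit.p_values[1:] if fit.p_values is not None else np.full(len(terms), np.nan)
    for (kind, term), est, p in zip(terms, coefs, pv):
        rows.append(
            {
                "term_type": kind,
                "markers": ";".join(name(i) for i in term),
                "estimate": est,
                "p_value": p,
            }
        )
    rows.append(
        {
            "term_type": "total_aaa",
            "markers": "",
            "estimate": regest.total_aaa(fit),
            "p_value": np.nan,
        }
    )
    rows.append(
        {"term_type": "r_squared", "markers": "", "estimate": fit.r_squared, "p_value": np.nan}
    )
    return pd.DataFrame(rows)


def write_report_csv(fit: regest.FitResult, path, gmap: GeneticMap | None = None) -> None:
    report_frame(fit, gmap).to_csv(path, index=False)


def write_variant_catalog_csv(path) -> None:
    genome.variant_catalog().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Strict-schema configuration for Monte Carlo study runs."""

    n_lines: int = 500
    n_plants: int = 10
    n_reps: int = 200
    base_seed: int = 0
    conditions: list[str] = field(default_factory=list)  # variant codes filter; empty = all
    error_variances: list[float] = field(default_factory=lambda: [5.0, 10.0])
    alpha: float = 0.05
    aaa_form: str = "centered"
    mse_mode: str = "dispersion"
    map_path: str | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.n_lines < 2 or self.n_plants < 2 or self.n_reps < 2:
            raise ValueError("n_lines, n_plants and n_reps must all be >= 2")
        if int(self.base_seed) != self.base_seed:
            raise ValueError("base_seed must be an integer")
        for code in self.conditions:
            genome.variant_triples(code)
        if self.aaa_form not in ("centered", "literal"):
            raise ValueError("aaa_form must be 'centered' or 'literal'")
        if self.mse_mode not in ("dispersion", "truth"):
            raise ValueError("mse_mode must be 'dispersion' or 'truth'")


def load_config(path) -> StudyConfig:
    """Load YAML (.yml/.yaml) or JSON (.json) config; unknown keys rejected."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        data = yaml.safe_load(text) or {}
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise ValueError(f"config must be .yaml/.yml or .json, got {path.suffix!r}")
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    known = set(StudyConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}")
    return StudyConfig(**data)


def config_to_dict(cfg: StudyConfig) -> dict:
    return asdict(cfg)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixture(scale: str = "tiny", seed: int = 0):
    """Deterministic test populations.

    ``tiny``: 2 chromosomes x 10 markers (10 cM spacing), 40 lines, 5 QTLs,
    one epistatic pair and one triple carrying the full aaa total of 15.
    ``small``: the default 10 x 100 map at 100 lines under variant C01.
    Returns ``(population, architecture)``.
    """
    scale_key = {"tiny": 1, "small": 2}.get(scale, 0)
    rng = np.random.default_rng(np.random.SeedSequence([scale_key, int(seed)]))
    if scale == "tiny":
        gmap = genome.default_map(n_chromosomes=2, markers_per_chromosome=10, spacing_cm=10.0)
        arch = TraitArchitecture(
            qtl_names=("Q1", "Q2", "Q3", "Q4", "Q5"),
            qtl_markers=(1, 4, 7, 12, 15),
            additive_effects=(2.0, 2.0, 2.0, 2.0, 2.0),
            epistatic_pairs=((1, 12, 2.0),),
            triples=((1, 4, 7, 15.0),),
            intercept=100.0,
            error_variance=5.0,
        )
        pop = popsim.simulate_population(gmap, arch, n_lines=40, n_plants=10, rng=rng)
        return pop, arch
    if scale == "small":
        gmap = genome.default_map()
        arch = genome.build_architecture("C01", epistasis_on=True, error_variance=5.0, gmap=gmap)
        pop = popsim.simulate_population(gmap, arch, n_lines=100, n_plants=10, rng=rng)
        return pop, arch
    raise ValueError("scale must be 'tiny' or 'small'")
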