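"""Genetic map, QTL architecture and the catalog of QTL-triple variants.

The study design is a biparental doubled-haploid (DH) population genotyped on
10 chromosomes of 100 cM, with 100 evenly spaced markers (1 cM) per
chromosome.  A fixed set of 14 QTLs (Q1..Q14, additive effect 2 each) sits on
chromosomes 1, 3, 5, 7, 9 and 10; five epistatic pairs act with a common
additive-by-additive effect (2, or 0 when epistasis is switched off); and one
of twelve cataloged layouts (C01..C12) assigns 1, 2, 3 or 5 QTL triples whose
additive-by-additive-by-additive (aaa) effects always sum to a fixed total of
15 trait units.  The trait intercept is 100.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "TraitArchitecture",
    "VariantSpec",
    "default_map",
    "variant_triples",
    "triple_effects",
    "build_architecture",
    "variant_catalog",
    "TOTAL_AAA",
    "QTL_LOCATIONS",
    "QTL_NAMES",
    "EPISTATIC_PAIR_NAMES",
    "VARIANT_CODES",
]

#: Total additive-by-additive-by-additive effect assumed in every variant.
TOTAL_AAA = 15.0
DEFAULT_ADDITIVE_EFFECT = 2.0
DEFAULT_EPISTATIC_EFFECT = 2.0
DEFAULT_INTERCEPT = 100.0

#: Chromosome and cM position of each QTL.  The chromosome assignment
#: (Q1 on 1; Q2,Q3 on 3; Q4,Q5 on 5; Q6-Q8 on 7; Q9-Q11 on 9; Q12-Q14 on 10)
#: is part of the study design; the within-chromosome positions are a fixed
#: package default chosen to keep linked and unlinked triple layouts distinct.
QTL_LOCATIONS: dict[str, tuple[int, float]] = {
    "Q1": (1, 50.0),
    "Q2": (3, 33.0),
    "Q3": (3, 66.0),
    "Q4": (5, 33.0),
    "Q5": (5, 66.0),
    "Q6": (7, 25.0),
    "Q7": (7, 50.0),
    "Q8": (7, 75.0),
    "Q9": (9, 25.0),
    "Q10": (9, 50.0),
    "Q11": (9, 75.0),
    "Q12": (10, 25.0),
    "Q13": (10, 50.0),
    "Q14": (10, 75.0),
}

QTL_NAMES: tuple[str, ...] = tuple(QTL_LOCATIONS)

#: The five epistatic QTL pairs acting on the trait.
EPISTATIC_PAIR_NAMES: tuple[tuple[str, str], ...] = (
    ("Q1", "Q2"),
    ("Q4", "Q5"),
    ("Q6", "Q7"),
    ("Q8", "Q11"),
    ("Q1", "Q14"),
)

# variant code -> (triples, placement descriptor)
_VARIANT_TABLE: dict[str, tuple[tuple[tuple[str, str, str], ...], str]] = {
    "C01": ((("Q6", "Q7", "Q8"),), "all on one chromosome"),
    "C02": ((("Q1", "Q2", "Q3"),), "on two different chromosomes"),
    "C03": ((("Q1", "Q2", "Q4"),), "on three different chromosomes"),
    "C04": ((("Q6", "Q7", "Q8"), ("Q9", "Q10", "Q11")), "all on one chromosome"),
    "C05": ((("Q1", "Q2", "Q3"), ("Q4", "Q5", "Q6")), "on two different chromosomes"),
    "C06": ((("Q1", "Q2", "Q4"), ("Q3", "Q5", "Q7")), "on three different chromosomes"),
    "C07": (
        (("Q6", "Q7", "Q8"), ("Q9", "Q10", "Q11"), ("Q12", "Q13", "Q14")),
        "all on one chromosome",
    ),
    "C08": (
        (("Q1", "Q2", "Q3"), ("Q4", "Q5", "Q6"), ("Q7", "Q10", "Q11")),
        "on two different chromosomes",
    ),
    "C09": (
        (("Q1", "Q2", "Q4"), ("Q3", "Q5", "Q7"), ("Q4", "Q6", "Q9")),
        "on three different chromosomes",
    ),
    "C10": (
        (
            ("Q6", "Q7", "Q8"),
            ("Q9", "Q10", "Q11"),
            ("Q12", "Q13", "Q14"),
            ("Q1", "Q2", "Q3"),
            ("Q1", "Q4", "Q5"),
        ),
        "three triples on one chromosome and two triples on two chromosomes",
    ),
    "C11": (
        (
            ("Q1", "Q2", "Q3"),
            ("Q2", "Q4", "Q5"),
            ("Q4", "Q6", "Q7"),
            ("Q1", "Q9", "Q10"),
            ("Q1", "Q12", "Q14"),
        ),
        "on two different chromosomes",
    ),
    "C12": (
        (
            ("Q1", "Q2", "Q4"),
            ("Q3", "Q5", "Q6"),
            ("Q1", "Q9", "Q12"),
            ("Q2", "Q10", "Q14"),
            ("Q5", "Q10", "Q12"),
        ),
        "on three different chromosomes",
    ),
}

VARIANT_CODES: tuple[str, ...] = tuple(_VARIANT_TABLE)

#: Unequal per-triple aaa effects; the first listed triple carries the large
#: effect.  All splits sum to TOTAL_AAA.
_DIFFERENT_EFFECTS: dict[int, tuple[float, ...]] = {
    2: (10.0, 5.0),
    3: (9.0, 3.0, 3.0),
    5: (7.0, 2.0, 2.0, 2.0, 2.0),
}

_VALID_N_TRIPLES = (1, 2, 3, 5)


@dataclass(frozen=True, eq=False)
class GeneticMap:
    """Ordered marker loci with chromosome assignment and cM positions.

    Markers must be grouped by chromosome, with strictly increasing positions
    within each chromosome and unique marker identifiers.
    """

    marker_ids: tuple[str, ...]
    chromosome: np.ndarray  # 1-based chromosome index per marker
    position_cm: np.ndarray  # cM position per marker

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        pos = np.asarray(self.position_cm, dtype=np.float64)
        ids = tuple(str(m) for m in self.marker_ids)
        if not (len(ids) == chrom.size == pos.size):
            raise ValueError("marker_ids, chromosome and position_cm must have equal length")
        if len(ids) == 0:
            raise ValueError("a genetic map needs at least one marker")
        if len(set(ids)) != len(ids):
            raise ValueError("marker_ids must be unique")
        if np.any(chrom < 1):
            raise ValueError("chromosome indices are 1-based and must be >= 1")
        # grouped by chromosome, positions strictly increasing within a group
        change = np.flatnonzero(np.diff(chrom) != 0)
        seen = set()
        start = 0
        for stop in [*(change + 1), chrom.size]:
            c = int(chrom[start])
            if c in seen:
                raise ValueError(f"markers of chromosome {c} are not contiguous")
            seen.add(c)
            block = pos[start:stop]
            if np.any(np.diff(block) <= 0):
                raise ValueError(f"positions on chromosome {c} must be strictly increasing")
            start = stop
        object.__setattr__(self, "marker_ids", ids)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_cm", pos)
        object.__setattr__(self, "_id_index", {m: i for i, m in enumerate(ids)})

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def chromosomes(self) -> tuple[int, ...]:
        out: list[int] = []
        for c in self.chromosome:
            if not out or out[-1] != int(c):
                out.append(int(c))
        return tuple(out)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def chromosome_index(self, chrom: int) -> np.ndarray:
        """Marker indices of one chromosome, in map order."""
        idx = np.flatnonzero(self.chromosome == chrom)
        if idx.size == 0:
            raise KeyError(f"no chromosome {chrom} in map")
        return idx

    def index_of(self, marker_id: str) -> int:
        try:
            return self._id_index[marker_id]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def marker_at(self, chrom: int, pos_cm: float) -> int:
        """Index of the marker at an exact (chromosome, position) locus."""
        idx = self.chromosome_index(chrom)
        hit = idx[np.isclose(self.position_cm[idx], pos_cm)]
        if hit.size == 0:
            raise KeyError(f"no marker at chromosome {chrom}, {pos_cm} cM")
        return int(hit[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": list(self.marker_ids),
                "chrom": self.chromosome,
                "pos_cM": self.position_cm,
            }
        )


def default_map(
    n_chromosomes: int = 10,
    markers_per_chromosome: int = 100,
    spacing_cm: float = 1.0,
) -> GeneticMap:
    """The study's default map: 10 x 100 markers, 1 cM apart, 100 cM chromosomes.

    Marker ``k`` of chromosome ``c`` sits at ``k * spacing_cm`` (k = 1..100),
    so adjacent spacing and total chromosome length both match the design.
    """
    ids: list[str] = []
    chrom: list[int] = []
    pos: list[float] = []
    for c in range(1, n_chromosomes + 1):
        for k in range(1, markers_per_chromosome + 1):
            ids.append(f"M{c:02d}_{k:03d}")
            chrom.append(c)
            pos.append(k * spacing_cm)
    return GeneticMap(tuple(ids), np.array(chrom), np.array(pos))


@dataclass(frozen=True)
class VariantSpec:
    """One row of the QTL-triple catalog (codes C01..C12)."""

    code: str
    n_triples: int
    triples: tuple[tuple[str, str, str], ...]
    placement: str
    effect_mode: str = "equal"

    def __post_init__(self) -> None:
        if self.n_triples != len(self.triples):
            raise ValueError("n_triples must match the number of triples")
        if self.effect_mode not in ("equal", "different"):
            raise ValueError("effect_mode must be 'equal' or 'different'")
        if self.effect_mode == "different" and self.n_triples < 2:
            raise ValueError("effect_mode='different' requires at least two triples")
        for t in self.triples:
            if len(set(t)) != 3:
                raise ValueError(f"triple {t} repeats a QTL")
            for q in t:
                if q not in QTL_LOCATIONS:
                    raise ValueError(f"unknown QTL name {q!r}")


def variant_triples(code: str, effect_mode: str = "equal") -> VariantSpec:
    """Catalog lookup: the QTL triples and placement for a variant code."""
    try:
        triples, placement = _VARIANT_TABLE[code]
    except KeyError:
        valid = ", ".join(VARIANT_CODES)
        raise KeyError(f"unknown variant code {code!r}; valid codes are {valid}") from None
    return VariantSpec(code, len(triples), triples, placement, effect_mode)


def triple_effects(n_triples: int, effect_mode: str = "equal") -> list[float]:
    """Per-triple aaa effects summing to ``TOTAL_AAA`` (= 15 trait units).

    ``equal`` splits the total evenly; ``different`` gives one triple a much
    larger effect ([10, 5]; [9, 3, 3]; [7, 2, 2, 2, 2]).
    """
    if n_triples not in _VALID_N_TRIPLES:
        raise ValueError(f"n_triples must be one of {_VALID_N_TRIPLES}, got {n_triples}")
    if effect_mode == "equal":
        return [TOTAL_AAA / n_triples] * n_triples
    if effect_mode == "different":
        if n_triples < 2:
            raise ValueError("effect_mode='different' requires at least two triples")
        return list(_DIFFERENT_EFFECTS[n_triples])
    raise ValueError("effect_mode must be 'equal' or 'different'")


@dataclass(frozen=True)
class TraitArchitecture:
    """True genetic architecture of the simulated quantitative trait.

    Effect parameters follow the standard biometrical model for fully
    homozygous lines coded -1/+1: additive effects multiply single genotype
    codes, epistatic (aa) effects multiply products of two codes and triple
    (aaa) effects products of three codes.  ``error_variance`` is the
    environmental variance at the line-mean level.
    """

    qtl_names: tuple[str, ...]
    qtl_markers: tuple[int, ...]  # marker column index per QTL
    additive_effects: tuple[float, ...]
    epistatic_pairs: tuple[tuple[int, int, float], ...]  # (marker, marker, gamma)
    triples: tuple[tuple[int, int, int, float], ...]  # (marker, marker, marker, delta)
    intercept: float = DEFAULT_INTERCEPT
    error_variance: float = 5.0

    def __post_init__(self) -> None:
        if len(self.qtl_names) != len(self.qtl_markers) or len(self.qtl_names) != len(
            self.additive_effects
        ):
            raise ValueError("qtl_names, qtl_markers and additive_effects must align")
        if len(set(self.qtl_markers)) != len(self.qtl_markers):
            raise ValueError("QTLs must sit on distinct markers")
        if self.error_variance < 0:
            raise ValueError("error_variance must be >= 0")
        for a, b, _ in self.epistatic_pairs:
            if a == b:
                raise ValueError("an epistatic pair needs two distinct loci")
        for a, b, c, _ in self.triples:
            if len({a, b, c}) != 3:
                raise ValueError("a triple needs three distinct loci")

    @property
    def total_triple_effect(self) -> float:
        return float(sum(t[-1] for t in self.triples))

    def marker_of(self, qtl_name: str) -> int:
        return self.qtl_markers[self.qtl_names.index(qtl_name)]


def build_architecture(
    variant: VariantSpec | str,
    epistasis_on: bool = True,
    error_variance: float = 5.0,
    gmap: GeneticMap | None = None,
    qtl_locations: dict[str, tuple[int, float]] | None = None,
    additive_effect: float = DEFAULT_ADDITIVE_EFFECT,
    epistatic_effect: float = DEFAULT_EPISTATIC_EFFECT,
    intercept: float = DEFAULT_INTERCEPT,
) -> TraitArchitecture:
    """Assemble the full trait architecture for one study variant.

    Every QTL coincides exactly with the marker at its map position (perfect
    marking: no recombination between a QTL and its marker), so QTLs are
    addressed by marker column index throughout.
    """
    if isinstance(variant, str):
        variant = variant_triples(variant)
    if error_variance < 0:
        raise ValueError("error_variance must be >= 0")
    gmap = gmap if gmap is not None else default_map()
    locations = qtl_locations if qtl_locations is not None else QTL_LOCATIONS
    idx = {name: gmap.marker_at(c, p) for name, (c, p) in locations.items()}
    gamma = epistatic_effect if epistasis_on else 0.0
    pairs = tuple((idx[a], idx[b], gamma) for a, b in EPISTATIC_PAIR_NAMES)
    effects = triple_effects(variant.n_triples, variant.effect_mode)
    triples = tuple(
        (idx[a], idx[b], idx[c], eff)
        for (a, b, c), eff in zip(variant.triples, effects)
    )
    return TraitArchitecture(
        qtl_names=tuple(locations),
        qtl_markers=tuple(idx[n] for n in locations),
        additive_effects=(additive_effect,) * len(locations),
        epistatic_pairs=pairs,
        triples=triples,
        intercept=intercept,
        error_variance=error_variance,
    )


def variant_catalog() -> pd.DataFrame:
    """The triple catalog as a table (one row per variant code)."""
    rows = []
    for code in VARIANT_CODES:
        triples, placement = _VARIANT_TABLE[code]
        rows.append(
            {
                "variant_code": code,
                "n_triples": len(triples),
                "triples": "; ".join("".join(t) for t in triples),
                "placement": placement,
            }
        )
    return pd.DataFrame(rows)


def qtl_chromosome(name: str) -> int:
    """Chromosome carrying a named QTL."""
    return QTL_LOCATIONS[name][0]
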