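"""Phenotypic (extreme-line) estimation of the total aaa effect.

The phenotypic route needs no marker data: the total three-way interaction
effect is read off the best and worst line means relative to the population
mean, and a rough count of segregating effective factors follows from the
phenotypic range and the variance of line means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhenotypicEstimate", "aaa_phenotypic", "effective_factors", "phenotypic_estimate"]


@dataclass(frozen=True)
class PhenotypicEstimate:
    """Summary of the extreme-line analysis of one population."""

    l_max: float
    l_min: float
    l_bar: float
    aaa_p: float
    v_l: float
    k_hat: float | None  # None when V_L = 0 (degenerate input)


def _as_means(line_means) -> np.ndarray:
    y = np.asarray(line_means, dtype=np.float64).ravel()
    if y.size < 2:
        raise ValueError("need at least two line means")
    if not np.isfinite(y).all():
        raise ValueError("line means must be finite")
    return y


def aaa_phenotypic(line_means, form: str = "centered") -> float:
    """Extreme-line estimate of the total aaa interaction effect.

    ``form='centered'`` (default) computes ``(L_max + L_min)/2 - L_bar``: the
    midpoint of the extreme lines relative to the population mean, which is
    location-invariant.  ``form='literal'`` computes
    ``(L_max + L_min - L_bar)/2`` instead.
    """
    y = _as_means(line_means)
    l_max, l_min, l_bar = y.max(), y.min(), y.mean()
    if form == "centered":
        return float(0.5 * (l_max + l_min) - l_bar)
    if form == "literal":
        return float(0.5 * (l_max + l_min - l_bar))
    raise ValueError("form must be 'centered' or 'literal'")


def effective_factors(line_means) -> float:
    """Effective-factor count K = (L_max - L_min)^2 / (4 V_L).

    ``V_L`` is the sample variance (divisor n-1) of the line means.  A zero
    variance (all lines identical) leaves the count undefined and is
    rejected.
    """
    y = _as_means(line_means)
    v_l = float(y.var(ddof=1))
    if v_l == 0.0:
        raise ValueError("effective_factors undefined: line means have zero variance")
    rng = float(y.max() - y.min())
    return rng * rng / (4.0 * v_l)


def phenotypic_estimate(line_means, form: str = "centered") -> PhenotypicEstimate:
    """All extreme-line summaries of one vector of line means."""
    y = _as_means(line_means)
    v_l = float(y.var(ddof=1))
    k_hat = None if v_l == 0.0 else effective_factors(y)
    return PhenotypicEstimate(
        l_max=float(y.max()),
        l_min=float(y.min()),
        l_bar=float(y.mean()),
        aaa_p=aaa_phenotypic(y, form=form),
        v_l=v_l,
        k_hat=k_hat,
    )
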