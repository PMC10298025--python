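"""Genotypic estimation of QTL, epistatic and three-way interaction effects.

The trait model for line means is ``y = G alpha + e`` with
``G = [1 | A | E | T]``: a column of ones, the -1/+1 genotype codes of the
selected markers (A), elementwise products of two selected columns (E,
additive-by-additive epistasis) and elementwise products of three selected
columns (T, additive-by-additive-by-additive interaction).  Interaction
columns may only reference markers that carry an additive term.

Marker selection is a staged stepwise search by the Akaike Information
Criterion: additive terms are first selected within each chromosome, the
survivors are pooled and re-selected, then candidate pair products and
candidate triple products among the selected markers are added stepwise.
Retained coefficients are finally screened by Bonferroni-corrected t-tests.

Fitting is by ordinary least squares or by weighted least squares with
per-line variance weights (the empirical plant variance of each DH line);
both are computed through a QR decomposition, which is algebraically equal
to the textbook normal-equation solutions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .popsim import DHPopulation
from .genome import GeneticMap

__all__ = [
    "ModelSpec",
    "FitResult",
    "CollinearityError",
    "build_design",
    "fit_ols",
    "fit_wls",
    "select_model",
    "total_aaa",
    "r_squared",
    "floor_weights",
    "estimate_all",
]

logger = logging.getLogger(__name__)

_COLLIN_RTOL = 1e-8  # candidate/column considered dependent below this relative residual
_SSE_FLOOR = 1e-12
_AIC_EPS = 1e-7


class CollinearityError(ValueError):
    """Raised when a design matrix is (numerically) rank deficient."""

    def __init__(self, message: str, columns: tuple[int, ...] = ()):
        super().__init__(message)
        self.columns = columns


@dataclass(frozen=True)
class ModelSpec:
    """Selected model terms: additive marker indices, pairs and triples.

    Terms are stored in canonical sorted order; pair and triple terms may
    only reference markers present in ``additive``.
    """

    additive: tuple[int, ...] = ()
    pairs: tuple[tuple[int, int], ...] = ()
    triples: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        additive = tuple(sorted(int(i) for i in self.additive))
        if len(set(additive)) != len(additive):
            raise ValueError("duplicate additive terms")
        aset = set(additive)

        def canon(term, size, kind):
            t = tuple(sorted(int(i) for i in term))
            if len(t) != size or len(set(t)) != size:
                raise ValueError(f"{kind} term {term} must name {size} distinct loci")
            missing = [i for i in t if i not in aset]
            if missing:
                raise ValueError(
                    f"{kind} term {term} references markers {missing} without additive terms"
                )
            return t

        pairs = tuple(sorted(canon(p, 2, "pair") for p in self.pairs))
        triples = tuple(sorted(canon(t, 3, "triple") for t in self.triples))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate pair terms")
        if len(set(triples)) != len(triples):
            raise ValueError("duplicate triple terms")
        object.__setattr__(self, "additive", additive)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "triples", triples)

    @classmethod
    def from_architecture(cls, arch) -> "ModelSpec":
        """The true model terms of a simulated architecture (oracle spec)."""
        return cls(
            additive=tuple(arch.qtl_markers),
            pairs=tuple((a, b) for a, b, _ in arch.epistatic_pairs),
            triples=tuple((a, b, c) for a, b, c, _ in arch.triples),
        )

    @property
    def n_terms(self) -> int:
        return len(self.additive) + len(self.pairs) + len(self.triples)

    def term_labels(self) -> list[str]:
        """Human-readable labels for the design columns (incl. intercept)."""
        labels = ["intercept"]
        labels += [f"m{i}" for i in self.additive]
        labels += ["x".join(f"m{i}" for i in p) for p in self.pairs]
        labels += ["x".join(f"m{i}" for i in t) for t in self.triples]
        return labels


def build_design(genotypes: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Design matrix G = [1 | A | E | T] for the given term specification."""
    x = np.asarray(genotypes, dtype=np.float64)
    n, q = x.shape
    for i in spec.additive:
        if not 0 <= i < q:
            raise IndexError(f"additive term references marker {i} outside matrix with {q} markers")
    cols = [np.ones(n)]
    cols += [x[:, i] for i in spec.additive]
    cols += [x[:, a] * x[:, b] for a, b in spec.pairs]
    cols += [x[:, a] * x[:, b] * x[:, c] for a, b, c in spec.triples]
    return np.column_stack(cols)


@dataclass
class FitResult:
    """A fitted model: coefficients aligned with a :class:`ModelSpec`."""

    method: str  # "ols" or "wls"
    spec: ModelSpec | None
    mu_hat: float
    beta_hat: np.ndarray
    gamma_hat: np.ndarray
    delta_hat: np.ndarray
    residuals: np.ndarray
    r_squared: float
    sse: float
    df_resid: int
    coef: np.ndarray = field(repr=False, default=None)  # full vector incl. intercept
    coef_se: np.ndarray | None = field(repr=False, default=None)
    p_values: np.ndarray | None = field(repr=False, default=None)
    weights_used: np.ndarray | None = field(repr=False, default=None)


def _check_design(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    G = np.asarray(G, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if G.ndim != 2 or G.shape[0] != y.size:
        raise ValueError("design matrix rows must match the length of y")
    if G.shape[0] < G.shape[1]:
        raise ValueError("need at least as many observations as design columns")
    return G, y


def _fit(G, y, spec, weights=None) -> FitResult:
    """Least-squares fit via QR; with weights w_ii, the WLS estimator."""
    G, y = _check_design(G, y)
    n, k = G.shape
    if weights is not None:
        w = np.asarray(weights, dtype=np.float64).ravel()
        if w.size != n:
            raise ValueError("weights must have one entry per observation")
        if np.any(w <= 0) or not np.isfinite(w).all():
            raise ValueError("all weights (per-line variances) must be positive and finite")
        sw = np.sqrt(w)
        Gt, yt = G / sw[:, None], y / sw
    else:
        sw = None
        Gt, yt = G, y

    Q, R, piv = linalg.qr(Gt, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(n, k) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = diag <= tol
    if bad.any():
        labels = spec.term_labels() if spec is not None else [f"col{j}" for j in range(k)]
        cols = tuple(int(j) for j in piv[np.flatnonzero(bad)])
        dep = [labels[j] for j in cols]
        raise CollinearityError(
            f"design matrix is rank deficient; dependent columns: {dep}", columns=cols
        )
    z = Q.T @ yt
    coef_p = linalg.solve_triangular(R, z)
    coef = np.empty(k)
    coef[piv] = coef_p
    fitted = G @ coef
    resid = y - fitted
    rt = yt - Gt @ coef
    sse = float(rt @ rt)
    df = n - k
    sigma2 = sse / df if df > 0 else np.nan

    # covariance of coefficients: sigma2 * (G'G)^-1 (in the fitting metric)
    Rinv = linalg.solve_triangular(R, np.eye(k))
    xtx_inv_p = Rinv @ Rinv.T
    xtx_inv_diag = np.empty(k)
    xtx_inv_diag[piv] = np.diag(xtx_inv_p)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * xtx_inv_diag)
        tstat = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df) if df > 0 else np.full(k, np.nan)

    # coefficient of determination in the fitting metric
    if sw is None:
        sst = float(np.sum((y - y.mean()) ** 2))
    else:
        wgt = 1.0 / (sw**2)
        ybar = float(np.sum(wgt * y) / np.sum(wgt))
        sst = float(np.sum(wgt * (y - ybar) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    r2 = float(min(1.0, max(0.0, r2))) if np.isfinite(r2) else np.nan

    if spec is not None:
        p, e = len(spec.additive), len(spec.pairs)
        beta = coef[1 : 1 + p]
        gamma = coef[1 + p : 1 + p + e]
        delta = coef[1 + p + e :]
    else:
        beta, gamma, delta = coef[1:], np.empty(0), np.empty(0)
    return FitResult(
        method="wls" if weights is not None else "ols",
        spec=spec,
        mu_hat=float(coef[0]),
        beta_hat=beta,
        gamma_hat=gamma,
        delta_hat=delta,
        residuals=resid,
        r_squared=r2,
        sse=sse,
        df_resid=df,
        coef=coef,
        coef_se=se,
        p_values=pvals,
        weights_used=None if weights is None else np.asarray(weights, dtype=np.float64),
    )


def fit_ols(G, y, spec: ModelSpec | None = None) -> FitResult:
    """Ordinary least squares on a prebuilt design (first column = intercept)."""
    return _fit(G, y, spec, weights=None)


def fit_wls(G, y, weights, spec: ModelSpec | None = None) -> FitResult:
    """Weighted least squares with per-observation variances ``weights``."""
    return _fit(G, y, spec, weights=weights)


def total_aaa(fit: FitResult) -> float:
    """Total aaa effect: the sum of the fitted triple coefficients."""
    return float(np.sum(fit.delta_hat))


def r_squared(fit: FitResult, y) -> float:
    """Coefficient of determination of a fit, recomputed from ``y``.

    Uses the plain total sum of squares for OLS fits and the
    variance-weighted analog (weights 1/w_ii, weighted mean) for WLS fits.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    if np.ptp(y) == 0:
        raise ValueError("R^2 undefined for constant y")
    resid = fit.residuals
    if fit.method == "wls" and fit.weights_used is not None:
        wgt = 1.0 / fit.weights_used
        ybar = float(np.sum(wgt * y) / np.sum(wgt))
        sse = float(np.sum(wgt * resid**2))
        sst = float(np.sum(wgt * (y - ybar) ** 2))
    else:
        sse = float(np.sum(resid**2))
        sst = float(np.sum((y - y.mean()) ** 2))
    return float(min(1.0, max(0.0, 1.0 - sse / sst)))


def floor_weights(w, rel: float = 1e-6) -> np.ndarray:
    """Clamp per-line variance estimates away from zero.

    A line whose plants happen to be nearly identical would otherwise get an
    enormous weight; the floor is ``rel`` times the median variance (with an
    absolute floor for fully degenerate inputs, e.g. noise-free data, under
    which weighting collapses to OLS).
    """
    w = np.asarray(w, dtype=np.float64).ravel()
    floor = max(rel * float(np.median(w)), 1e-12)
    return np.maximum(w, floor)


# ---------------------------------------------------------------------------
# stepwise AIC selection
# ---------------------------------------------------------------------------


def _aic(n: int, sse: float, k: int) -> float:
    """Gaussian AIC up to a constant: n log(SSE/n) + 2k."""
    return n * math.log(max(sse, _SSE_FLOOR) / n) + 2 * k


def _stepwise(y, base, cand, max_add: int, droppable: bool = True) -> list[int]:
    """Bidirectional stepwise AIC over candidate columns.

    ``base`` columns (intercept plus any terms locked in by earlier stages)
    are always kept; candidate columns are added while the AIC improves and
    may be dropped again.  Candidates whose residual against the current
    model falls below a relative tolerance are skipped (collinearity guard).
    Returns indices into ``cand`` in canonical sorted order.
    """
    n = y.size
    m = cand.shape[1]
    k0 = base.shape[1]
    cn = np.einsum("ij,ij->j", cand, cand)
    dtol = (_COLLIN_RTOL**2) * np.maximum(cn, _SSE_FLOOR)
    selected: list[int] = []
    in_model = np.zeros(m, dtype=bool)

    def rebuild():
        X = np.hstack([base, cand[:, selected]]) if selected else base
        Q, _ = np.linalg.qr(X)
        r = y - Q @ (Q.T @ y)
        Rc = cand - Q @ (Q.T @ cand)
        return r, Rc

    r, Rc = rebuild()
    sse = float(r @ r)
    k = k0
    aic = _aic(n, sse, k)
    max_iter = 4 * max_add + 100
    for _ in range(max_iter):
        # forward move: candidates are kept residualized against the current
        # model, so each scan is one pass over the columns
        moved = False
        if len(selected) < max_add and m:
            d = np.einsum("ij,ij->j", Rc, Rc)
            ok = (~in_model) & (d > dtol)
            if ok.any():
                dsse = np.zeros(m)
                num = (Rc.T @ r) ** 2
                dsse[ok] = num[ok] / d[ok]
                j = int(np.argmax(dsse))
                if ok[j] and _aic(n, sse - dsse[j], k + 1) < aic - _AIC_EPS:
                    u = Rc[:, j] / math.sqrt(d[j])
                    r = r - u * (u @ r)
                    Rc = Rc - np.outer(u, u @ Rc)
                    selected.append(j)
                    in_model[j] = True
                    sse = float(r @ r)
                    k += 1
                    aic = _aic(n, sse, k)
                    moved = True
        if moved:
            continue
        # backward move, evaluated when no addition improves the AIC:
        # dropping column j raises the SSE by coef_j^2 / (X'X)^-1_jj
        if droppable and selected:
            X = np.hstack([base, cand[:, selected]])
            Q, R = np.linalg.qr(X)
            coef = linalg.solve_triangular(R, Q.T @ y)
            Rinv = linalg.solve_triangular(R, np.eye(k))
            inv_diag = np.einsum("ij,ij->i", Rinv, Rinv)
            best_aic, best_j = aic - _AIC_EPS, None
            for pos, j in enumerate(selected):
                jj = k0 + pos
                aic_drop = _aic(n, sse + coef[jj] ** 2 / inv_diag[jj], k - 1)
                if aic_drop < best_aic:
                    best_aic, best_j = aic_drop, j
            if best_j is not None:
                selected.remove(best_j)
                in_model[best_j] = False
                r, Rc = rebuild()
                sse = float(r @ r)
                k -= 1
                aic = _aic(n, sse, k)
                continue
        break
    return sorted(selected)


def _interaction_columns(x, terms):
    if not terms:
        return np.empty((x.shape[0], 0))
    return np.column_stack([np.prod(x[:, list(t)], axis=1) for t in terms])


def _candidate_products(x, additive, order, cap):
    """All unordered ``order``-tuples of the selected additive markers."""
    combos = list(itertools.combinations(additive, order))
    if len(combos) > cap:
        logger.warning(
            "interaction candidate pool (%d terms of order %d) exceeds cap %d; truncating",
            len(combos),
            order,
            cap,
        )
        combos = combos[:cap]
    return combos, _interaction_columns(x, combos)


def _term_of_column(spec: ModelSpec, j: int):
    """Map a design-column index to its (stage, term); None for the intercept
    or for scaffold columns appended past the spec terms."""
    p, e, t = len(spec.additive), len(spec.pairs), len(spec.triples)
    if 1 <= j <= p:
        return "additive", spec.additive[j - 1]
    if p < j <= p + e:
        return "pairs", spec.pairs[j - 1 - p]
    if p + e < j <= p + e + t:
        return "triples", spec.triples[j - 1 - p - e]
    return None


def _drop_dependent(spec: ModelSpec, columns, prefer_stage: str | None = None) -> ModelSpec:
    """Remove one term responsible for a rank deficiency.

    Picks among the dependent columns, preferring the requested stage, then
    the highest-order terms (a redundant interaction is dropped before the
    markers it is built from)."""
    hits = [h for h in (_term_of_column(spec, j) for j in columns) if h is not None]
    if not hits:
        # deficiency involves only intercept/scaffold columns: drop the last
        # interaction term as a safe fallback
        if spec.triples:
            return _without(spec, "triples", spec.triples[-1])
        if spec.pairs:
            return _without(spec, "pairs", spec.pairs[-1])
        if spec.additive:
            return _without(spec, "additive", spec.additive[-1])
        raise CollinearityError("rank-deficient design with no removable terms")
    order = {"triples": 0, "pairs": 1, "additive": 2}
    hits.sort(key=lambda h: (h[0] != prefer_stage, order[h[0]]))
    stage, term = hits[0]
    logger.debug("dropping %s term %s (collinear with earlier columns)", stage, term)
    return _without(spec, stage, term)


def _fit_with_guard(x, y, spec: ModelSpec, weights=None) -> FitResult:
    """Fit a term specification, removing dependent terms if necessary."""
    while True:
        G = build_design(x, spec)
        try:
            return _fit(G, y, spec, weights=weights)
        except CollinearityError as exc:
            spec = _drop_dependent(spec, exc.columns)


def _prune_terms(x, y, spec, stage, m_tests, alpha, weights, extra=None):
    """Significance screen: iteratively drop the stage's weakest term with
    p >= alpha/m, refitting after each drop.

    ``extra`` columns (scaffolding terms from a previous selection sweep)
    are appended to the design but never tested or dropped.  Additive terms
    that participate in a retained pair or triple are kept (marginality: an
    interaction that passed its own screen keeps its main effects in the
    model); dropping an additive term also drops any interaction that
    references it.
    """
    if m_tests == 0:
        return spec
    while True:
        terms = {"additive": spec.additive, "pairs": spec.pairs, "triples": spec.triples}[stage]
        if stage == "additive":
            protected = {i for p in spec.pairs for i in p} | {i for t in spec.triples for i in t}
            terms = tuple(i for i in terms if i not in protected)
        if not terms:
            return spec
        G = build_design(x, spec)
        if extra is not None and extra.shape[1]:
            G = np.hstack([G, extra])
        try:
            fit = _fit(G, y, None if extra is not None and extra.shape[1] else spec, weights=weights)
        except CollinearityError as exc:
            spec = _drop_dependent(spec, exc.columns, prefer_stage=stage)
            continue
        p, e = len(spec.additive), len(spec.pairs)
        offset = {"additive": 1, "pairs": 1 + p, "triples": 1 + p + e}[stage]
        all_terms = {"additive": spec.additive, "pairs": spec.pairs, "triples": spec.triples}[stage]
        pv_all = fit.p_values[offset : offset + len(all_terms)]
        pv = {t: pv_all[i] for i, t in enumerate(all_terms) if t in terms}
        worst = max(pv, key=lambda t: np.inf if np.isnan(pv[t]) else pv[t])
        if np.isnan(pv[worst]) or pv[worst] >= alpha / m_tests:
            spec = _without(spec, stage, worst)
        else:
            return spec


def _without(spec: ModelSpec, stage: str, term) -> ModelSpec:
    if stage == "additive":
        additive = tuple(i for i in spec.additive if i != term)
        pairs = tuple(p for p in spec.pairs if term not in p)
        triples = tuple(t for t in spec.triples if term not in t)
        return ModelSpec(additive, pairs, triples)
    if stage == "pairs":
        return ModelSpec(spec.additive, tuple(p for p in spec.pairs if p != term), spec.triples)
    return ModelSpec(spec.additive, spec.pairs, tuple(t for t in spec.triples if t != term))


_WEIGHTING_MODES = ("none", "final_stage", "all_stages")


def _stage_weighting(weighting: str) -> tuple[bool, bool, bool]:
    """Whether (additive, pair, triple+final) stages use weighted fits."""
    if weighting not in _WEIGHTING_MODES:
        raise ValueError(f"weighting must be one of {_WEIGHTING_MODES}")
    return {
        "none": (False, False, False),
        "final_stage": (False, False, True),
        "all_stages": (True, True, True),
    }[weighting]


class _Selector:
    """Shared state for staged stepwise selection on one population."""

    def __init__(
        self,
        y,
        population: DHPopulation,
        gmap: GeneticMap | None,
        alpha: float,
        max_interaction_terms: int,
        max_terms_per_stage: int,
    ):
        self.x = population.genotypes.astype(np.float64)
        self.y = np.asarray(y, dtype=np.float64).ravel()
        if self.y.size != population.n_lines:
            raise ValueError("y must have one entry per line")
        self.gmap = gmap if gmap is not None else population.map_ref
        if self.gmap is None:
            raise ValueError("a genetic map is required (population.map_ref or gmap)")
        self.alpha = alpha
        self.cap = max_interaction_terms
        self.max_add = max_terms_per_stage
        self.w = floor_weights(population.line_variances)
        self.n = self.y.size
        self._marker_cache: dict[bool, tuple] = {}

    def _transform(self, use_w):
        if use_w:
            sw = np.sqrt(self.w)
            return self.x / sw[:, None], self.y / sw, self.w
        return self.x, self.y, None

    def _intercept(self, use_w: bool) -> np.ndarray:
        return (1.0 / np.sqrt(self.w))[:, None] if use_w else np.ones((self.n, 1))

    def _scaffold_cols(self, terms) -> np.ndarray:
        """Raw-scale columns for interaction terms carried over from a
        previous sweep (locked, never tested)."""
        return _interaction_columns(self.x, tuple(terms))

    def _additive_stage(
        self,
        use_w: bool,
        scaffold: np.ndarray | None,
        scaffold_terms: tuple = (),
    ) -> tuple[int, ...]:
        """Stages A+B: per-chromosome stepwise, then pooled re-selection.

        The pooled model is screened at an unadjusted 5% t-test: the AIC
        admits any marker reducing the deviance by ~2, which with hundreds
        of correlated candidates leaves a tail of weak proxies that would
        bloat the interaction candidate pools.  The Bonferroni-corrected
        screen runs later on the final joint model, where interaction
        variance no longer inflates the residual.
        """
        xt, yt, weights = self._transform(use_w)
        lock = None
        if scaffold is not None and scaffold.shape[1]:
            lock = scaffold / np.sqrt(self.w)[:, None] if use_w else scaffold
        base = self._intercept(use_w) if lock is None else np.hstack([self._intercept(use_w), lock])
        # Per-chromosome scans with backfitting: each chromosome is re-scanned
        # conditioning on the current selections of the other chromosomes, so
        # the within-chromosome search is not drowned by genetic variance
        # segregating elsewhere in the genome.
        chrom_sel: dict[int, list[int]] = {c: [] for c in self.gmap.chromosomes}
        for sweep in range(3):
            changed = False
            for chrom in self.gmap.chromosomes:
                idx = self.gmap.chromosome_index(chrom)
                others = [m for c, ms in chrom_sel.items() if c != chrom for m in ms]
                cbase = np.hstack([base, xt[:, others]]) if others else base
                sel = _stepwise(yt, cbase, xt[:, idx], self.max_add)
                new = [int(idx[j]) for j in sel]
                if new != chrom_sel[chrom]:
                    changed = True
                chrom_sel[chrom] = new
            if not changed:
                break
        survivors = sorted(m for ms in chrom_sel.values() for m in ms)
        if survivors:
            pool = np.array(survivors)
            sel = _stepwise(yt, base, xt[:, pool], self.max_add)
            additive = tuple(int(pool[j]) for j in sel)
        else:
            additive = ()
        if scaffold_terms:
            # loci of carried-over interactions must stay available as
            # additive terms, or the rebuilt pools cannot re-form them
            forced = {i for t in scaffold_terms for i in t}
            additive = tuple(sorted(set(additive) | forced))
            spec = ModelSpec(
                additive=additive,
                triples=tuple(t for t in scaffold_terms if len(t) == 3),
                pairs=tuple(t for t in scaffold_terms if len(t) == 2),
            )
            spec = _prune_terms(self.x, self.y, spec, "additive", 1, self.alpha, weights)
        else:
            spec = _prune_terms(
                self.x,
                self.y,
                ModelSpec(additive=additive),
                "additive",
                1,
                self.alpha,
                weights,
                extra=scaffold,
            )
        return spec.additive

    def _pair_stage(
        self, use_w: bool, additive: tuple[int, ...], scaffold: np.ndarray | None
    ) -> tuple[tuple, int]:
        """Stage C: stepwise over pair products of the additive terms,
        Bonferroni-screened right away (with large scanned pools the AIC
        alone admits many spurious products, which would soak up genuine
        three-way signal before the triple stage runs)."""
        xt, yt, weights = self._transform(use_w)
        combos, cols = _candidate_products(self.x, additive, 2, self.cap)
        if use_w:
            cols = cols / np.sqrt(self.w)[:, None]
        base_cols = [self._intercept(use_w)]
        if additive:
            base_cols.append(xt[:, list(additive)])
        if scaffold is not None and scaffold.shape[1]:
            base_cols.append(scaffold / np.sqrt(self.w)[:, None] if use_w else scaffold)
        base = np.hstack(base_cols)
        sel = _stepwise(yt, base, cols, self.max_add) if combos else []
        pairs = tuple(combos[j] for j in sel)
        spec = _prune_terms(
            self.x,
            self.y,
            ModelSpec(additive=additive, pairs=pairs),
            "pairs",
            len(combos),
            self.alpha,
            weights,
            extra=scaffold,
        )
        return spec.pairs, len(combos)

    def _triple_stage(
        self, use_w: bool, additive: tuple[int, ...], pairs: tuple
    ) -> tuple[tuple, int]:
        """Stage D: stepwise over triple products of the additive terms."""
        xt, yt, _ = self._transform(use_w)
        combos, cols = _candidate_products(self.x, additive, 3, self.cap)
        if use_w:
            cols = cols / np.sqrt(self.w)[:, None]
        base_cols = [self._intercept(use_w)]
        if additive:
            base_cols.append(xt[:, list(additive)])
        if pairs:
            pair_cols = _interaction_columns(self.x, pairs)
            base_cols.append(pair_cols / np.sqrt(self.w)[:, None] if use_w else pair_cols)
        base = np.hstack(base_cols)
        sel = _stepwise(yt, base, cols, self.max_add) if combos else []
        return tuple(combos[j] for j in sel), len(combos)

    def marker_terms(self, use_w: bool) -> tuple[tuple[int, ...], tuple, int]:
        """Additive and pair terms after the refinement sweep.

        A first full pass (additive, pairs, triples) localizes the strong
        signals; the additive and pair stages are then re-run with the
        first-pass interaction columns locked into the base model.  Without
        the scaffolding, the additive scan must soak up three-way signal
        through markers correlated with the triple products, which drags
        selected markers away from the QTL positions and degrades the
        interaction candidate pools built from them.
        """
        if use_w in self._marker_cache:
            return self._marker_cache[use_w]
        a1 = self._additive_stage(use_w, None)
        p1, n_pair_cand = self._pair_stage(use_w, a1, None)
        t1, n_tri_cand = self._triple_stage(use_w, a1, p1)
        _, _, weights = self._transform(use_w)
        t1 = _prune_terms(
            self.x,
            self.y,
            ModelSpec(additive=a1, pairs=p1, triples=t1),
            "triples",
            n_tri_cand,
            self.alpha,
            weights,
        ).triples
        if t1:
            scaffold_t = self._scaffold_cols(t1)
            additive = self._additive_stage(use_w, scaffold_t, scaffold_terms=t1)
            pairs, n_pair_cand = self._pair_stage(use_w, additive, scaffold_t)
        else:
            additive, pairs = a1, p1
        out = (additive, pairs, n_pair_cand)
        self._marker_cache[use_w] = out
        return out

    def full_spec(self, weighting: str) -> ModelSpec:
        """All stages plus the final Bonferroni screen for one weighting scheme."""
        w_add, _w_pair, w_tri = _stage_weighting(weighting)
        additive, pairs, n_pair_cand = self.marker_terms(w_add)
        triples, n_tri_cand = self._triple_stage(w_tri, additive, pairs)
        _, _, weights = self._transform(w_tri)
        # Bonferroni screen on the joint model, each class at its own scan size
        spec = ModelSpec(additive=additive, pairs=pairs, triples=triples)
        spec = _prune_terms(self.x, self.y, spec, "triples", n_tri_cand, self.alpha, weights)
        spec = _prune_terms(self.x, self.y, spec, "pairs", n_pair_cand, self.alpha, weights)
        spec = _prune_terms(
            self.x, self.y, spec, "additive", self.x.shape[1], self.alpha, weights
        )
        return spec

    def final_fit(self, spec: ModelSpec, weighting: str) -> FitResult:
        weights = self.w if _stage_weighting(weighting)[2] else None
        return _fit_with_guard(self.x, self.y, spec, weights=weights)


def select_model(
    y,
    population: DHPopulation,
    gmap: GeneticMap | None = None,
    weighting: str = "none",
    alpha: float = 0.05,
    max_interaction_terms: int = 10_000,
    max_terms_per_stage: int = 30,
) -> ModelSpec:
    """Staged stepwise AIC selection of additive, pair and triple terms.

    ``weighting`` controls which stages fit in the weighted metric:
    ``"none"`` (all OLS), ``"final_stage"`` (triple stage and final fit WLS)
    or ``"all_stages"`` (everything WLS).  An empty specification is a valid
    outcome (no term survives selection and Bonferroni screening).
    """
    sel = _Selector(y, population, gmap, alpha, max_interaction_terms, max_terms_per_stage)
    return sel.full_spec(weighting)


def estimate_all(
    population: DHPopulation,
    gmap: GeneticMap | None = None,
    alpha: float = 0.05,
    methods: tuple[str, ...] = ("gu", "gw1", "gw2"),
    max_interaction_terms: int = 10_000,
    max_terms_per_stage: int = 30,
) -> dict[str, FitResult]:
    """Run the genotypic estimators, sharing the unweighted early stages.

    ``gu`` is the fully unweighted pipeline, ``gw1`` weights only the triple
    stage and the final joint fit (variant (i)) and ``gw2`` weights every
    stage (variant (ii)).  Returns the final joint fit per method.
    """
    sel = _Selector(
        population.line_means,
        population,
        gmap,
        alpha,
        max_interaction_terms,
        max_terms_per_stage,
    )
    mode = {"gu": "none", "gw1": "final_stage", "gw2": "all_stages"}
    out: dict[str, FitResult] = {}
    for name in methods:
        weighting = mode[name]
        spec = sel.full_spec(weighting)
        out[name] = sel.final_fit(spec, weighting)
    return out
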