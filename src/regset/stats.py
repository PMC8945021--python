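"""Probability models and the singular enrichment analysis (SEA) driver.

Two tests are provided for over-representation of an annotation term in an
input list drawn from a background of M elements:

* the central hypergeometric (Fisher exact) test — uniform sampling;
* the Wallenius noncentral hypergeometric test — biased sampling, where a
  term's elements are drawn with odds w against the rest. With counts
  x (input ∩ term), n (term size), N (input size), M (background) the pmf is

      p(x) = C(n,x) C(M−n, N−x) ∫₀¹ (1 − t^{w/D})^x (1 − t^{1/D})^{N−x} dt,
      D = w(n−x) + ((M−n) − (N−x)).

  The integral is evaluated by locating the peak of the (substituted)
  integrand on a dense grid and applying composite Gauss–Legendre panels
  over the region carrying non-negligible mass; at w = 1 the result reduces
  to the central pmf.

P-values are upper tails P(X ≥ x) (over-representation only, observed point
included) and are corrected per tested term set by Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom as _hypergeom
from statsmodels.stats.multitest import multipletests

from .bias import PwfFit, term_odds
from .data_model import AnnotationDatabase, Universe

__all__ = [
    "ContingencyCounts",
    "WalleniusParams",
    "EnrichmentRow",
    "hypergeom_pmf",
    "hypergeom_pvalue",
    "wallenius_pmf",
    "wallenius_pvalue",
    "bh_adjust",
    "relative_enrichment",
    "run_sea",
    "PVALUE_FLOOR",
]

PVALUE_FLOOR = 1e-300


@dataclass(frozen=True)
class ContingencyCounts:
    """The (x, n, N, M) of one term's 2×2 table.

    x — input elements in the term; n — term size in the background;
    N — input size in the background; M — background size.
    """

    x: int
    n: int
    N: int
    M: int

    def __post_init__(self) -> None:
        if not (0 <= self.n <= self.M and 0 <= self.N <= self.M):
            raise ValueError(f"invalid counts: n={self.n}, N={self.N}, M={self.M}")
        if not (max(0, self.N - (self.M - self.n)) <= self.x <= min(self.n, self.N)):
            raise ValueError(f"x={self.x} outside support for n={self.n}, N={self.N}, M={self.M}")

    @property
    def support(self) -> range:
        return range(max(0, self.N - (self.M - self.n)), min(self.n, self.N) + 1)


@dataclass(frozen=True)
class WalleniusParams:
    counts: ContingencyCounts
    w: float

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("w must be positive")

    @property
    def D(self) -> float:
        c = self.counts
        return self.w * (c.n - c.x) + ((c.M - c.n) - (c.N - c.x))


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    source: str
    counts: ContingencyCounts
    w: Optional[float]
    pvalue: float
    padj: float
    rel_enrichment: float
    support: frozenset[str]
    input_elements: frozenset[str]


# ---------------------------------------------------------------------------
# central hypergeometric


def hypergeom_pmf(c: ContingencyCounts) -> float:
    """P(X = x) under uniform sampling without replacement."""
    return float(_hypergeom.pmf(c.x, c.M, c.n, c.N))


def hypergeom_pvalue(c: ContingencyCounts) -> float:
    """Upper tail P(X >= x), the one-sided over-representation test."""
    return float(min(1.0, _hypergeom.sf(c.x - 1, c.M, c.n, c.N)))


# ---------------------------------------------------------------------------
# Wallenius noncentral hypergeometric

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)
_N_PANELS = 12


def _log1mexp(a: np.ndarray) -> np.ndarray:
    """log(1 - exp(a)) for a <= 0, stable at both ends."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    small = a > -0.6931471805599453  # -log 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out[small] = np.log(-np.expm1(a[small]))
        out[~small] = np.log1p(-np.exp(a[~small]))
    return out


def _log_integrate_unit_interval(log_f) -> float:
    """log ∫₀¹ exp(log_f(u)) du for a continuous integrand that is
    non-negligible only on one contiguous region of (0,1).

    A dense scouting grid locates the region where log_f is within 46 nats
    of its maximum (outside it the integrand is < 1e-20 of the peak); the
    region is then covered by composite Gauss–Legendre panels. Working on
    the log scale keeps extreme tails (integrals ~1e-300) representable.
    """
    eps = 1e-15
    grid = np.unique(np.concatenate([
        np.linspace(eps, 1.0 - eps, 201),
        np.geomspace(1e-13, 0.5, 60),
        1.0 - np.geomspace(1e-13, 0.5, 60),
    ]))
    h = log_f(grid)
    h[~np.isfinite(h)] = -np.inf
    imax = int(np.argmax(h))
    hmax = h[imax]
    if not np.isfinite(hmax):
        return -np.inf
    keep = h >= hmax - 46.0
    ilo = imax
    while ilo > 0 and keep[ilo - 1]:
        ilo -= 1
    ihi = imax
    while ihi < len(grid) - 1 and keep[ihi + 1]:
        ihi += 1
    lo = grid[max(ilo - 1, 0)] if ilo > 0 else 0.0
    hi = grid[min(ihi + 1, len(grid) - 1)] if ihi < len(grid) - 1 else 1.0
    edges = np.linspace(lo, hi, _N_PANELS + 1)
    mid = 0.5 * (edges[1:] + edges[:-1])
    half = 0.5 * (edges[1:] - edges[:-1])
    pts = (mid[:, None] + half[:, None] * _GL_NODES[None, :]).ravel()
    vals = np.exp(log_f(pts) - hmax)
    vals[~np.isfinite(vals)] = 0.0
    wts = (half[:, None] * _GL_WEIGHTS[None, :]).ravel()
    total = float(np.dot(wts, vals))
    if total <= 0.0:
        return -np.inf
    return float(hmax + np.log(total))


def _wallenius_log_integral(x: int, N: int, w: float, D: float) -> float:
    """log ∫₀¹ (1−t^{w/D})^x (1−t^{1/D})^{N−x} dt.

    The substitution t = s^c with c = max(1, D, D/w) turns every exponent
    (the Jacobian's c−1 and the two inner powers wc/D, c/D) into a value
    ≥ 1, removing the fractional-power cusps at the endpoints that defeat
    polynomial quadrature; the transformed integrand is bounded and
    unimodal.
    """
    y = N - x
    c_sub = max(1.0, D, D / w)
    a = w * c_sub / D  # >= 1
    b = c_sub / D      # >= 1
    log_c = np.log(c_sub)

    def log_f(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ls = np.log(s)
            out = log_c + (c_sub - 1.0) * ls
            if x > 0:
                out = out + x * _log1mexp(a * ls)
            if y > 0:
                out = out + y * _log1mexp(b * ls)
        return out

    return _log_integrate_unit_interval(log_f)


def wallenius_pmf(params: WalleniusParams) -> float:
    """P(X = x) when in-term elements are drawn with odds w."""
    c = params.counts
    lo, hi = max(0, c.N - (c.M - c.n)), min(c.n, c.N)
    if not (lo <= c.x <= hi):
        return 0.0
    if lo == hi:
        return 1.0
    D = params.D
    if D <= 0:
        raise ArithmeticError(f"D={D} <= 0 at a non-degenerate outcome (x={c.x})")
    log_binom = (
        gammaln(c.n + 1) - gammaln(c.x + 1) - gammaln(c.n - c.x + 1)
        + gammaln(c.M - c.n + 1) - gammaln(c.N - c.x + 1) - gammaln(c.M - c.n - (c.N - c.x) + 1)
    )
    log_integral = _wallenius_log_integral(c.x, c.N, params.w, D)
    if not np.isfinite(log_integral):
        return 0.0
    return float(min(1.0, np.exp(log_binom + log_integral)))


def wallenius_pmf_counts(x: int, c: ContingencyCounts, w: float) -> float:
    """pmf at an arbitrary outcome x for the same urn (helper for tails)."""
    lo, hi = max(0, c.N - (c.M - c.n)), min(c.n, c.N)
    if not (lo <= x <= hi):
        return 0.0
    return wallenius_pmf(WalleniusParams(counts=replace(c, x=x), w=w))


def wallenius_pvalue(c: ContingencyCounts, w: float) -> float:
    """Upper tail P(X >= x); each outcome uses its own D."""
    hi = min(c.n, c.N)
    total = 0.0
    for k in range(c.x, hi + 1):
        pk = wallenius_pmf_counts(k, c, w)
        total += pk
        # outcomes beyond the mode decay fast; stop once negligible
        if k > c.x and pk < 1e-18 and pk < 1e-12 * max(total, 1e-300):
            break
    return float(min(1.0, max(0.0, total)))


# ---------------------------------------------------------------------------
# multiplicity, score, driver


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return [float(q) for q in padj]


def relative_enrichment(c: ContingencyCounts, n_db: int, M_db: int) -> float:
    """(x/N) / (n_db/M_db): input fraction in the term over the database
    fraction in the term; > 1 means over-representation."""
    if c.N <= 0 or n_db <= 0 or M_db <= 0:
        raise ValueError("relative enrichment requires positive N, n_db and M_db")
    return (c.x / c.N) / (n_db / M_db)


def run_sea(
    input_elements: frozenset[str] | set[str],
    db: AnnotationDatabase,
    universe: Universe,
    method: str = "hypergeom",
    pwf: Optional[PwfFit] = None,
    odds_mode: str = "ratio-of-means",
    input_provenance: Optional[Mapping[str, frozenset[str]]] = None,
) -> list[EnrichmentRow]:
    """Singular enrichment analysis of one database.

    Every term with n ≥ 1 and x ≥ 1 after universe intersection is tested;
    the FDR multiplicity is the number of tested terms. Rows come back
    sorted by (padj, pvalue, term_id).

    ``input_provenance`` optionally maps a tested element to the original
    input IDs it derives from (e.g. target gene → contributing miRNAs),
    used to fill the input_elements column.
    """
    if method not in ("hypergeom", "wallenius"):
        raise ValueError(f"unknown method {method!r}")
    if method == "wallenius" and pwf is None:
        raise ValueError("method='wallenius' requires a fitted PWF")
    tested_input = frozenset(input_elements) & universe.elements
    if not tested_input:
        raise ValueError("input has no elements in the background")
    N, M = len(tested_input), universe.M
    db_universe_size = len(db.annotated_universe())

    rows: list[EnrichmentRow] = []
    for tid in sorted(db.terms):
        name, full_elems = db.terms[tid]
        elems = full_elems & universe.elements
        n = len(elems)
        if n == 0:
            continue
        support = tested_input & elems
        x = len(support)
        if x == 0:
            continue
        counts = ContingencyCounts(x=x, n=n, N=N, M=M)
        if method == "wallenius":
            w: Optional[float] = term_odds(pwf, elems, universe.elements, mode=odds_mode)
            pval = wallenius_pvalue(counts, w)
        else:
            w = None
            pval = hypergeom_pvalue(counts)
        pval = max(pval, PVALUE_FLOOR)
        if input_provenance is not None:
            origin: set[str] = set()
            for g in support:
                origin |= input_provenance.get(g, frozenset({g}))
            input_elems = frozenset(origin)
        else:
            input_elems = frozenset(support)
        rows.append(EnrichmentRow(
            term_id=tid,
            term_name=name,
            source=db.source_name,
            counts=counts,
            w=w,
            pvalue=pval,
            padj=1.0,  # filled below
            rel_enrichment=relative_enrichment(counts, len(full_elems), db_universe_size),
            support=frozenset(support),
            input_elements=input_elems,
        ))
    if not rows:
        raise ValueError("no testable terms (every term has x = 0 or n = 0)")
    padj = bh_adjust([r.pvalue for r in rows])
    rows = [replace(r, padj=max(q, r.pvalue)) for r, q in zip(rows, padj)]
    rows.sort(key=lambda r: (r.padj, r.pvalue, r.term_id))
    return rows
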