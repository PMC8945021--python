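"""Selection-bias model: the probability weighting function (PWF) and the
per-term odds w that parameterise the Wallenius test.

Target-gene lists of miRNAs/TFs/CpGs are not uniform samples of the genome:
a gene targeted by many regulators (or carrying many methylation probes, or
simply long) is more likely to enter the list. The PWF quantifies that by
fitting a monotone logistic curve to the binary in-list indicator against
the bias covariate; each gene receives a selection probability in (0,1).
A term's odds w is the mean selection probability of its genes divided by
the mean over the rest of the background (optionally an odds ratio of the
two means).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.isotonic import IsotonicRegression

from .data_model import GeneCovariateTable, Interactome

__all__ = ["PwfFit", "bias_covariate", "fit_pwf", "term_odds"]

WEIGHT_EPS = 1e-6  # weights clamped to [eps, 1-eps]
ODDS_CLAMP = (1e-3, 1e3)


@dataclass(frozen=True)
class PwfFit:
    """Fitted probability weighting function.

    ``weight`` maps every fitted gene to its selection probability, strictly
    inside (0,1) and nondecreasing in the covariate.
    """

    covariate: Mapping[str, float]
    weight: Mapping[str, float]
    fit_meta: dict

    def __post_init__(self) -> None:
        for g, w in self.weight.items():
            if not (0.0 < w < 1.0):
                raise ValueError(f"weight for {g!r} outside (0,1): {w}")


def bias_covariate(
    universe: frozenset[str] | set[str],
    source: Union[GeneCovariateTable, Interactome],
) -> GeneCovariateTable:
    """Build the per-gene bias covariate for every gene of the universe.

    A gene-length table is used as-is; an interactome (miRNA–gene, TF–gene
    or CpG–gene) contributes the number of distinct regulators/probes per
    gene. Genes absent from the source get 0.
    """
    if isinstance(source, Interactome):
        counts = source.regulator_count()
        name = f"{source.kind}_per_gene"
        values = {g: float(counts.get(g, 0)) for g in universe}
    else:
        name = source.name
        values = {g: source.get(g) for g in universe}
    return GeneCovariateTable(values=values, name=name)


def _ispline_design(x: np.ndarray, knots_x: np.ndarray, basis_size: int, degree: int = 3) -> np.ndarray:
    """Monotone design matrix: intercept + cumulative ('integrated') cubic
    B-spline columns, each nondecreasing in x. Nonnegative coefficients on
    the non-intercept columns then guarantee a nondecreasing predictor."""
    lo, hi = knots_x.min(), knots_x.max()
    n_interior = max(basis_size - degree - 1, 0)
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(knots_x, qs)
        interior = interior[(interior > lo) & (interior < hi)]
    else:
        interior = np.array([])
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    xc = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xc, t, degree).toarray()
    # reversed cumulative sum over basis functions: column j = sum_{k>=j} B_k,
    # nondecreasing because clamped B-splines are a partition of unity
    C = np.cumsum(B[:, ::-1], axis=1)[:, ::-1]
    # C[:,0] == 1 everywhere -> acts as intercept; keep it as such
    return C


def _fit_monotone_logistic(x: np.ndarray, y: np.ndarray, basis_size: int) -> tuple[np.ndarray, dict]:
    """Constrained-spline logistic fit; returns fitted probabilities at x."""
    X = _ispline_design(x, np.unique(x), basis_size)
    m = X.shape[1]
    ridge = 1e-6

    def nll(theta: np.ndarray) -> tuple[float, np.ndarray]:
        eta = X @ theta
        # log(1+e^eta) - y*eta, numerically stable
        val = np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * ridge * theta @ theta
        grad = X.T @ (expit(eta) - y) + ridge * theta
        return val, grad

    theta0 = np.zeros(m)
    theta0[0] = np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
    bounds = [(None, None)] + [(0.0, None)] * (m - 1)
    res = minimize(nll, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12})
    p = expit(X @ res.x)
    meta = {
        "method": "monotone-spline-logistic",
        "basis_size": basis_size,
        "monotone_constraint": True,
        "converged": bool(res.success),
        "deviance": float(2.0 * (np.sum(np.logaddexp(0.0, X @ res.x) - y * (X @ res.x)))),
    }
    return p, meta


def fit_pwf(
    membership: Mapping[str, int],
    covariate: GeneCovariateTable,
    basis_size: int = 6,
) -> PwfFit:
    """Fit the PWF on a binary series (1 = gene is in the input / is a
    target of the input) against the bias covariate.

    Degenerate covariates (fewer than 3 distinct values) fall back to the
    constant weight mean(membership). A failed constrained fit falls back
    to isotonic regression on the binary series.
    """
    genes = sorted(membership)
    if len(genes) < 10:
        raise ValueError("need at least 10 genes to fit a selection probability")
    y = np.array([float(membership[g]) for g in genes])
    classes = set(np.unique(y))
    if classes != {0.0, 1.0}:
        raise ValueError("cannot fit selection probability: membership has a single class")
    x = np.array([covariate.get(g) for g in genes])
    cov_map = {g: float(v) for g, v in zip(genes, x)}

    if len(np.unique(x)) < 3:
        w = float(np.clip(y.mean(), WEIGHT_EPS, 1 - WEIGHT_EPS))
        return PwfFit(
            covariate=cov_map,
            weight={g: w for g in genes},
            fit_meta={"method": "constant", "basis_size": 0, "monotone_constraint": True,
                      "deviance": float(2 * len(y) * (np.logaddexp(0, np.log(w / (1 - w))) - y.mean() * np.log(w / (1 - w))))},
        )

    try:
        p, meta = _fit_monotone_logistic(x, y, basis_size)
        if not np.all(np.isfinite(p)):
            raise FloatingPointError("non-finite fitted probabilities")
    except Exception:
        # isotonic fallback: same contract (monotone, bounded)
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        p = iso.fit_transform(x, y)
        # light smoothing: average isotonic step values over a small window in rank space
        order = np.argsort(x, kind="stable")
        ps = p[order]
        k = max(1, len(ps) // 50)
        kernel = np.ones(2 * k + 1) / (2 * k + 1)
        sm = np.convolve(np.r_[[ps[0]] * k, ps, [ps[-1]] * k], kernel, mode="valid")
        sm = np.maximum.accumulate(sm)  # keep monotone after smoothing
        p = np.empty_like(ps)
        p[order] = sm
        meta = {"method": "isotonic-fallback", "basis_size": 0, "monotone_constraint": True,
                "deviance": float("nan")}

    p = np.clip(p, WEIGHT_EPS, 1 - WEIGHT_EPS)
    # equal covariate values must get equal weights
    weight: dict[str, float] = {}
    by_value: dict[float, list[int]] = {}
    for i, g in enumerate(genes):
        by_value.setdefault(float(x[i]), []).append(i)
    for val, idxs in by_value.items():
        wv = float(np.mean(p[idxs]))
        for i in idxs:
            weight[genes[i]] = wv
    return PwfFit(covariate=cov_map, weight=weight, fit_meta=meta)


def term_odds(
    pwf: PwfFit,
    term_genes: frozenset[str] | set[str],
    background: frozenset[str] | set[str],
    mode: str = "ratio-of-means",
) -> float:
    """Per-term odds w: the average selection weight of the term's genes in
    the background divided by the average over the background genes outside
    the term. ``mode='odds-of-means'`` instead forms the odds ratio
    (p̄_in/(1−p̄_in)) / (p̄_out/(1−p̄_out)).

    Clamped to [1e-3, 1e3]; w = 1 when the two means coincide.
    """
    inside = term_genes & set(background)
    outside = set(background) - set(term_genes)
    if not inside:
        raise ValueError("term has no genes in the background")
    if not outside:
        raise ValueError("term equals the background; untestable")
    # sorted iteration keeps the summation order (and hence the float
    # result) identical across processes
    p_in = float(np.mean([pwf.weight[g] for g in sorted(inside)]))
    p_out = float(np.mean([pwf.weight[g] for g in sorted(outside)]))
    if mode == "ratio-of-means":
        w = p_in / p_out
    elif mode == "odds-of-means":
        w = (p_in / (1 - p_in)) / (p_out / (1 - p_out))
    else:
        raise ValueError(f"unknown odds mode {mode!r}")
    return float(np.clip(w, *ODDS_CLAMP))
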