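"""Penalized least squares with REML smoothing-parameter selection.

This is the numerical core under the trend and land-use models: a design
matrix assembled from blocks (unpenalized fixed effects, difference-
penalized B-spline smooths, ridge-penalized random intercepts), with one
smoothing parameter per penalized block chosen by restricted maximum
likelihood for the Gaussian working model.

The REML criterion (constants dropped, scale profiled out) is

    (n - Mp) * log(rss + penalty) + log|X'WX + S| - sum_j rank_j * log(lam_j)

where Mp is the total dimension of the unpenalized space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import interpolate, linalg, optimize, stats


def bspline_basis(
    x: np.ndarray, k: int, domain: Optional[Tuple[float, float]] = None, degree: int = 3
) -> Tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline basis with ``k`` functions over ``domain``.

    Returns (basis matrix n x k, knot vector). Evaluation outside the
    domain extrapolates linearly from the boundary.
    """
    x = np.asarray(x, dtype=float)
    if domain is None:
        domain = (float(x.min()), float(x.max()))
    lo, hi = domain
    if hi <= lo:
        hi = lo + 1.0
    n_interior = k - degree - 1
    if n_interior < 0:
        raise ValueError(f"k={k} too small for degree {degree}")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])

    inside = np.clip(x, lo, hi)
    B = interpolate.BSpline.design_matrix(inside, t, degree).toarray()
    # linear extrapolation beyond the boundary knots
    out_lo = x < lo
    out_hi = x > hi
    if out_lo.any() or out_hi.any():
        eps = (hi - lo) * 1e-6
        for mask, x0 in ((out_lo, lo), (out_hi, hi)):
            if not mask.any():
                continue
            b0 = interpolate.BSpline.design_matrix(np.array([x0]), t, degree).toarray()[0]
            b1 = interpolate.BSpline.design_matrix(
                np.array([x0 + (eps if x0 == lo else -eps)]), t, degree
            ).toarray()[0]
            slope = (b1 - b0) / (eps if x0 == lo else -eps)
            B[mask] = b0 + np.outer(x[mask] - x0, slope)
    return B, t


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    """order-th difference penalty matrix D'D (rank k - order)."""
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def centering_transform(B: np.ndarray) -> np.ndarray:
    """Null-space basis Z of the column-mean constraint (k x (k-1)).

    Using B @ Z constrains the smooth to sum to zero over the observed
    rows, removing confounding with intercept terms.
    """
    c = B.mean(axis=0, keepdims=True)
    Z = linalg.null_space(c)
    return Z


@dataclass
class Block:
    """One design block: columns of X plus an optional penalty matrix."""

    name: str
    X: np.ndarray
    S: Optional[np.ndarray] = None  # penalty in the block's own coordinates
    rank: Optional[int] = None  # penalty rank; inferred when None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.S is not None:
            self.S = np.asarray(self.S, dtype=float)
            if self.rank is None:
                self.rank = int(np.linalg.matrix_rank(self.S))


@dataclass
class PenalizedFit:
    blocks: List[Block]
    slices: List[slice]
    beta: np.ndarray
    lambdas: np.ndarray  # one per penalized block, in block order
    edf_by_block: dict
    edf_total: float
    rss: float
    penalty: float
    sigma2: float
    loglik: float
    aic: float
    reml: float
    Vp: np.ndarray
    n: int
    y: np.ndarray = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)

    def coef(self, name: str) -> np.ndarray:
        for b, sl in zip(self.blocks, self.slices):
            if b.name == name:
                return self.beta[sl]
        raise KeyError(name)

    def cov(self, name: str) -> np.ndarray:
        for b, sl in zip(self.blocks, self.slices):
            if b.name == name:
                return self.Vp[sl, sl]
        raise KeyError(name)

    def lam(self, name: str) -> float:
        j = 0
        for b in self.blocks:
            if b.S is not None:
                if b.name == name:
                    return float(self.lambdas[j])
                j += 1
        raise KeyError(name)


def _assemble(blocks: Sequence[Block]):
    slices = []
    start = 0
    for b in blocks:
        p = b.X.shape[1]
        slices.append(slice(start, start + p))
        start += p
    X = np.hstack([b.X for b in blocks])
    return X, slices, start


def fit_reml(
    y: np.ndarray,
    blocks: Sequence[Block],
    weights: Optional[np.ndarray] = None,
    log_lambda_bounds: Tuple[float, float] = (-25.0, 25.0),
    x0: Optional[np.ndarray] = None,
) -> PenalizedFit:
    """Fit a penalized Gaussian model, selecting lambdas by REML."""
    y = np.asarray(y, dtype=float)
    X, slices, p = _assemble(blocks)
    n = len(y)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        Xw = X * w[:, None]
        yw = y * w
    else:
        Xw, yw = X, y
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    yty = float(yw @ yw)

    pen_idx = [j for j, b in enumerate(blocks) if b.S is not None]
    S_embed = []
    ranks = []
    for j in pen_idx:
        S_full = np.zeros((p, p))
        sl = slices[j]
        S_full[sl, sl] = blocks[j].S
        S_embed.append(S_full)
        ranks.append(blocks[j].rank)
    Mp = p - sum(ranks)

    def _solve(loglam):
        loglam = np.clip(loglam, *log_lambda_bounds)
        S = sum(
            np.exp(ll) * Sj for ll, Sj in zip(np.atleast_1d(loglam), S_embed)
        ) if S_embed else np.zeros((p, p))
        A = XtX + S
        jitter = 1e-10 * max(np.trace(XtX) / max(p, 1), 1.0)
        for _ in range(6):
            try:
                L = linalg.cholesky(A + jitter * np.eye(p), lower=True)
                break
            except linalg.LinAlgError:
                jitter *= 100
        else:  # pragma: no cover
            raise np.linalg.LinAlgError("normal equations not positive definite")
        beta = linalg.cho_solve((L, True), Xty)
        rss = max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 1e-300)
        penalty = float(beta @ S @ beta) if S_embed else 0.0
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        return loglam, L, beta, rss, penalty, logdet

    def score(loglam):
        loglam, L, beta, rss, penalty, logdet = _solve(loglam)
        r = (n - Mp) * np.log(rss + penalty) + logdet
        r -= sum(rk * ll for rk, ll in zip(ranks, np.atleast_1d(loglam)))
        return r

    if S_embed:
        d = len(S_embed)
        if x0 is None:
            x0 = np.zeros(d)
        res = optimize.minimize(
            score,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-5, "maxiter": 300 * d,
                     "maxfev": 300 * d},
        )
        loglam_opt = np.clip(res.x, *log_lambda_bounds)
        reml = float(res.fun)
    else:
        loglam_opt = np.zeros(0)
        reml = float(score(np.zeros(0)))

    loglam_opt, L, beta, rss, penalty, logdet = _solve(loglam_opt)
    Ainv = linalg.cho_solve((L, True), np.eye(p))
    F = Ainv @ XtX
    edf_diag = np.diag(F)
    edf_by_block = {
        b.name: float(edf_diag[sl].sum()) for b, sl in zip(blocks, slices)
    }
    edf_total = float(edf_diag.sum())
    sigma2 = rss / max(n - edf_total, 1.0)
    sigma2_ml = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    aic = -2.0 * loglik + 2.0 * (edf_total + 1.0)
    Vp = Ainv * sigma2
    return PenalizedFit(
        blocks=list(blocks),
        slices=slices,
        beta=beta,
        lambdas=np.exp(loglam_opt),
        edf_by_block=edf_by_block,
        edf_total=edf_total,
        rss=float(rss),
        penalty=float(penalty),
        sigma2=float(sigma2),
        loglik=float(loglik),
        aic=float(aic),
        reml=reml,
        Vp=Vp,
        n=n,
        y=y,
        X=X,
    )


def smooth_wald_test(fit: PenalizedFit, name: str) -> Tuple[float, float, float]:
    """Wald-type test of a penalized smooth: (statistic, edf-rank, p-value).

    Uses the Bayesian covariance restricted to the block, with rank set by
    the block's effective degrees of freedom (floor 1).
    """
    b = fit.coef(name)
    V = fit.cov(name)
    edf = max(fit.edf_by_block[name], 1.0)
    r = int(min(max(round(edf), 1), len(b)))
    vals, vecs = linalg.eigh(V)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order[:r]], vecs[:, order[:r]]
    vals = np.maximum(vals, 1e-12)
    z = vecs.T @ b
    stat = float(np.sum(z**2 / vals))
    p = float(stats.chi2.sf(stat, df=r))
    return stat, float(r), p


def scaled_t_irls(
    y: np.ndarray,
    blocks: Sequence[Block],
    df_grid: Sequence[float] = (3, 4, 5, 8, 12, 20),
    max_iter: int = 15,
) -> Tuple[PenalizedFit, float, float]:
    """Scaled-t family via iteratively reweighted REML fits.

    The t degrees of freedom are chosen by profile likelihood over
    ``df_grid``. Returns (fit at the best df, df, scale).
    """
    best = None
    for nu in df_grid:
        fit = fit_reml(y, blocks)
        scale = np.sqrt(max(fit.rss / fit.n, 1e-12))
        for _ in range(max_iter):
            resid = y - fit.X @ fit.beta
            w = (nu + 1.0) / (nu + (resid / scale) ** 2)
            fit = fit_reml(y, blocks, weights=w)
            resid = y - fit.X @ fit.beta
            scale_new = np.sqrt(max(np.mean(w * resid**2), 1e-12))
            if abs(scale_new - scale) < 1e-8 * scale:
                scale = scale_new
                break
            scale = scale_new
        resid = y - fit.X @ fit.beta
        ll = float(np.sum(stats.t.logpdf(resid / scale, df=nu) - np.log(scale)))
        if best is None or ll > best[0]:
            best = (ll, fit, nu, scale)
    _, fit, nu, scale = best
    fit.loglik = best[0]
    fit.aic = -2.0 * best[0] + 2.0 * (fit.edf_total + 2.0)
    return fit, float(nu), float(scale)
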