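"""Small Newton solvers for the ordinary regressions used by the CI tests.

Multinomial logistic regression is fit with a damped full-Hessian Newton
iteration on the reference-level parameterization; linear models go through
ordinary least squares.  These exist in-package because the independence
tests call them tens of thousands of times inside constraint-based search,
where per-call overhead dominates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_multinomial", "ols_loglik", "MultinomialFit"]


class MultinomialFit:
    __slots__ = ("coef", "loglik", "n_iter", "converged")

    def __init__(self, coef, loglik, n_iter, converged):
        self.coef = coef
        self.loglik = loglik
        self.n_iter = n_iter
        self.converged = converged


def _softmax_ref(eta_free: np.ndarray) -> np.ndarray:
    """Probabilities with an implicit zero score for the reference level."""
    n, Lm1 = eta_free.shape
    scores = np.concatenate([np.zeros((n, 1)), eta_free], axis=1)
    scores -= scores.max(axis=1, keepdims=True)
    ex = np.exp(scores)
    return ex / ex.sum(axis=1, keepdims=True)


def fit_multinomial(
    X: np.ndarray,
    y: np.ndarray,
    n_levels: int,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 1e-8,
) -> MultinomialFit:
    """Fit P(y = l | x) by maximum likelihood, reference level 0.

    ``X`` should include an intercept column if one is wanted.  ``ridge``
    is a tiny curvature floor that keeps quasi-separated designs solvable;
    it is not a tuned regularizer.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=np.int64)
    n, k = X.shape
    L = n_levels
    if L < 2:
        raise ValueError("multinomial fit needs >= 2 levels")
    Y = np.zeros((n, L))
    Y[np.arange(n), y] = 1.0

    B = np.zeros((L - 1, k))

    def _loglik(Bc):
        P = _softmax_ref(X @ Bc.T)
        return float(np.log(np.clip(P[np.arange(n), y], 1e-300, None)).sum()), P

    ll, P = _loglik(B)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        E = Y[:, 1:] - P[:, 1:]                       # (n, L-1)
        grad = E.T @ X                                 # (L-1, k)
        Pf = P[:, 1:]
        # block Hessian H[l, m] = X' diag(p_l (delta_lm - p_m)) X via BLAS
        H = np.empty(((L - 1) * k, (L - 1) * k))
        for l in range(L - 1):
            for m in range(l, L - 1):
                w = Pf[:, l] * ((l == m) - Pf[:, m])
                blk = X.T @ (w[:, None] * X)
                H[l * k:(l + 1) * k, m * k:(m + 1) * k] = blk
                if m != l:
                    H[m * k:(m + 1) * k, l * k:(l + 1) * k] = blk
        H += ridge * np.eye((L - 1) * k)
        try:
            step = np.linalg.solve(H, grad.reshape(-1)).reshape(L - 1, k)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular design in multinomial fit") from exc
        scale = 1.0
        for _ in range(30):
            cand = B + scale * step
            ll_new, P_new = _loglik(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise RuntimeError("multinomial Newton step-halving exhausted")
        B = B + scale * step
        P = P_new
        if abs(ll_new - ll) <= tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return MultinomialFit(B, ll, it, converged)


def ols_loglik(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """OLS fit returning (coef, rss, gaussian profile log-likelihood)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("singular design in linear model")
    resid = y - X @ coef
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return coef, rss, ll
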