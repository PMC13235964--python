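"""Cox proportional-hazards partial likelihood machinery.

Everything here works on right-censored pairs ``(times, events)`` and a
linear predictor ``eta``.  Tied event times are handled with Efron's
correction by default; Breslow's approximation is available because the
null-model Martingale residual identity (residuals sum to zero, and the
diagonal working product ``W z`` at ``eta = 0`` equals the residuals) holds
exactly under Breslow.

All computations are vectorized over samples and over tied-event groups so
that the structure-learning loops above this module stay fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoxWorkingSet",
    "cox_loglik_eta",
    "cox_working_quantities",
    "martingale_residuals",
    "nelson_aalen",
    "cox_newton",
    "CoxFit",
]

EFRON = "efron"
BRESLOW = "breslow"


def _check_surv(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be 1-d arrays of equal length")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("non-binary event indicator")
    if events.sum() == 0:
        raise ValueError("zero observed events: Cox partial likelihood is degenerate")
    return times, events.astype(np.int64)


@dataclass
class _SurvIndex:
    """Sort order and tied-event-group bookkeeping, reusable across iterations."""

    order: np.ndarray          # ascending time order
    t_sorted: np.ndarray
    e_sorted: np.ndarray
    group_times: np.ndarray    # unique event times, ascending
    group_start: np.ndarray    # index in sorted arrays of first sample with t >= group time
    d: np.ndarray              # tied event count per group
    l_group: np.ndarray        # flat Efron terms: group index per term
    l_frac: np.ndarray         # flat Efron terms: l/d per term (zeros under Breslow)
    event_group_of: np.ndarray  # per sorted sample: group idx of its event time, -1 if censored
    cum_idx: np.ndarray        # per sorted sample: number of groups with t_g <= t_i


def _index(times: np.ndarray, events: np.ndarray, ties: str) -> _SurvIndex:
    order = np.lexsort((1 - events, times))  # time asc; events before censored at ties (cosmetic)
    t = times[order]
    e = events[order]
    ev_times = t[e == 1]
    group_times, d = np.unique(ev_times, return_counts=True)
    group_start = np.searchsorted(t, group_times, side="left")
    if ties == EFRON:
        l_group = np.repeat(np.arange(group_times.size), d)
        starts = np.concatenate(([0], np.cumsum(d)[:-1]))
        l_within = np.arange(int(d.sum())) - np.repeat(starts, d)
        l_frac = l_within / np.repeat(d, d)
    elif ties == BRESLOW:
        l_group = np.repeat(np.arange(group_times.size), d)
        l_frac = np.zeros(l_group.size)
    else:
        raise ValueError(f"unknown tie handling {ties!r}")
    ev_grp = np.searchsorted(group_times, t)
    event_group_of = np.where(e == 1, ev_grp, -1)
    cum_idx = np.searchsorted(group_times, t, side="right")
    return _SurvIndex(order, t, e, group_times, group_start, d, l_group, l_frac,
                      event_group_of, cum_idx)


def _suffix_sum(x: np.ndarray) -> np.ndarray:
    return np.cumsum(x[::-1], axis=0)[::-1]


_INDEX_CACHE: dict = {}


def _index_cached(times: np.ndarray, events: np.ndarray, ties: str) -> _SurvIndex:
    key = (times.tobytes(), events.tobytes(), ties)
    idx = _INDEX_CACHE.get(key)
    if idx is None:
        idx = _index(times, events, ties)
        if len(_INDEX_CACHE) >= 64:
            _INDEX_CACHE.pop(next(iter(_INDEX_CACHE)))
        _INDEX_CACHE[key] = idx
    return idx


def _loglik_sorted(idx: _SurvIndex, eta_sorted: np.ndarray) -> float:
    """Partial log-likelihood only (line-search path)."""
    w = np.exp(eta_sorted)
    S_R = _suffix_sum(w)[idx.group_start]
    ev = idx.e_sorted == 1
    G = idx.group_times.size
    S_D = np.bincount(idx.event_group_of[ev], weights=w[ev], minlength=G)
    phi = S_R[idx.l_group] - idx.l_frac * S_D[idx.l_group]
    return float(eta_sorted[ev].sum() - np.log(phi).sum())


def _group_scalars(idx: _SurvIndex, w_sorted: np.ndarray):
    """Per-group Efron denominators and their reciprocal-power partial sums."""
    S_R = _suffix_sum(w_sorted)[idx.group_start]
    ev = idx.e_sorted == 1
    G = idx.group_times.size
    # sum of w over the tied event set of each group
    S_D = np.bincount(idx.event_group_of[ev], weights=w_sorted[ev], minlength=G)
    phi = S_R[idx.l_group] - idx.l_frac * S_D[idx.l_group]
    inv = 1.0 / phi
    inv2 = inv * inv
    s0 = np.bincount(idx.l_group, weights=inv, minlength=G)
    s1 = np.bincount(idx.l_group, weights=idx.l_frac * inv, minlength=G)
    t0 = np.bincount(idx.l_group, weights=inv2, minlength=G)
    t1 = np.bincount(idx.l_group, weights=idx.l_frac * inv2, minlength=G)
    t2 = np.bincount(idx.l_group, weights=idx.l_frac**2 * inv2, minlength=G)
    logphi = np.bincount(idx.l_group, weights=np.log(phi), minlength=G)
    return S_R, S_D, s0, s1, t0, t1, t2, logphi


def cox_loglik_eta(times, events, eta, ties: str = EFRON):
    """Partial log-likelihood and its first two derivatives in ``eta``.

    Returns ``(loglik, grad, hess_diag)`` where ``grad`` and ``hess_diag``
    are the gradient and the diagonal of the Hessian of the *positive*
    partial log-likelihood with respect to the per-sample linear predictor.
    """
    times, events = _check_surv(times, events)
    eta = np.asarray(eta, dtype=float)
    if eta.shape != times.shape:
        raise ValueError("eta must match times in length")
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    idx = _index_cached(times, events, ties)
    w = np.exp(eta[idx.order])
    _, _, s0, s1, t0, t1, t2, logphi = _group_scalars(idx, w)

    loglik = float(eta[idx.order][idx.e_sorted == 1].sum() - logphi.sum())

    C1 = np.concatenate(([0.0], np.cumsum(s0)))[idx.cum_idx]
    C2 = np.concatenate(([0.0], np.cumsum(t0)))[idx.cum_idx]
    is_ev = idx.e_sorted == 1
    h1 = np.where(is_ev, s1[np.clip(idx.event_group_of, 0, None)], 0.0)
    h2 = np.where(is_ev, (2 * t1 - t2)[np.clip(idx.event_group_of, 0, None)], 0.0)

    grad_sorted = idx.e_sorted - w * (C1 - h1)
    hess_sorted = w * (C1 - h1) - w * w * (C2 - h2)

    grad = np.empty_like(eta)
    hess = np.empty_like(eta)
    grad[idx.order] = grad_sorted
    hess[idx.order] = hess_sorted
    return loglik, grad, hess


@dataclass
class CoxWorkingSet:
    """Second-order working quantities of the negative partial log-likelihood.

    ``score`` and ``hess_diag`` are l' and diag(l'') of the *negative*
    partial log-likelihood at ``eta``; ``W = diag(l'')`` and
    ``z = eta - l''^{-1} l'`` so that ``W z = W eta - l'``.  At ``eta = 0``
    under Breslow ties, ``W z`` equals the null-model Martingale residuals.
    """

    loglik: float
    score: np.ndarray
    hess_diag: np.ndarray
    W: np.ndarray
    z: np.ndarray

    @property
    def wz(self) -> np.ndarray:
        return self.W * self.z


def cox_working_quantities(times, events, eta, ties: str = EFRON) -> CoxWorkingSet:
    """Second-order expansion of the negative Cox partial log-likelihood at eta."""
    loglik, grad, hess = cox_loglik_eta(times, events, eta, ties=ties)
    score = -grad
    W = np.maximum(hess, 0.0)
    eta = np.asarray(eta, dtype=float)
    # z = eta - l''^{-1} l'; where curvature vanishes (sample beyond the last
    # risk set) the score is zero too, so z := eta keeps W z = W eta - l' exact.
    z = np.where(W > 0, eta - score / np.where(W > 0, W, 1.0), eta)
    return CoxWorkingSet(loglik=loglik, score=score, hess_diag=hess, W=W, z=z)


def nelson_aalen(times, events) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated at each sample's time."""
    times, events = _check_surv(times, events)
    idx = _index_cached(times, events, BRESLOW)
    n_at_risk = times.size - idx.group_start
    increments = idx.d / n_at_risk
    cum = np.concatenate(([0.0], np.cumsum(increments)))
    Lambda_sorted = cum[idx.cum_idx]
    out = np.empty_like(times)
    out[idx.order] = Lambda_sorted
    return out


def martingale_residuals(times, events) -> np.ndarray:
    """Null-model Martingale residuals ``M_i = delta_i - Lambda(t_i)``.

    These measure observed minus expected event counts up to each sample's
    observation time under the covariate-free model; they sum to zero and
    serve as the regression representation of a censored covariate.
    """
    times, events = _check_surv(times, events)
    return events - nelson_aalen(times, events)


@dataclass
class CoxFit:
    coef: np.ndarray
    loglik: float
    cov: np.ndarray            # inverse observed information
    n_iter: int
    converged: bool
    n_events: int


def _eta_derivs_design(idx: _SurvIndex, X_sorted: np.ndarray, w: np.ndarray):
    """Gradient and full Hessian of the positive partial loglik wrt coefficients."""
    S_R, S_D, s0, s1, t0, t1, t2, logphi = _group_scalars(idx, w)
    wX = X_sorted * w[:, None]
    Sx_R = _suffix_sum(wX)[idx.group_start]                      # (G, k)
    G, k = Sx_R.shape
    ev = idx.e_sorted == 1
    grp_ev = idx.event_group_of[ev]
    Sx_D = np.empty((G, k))
    wX_ev = wX[ev]
    for a in range(k):
        Sx_D[:, a] = np.bincount(grp_ev, weights=wX_ev[:, a], minlength=G)
    wXX = wX[:, :, None] * X_sorted[:, None, :]
    Sxx_R = _suffix_sum(wXX)[idx.group_start]                    # (G, k, k)
    Sxx_D = np.empty((G, k, k))
    wXX_ev = wXX[ev]
    for a in range(k):
        for b in range(a, k):
            col = np.bincount(grp_ev, weights=wXX_ev[:, a, b], minlength=G)
            Sxx_D[:, a, b] = col
            Sxx_D[:, b, a] = col

    grad = X_sorted[ev].sum(axis=0) - (s0[:, None] * Sx_R - s1[:, None] * Sx_D).sum(axis=0)
    H = (
        np.einsum("g,gij->ij", s0, Sxx_R)
        - np.einsum("g,gij->ij", s1, Sxx_D)
        - np.einsum("g,gi,gj->ij", t0, Sx_R, Sx_R)
        + np.einsum("g,gi,gj->ij", t1, Sx_R, Sx_D)
        + np.einsum("g,gi,gj->ij", t1, Sx_D, Sx_R)
        - np.einsum("g,gi,gj->ij", t2, Sx_D, Sx_D)
    )
    return grad, H, logphi


def cox_newton(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ties: str = EFRON,
    max_iter: int = 50,
    tol: float = 1e-9,
    ridge: float = 0.0,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson with step-halving.

    ``X`` is the (n, k) covariate design (no intercept; the partial
    likelihood absorbs it).  Convergence is declared when the relative
    change in partial log-likelihood drops below ``tol``.  A tiny ``ridge``
    stabilizes nearly-singular designs; raise it explicitly for separation.
    """
    times, events = _check_surv(times, events)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.size:
        raise ValueError("design row count must match times")
    n, k = X.shape
    if k == 0:
        ll, _, _ = cox_loglik_eta(times, events, np.zeros(n), ties=ties)
        return CoxFit(np.zeros(0), ll, np.zeros((0, 0)), 0, True, int(events.sum()))
    idx = _index_cached(times, events, ties)
    Xs = X[idx.order]

    beta = np.zeros(k)
    def _loglik(b):
        return _loglik_sorted(idx, Xs @ b)

    ll = _loglik(beta)
    H_last = np.eye(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.exp(Xs @ beta)
        if not np.all(np.isfinite(w)):
            raise FloatingPointError("diverging linear predictor in Cox fit")
        grad, H, _ = _eta_derivs_design(idx, Xs, w)
        H_last = H + (ridge + 1e-10) * np.eye(k)
        try:
            step = np.linalg.solve(H_last, grad)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular design in Cox fit") from exc
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise RuntimeError("Cox Newton-Raphson step-halving exhausted")
        beta = beta + scale * step
        if abs(ll_new - ll) <= tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    cov = np.linalg.inv(H_last)
    return CoxFit(beta, ll, cov, it, converged, int(events.sum()))
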