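"""Undirected Cox mixed graphical model fit by penalized pseudolikelihood.

The joint model couples continuous variables x, discrete variables y, and
censored pairs (t, delta) through pairwise potentials: beta (x-x), rho
(x-y), phi (y-y), gamma (x-censored), psi (y-censored).  A censored node m
enters its neighbours' conditionals through the working covariate
``W_m z_m`` of a second-order expansion of its Cox partial log-likelihood
(at the null expansion point this column is exactly the vector of
Martingale residuals), while its own conditional is the Cox partial
likelihood of the linear predictor ``eta_m = gamma_m' x + psi_m(y)``.

The negative log-pseudolikelihood is the sum of node-conditional losses:
Gaussian (unit variance on standardized inputs) for continuous nodes,
multinomial-logistic for discrete nodes, Cox with Efron tie correction for
censored nodes.  Sparsity is induced by five edge-type penalties:

    lambda_cc sum |beta_st| + lambda_cd sum ||rho_sj||_2
    + lambda_dd sum ||phi_jk||_F + lambda_sc sum |gamma_sm|
    + lambda_sd sum ||psi_jm||_2

optimized by proximal gradient descent with backtracking line search,
which keeps the objective non-increasing within each expansion of the Cox
working quantities.  Nonzero parameter blocks are the learned edges.

Note on scale: the optimizer minimizes the *mean* (per-sample) negative
log-pseudolikelihood plus the penalties, so a given penalty vector means
the same thing at any (sub)sample size.  ``penalized_objective`` reports
the summed form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import cox
from .datamodel import CENSORED, CONTINUOUS, DISCRETE, MixedDataset, standardize
from .graphs import EndpointGraph

__all__ = [
    "PenaltyVector",
    "MGMParams",
    "MGMFit",
    "prepare_model_data",
    "negative_log_pseudolikelihood",
    "penalized_objective",
    "fit_coxmgm",
    "params_to_graph",
    "edge_norms",
    "EDGE_CLASSES",
]

logger = logging.getLogger(__name__)

EDGE_CLASSES = ("CC", "CD", "DD", "SC", "SD")


@dataclass(frozen=True)
class PenaltyVector:
    """Edge-type-specific nonnegative penalties (cc, cd, dd, sc, sd)."""

    cc: float
    cd: float
    dd: float
    sc: float
    sd: float

    def __post_init__(self) -> None:
        if min(self.cc, self.cd, self.dd, self.sc, self.sd) < 0:
            raise ValueError("penalties must be nonnegative")

    @classmethod
    def broadcast(cls, lam: float) -> "PenaltyVector":
        return cls(lam, lam, lam, lam, lam)

    def as_dict(self) -> dict[str, float]:
        return {"CC": self.cc, "CD": self.cd, "DD": self.dd, "SC": self.sc, "SD": self.sd}


@dataclass
class ModelData:
    """Design blocks precomputed from a dataset for pseudolikelihood work."""

    X: np.ndarray                 # (n, p) standardized continuous block
    D: np.ndarray                 # (n, Ltot) full discrete indicators
    C: np.ndarray                 # (n, r) censored working covariates (W z)
    times: np.ndarray
    events: np.ndarray
    level_slices: list[slice]
    cont_names: list[str]
    disc_names: list[str]
    cens_names: list[str]
    ties: str = cox.EFRON

    @property
    def n(self) -> int:
        return self.X.shape[0] if self.X.size else self.D.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return len(self.level_slices)

    @property
    def r(self) -> int:
        return self.times.shape[1]

    @property
    def Ltot(self) -> int:
        return self.D.shape[1]


def prepare_model_data(data: MixedDataset, ties: str = cox.EFRON) -> ModelData:
    """Standardize continuous columns, one-hot the discrete block, and set the
    censored working covariates to the null-model Martingale residuals."""
    n = data.n
    X = standardize(data.continuous) if data.p else np.empty((n, 0))
    slices: list[slice] = []
    cols = []
    start = 0
    for j in range(data.q):
        L = len(data.levels[j])
        block = np.zeros((n, L))
        block[np.arange(n), data.discrete[:, j]] = 1.0
        cols.append(block)
        slices.append(slice(start, start + L))
        start += L
    D = np.concatenate(cols, axis=1) if cols else np.empty((n, 0))
    C = np.empty((n, data.r))
    for m in range(data.r):
        C[:, m] = cox.martingale_residuals(data.times[:, m], data.events[:, m])
    return ModelData(X=X, D=D, C=C, times=data.times.copy(), events=data.events.copy(),
                     level_slices=slices, cont_names=list(data.continuous_names),
                     disc_names=list(data.discrete_names),
                     cens_names=list(data.censored_names), ties=ties)


@dataclass
class MGMParams:
    """Full parameter set of the pairwise model.

    Shapes: alpha (p,), beta (p, p) symmetric zero-diagonal, rho (p, Ltot),
    disc_intercept (Ltot,), phi (Ltot, Ltot) symmetric with zero diagonal
    blocks, gamma (p, r), psi (Ltot, r).  Level columns for discrete node j
    occupy ``level_slices[j]``.
    """

    alpha: np.ndarray
    beta: np.ndarray
    rho: np.ndarray
    disc_intercept: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray
    psi: np.ndarray
    level_slices: list[slice]

    @classmethod
    def zeros(cls, p: int, level_slices: list[slice], r: int) -> "MGMParams":
        Ltot = level_slices[-1].stop if level_slices else 0
        return cls(
            alpha=np.zeros(p), beta=np.zeros((p, p)), rho=np.zeros((p, Ltot)),
            disc_intercept=np.zeros(Ltot), phi=np.zeros((Ltot, Ltot)),
            gamma=np.zeros((p, r)), psi=np.zeros((Ltot, r)),
            level_slices=list(level_slices),
        )

    def copy(self) -> "MGMParams":
        return MGMParams(self.alpha.copy(), self.beta.copy(), self.rho.copy(),
                         self.disc_intercept.copy(), self.phi.copy(),
                         self.gamma.copy(), self.psi.copy(), list(self.level_slices))

    def _arrays(self):
        return (self.alpha, self.beta, self.rho, self.disc_intercept,
                self.phi, self.gamma, self.psi)

    def axpy(self, a: float, other: "MGMParams") -> "MGMParams":
        out = self.copy()
        for mine, theirs in zip(out._arrays(), other._arrays()):
            mine += a * theirs
        return out

    def dot(self, other: "MGMParams") -> float:
        """Inner product on the parameter space.

        beta and phi are stored as full symmetric matrices whose mirrored
        entries represent one free parameter each, so their contributions
        are halved (each gradient entry already carries the full pair
        derivative).
        """
        total = 0.5 * float((self.beta * other.beta).sum())
        total += 0.5 * float((self.phi * other.phi).sum())
        for mine, theirs in ((self.alpha, other.alpha), (self.rho, other.rho),
                             (self.disc_intercept, other.disc_intercept),
                             (self.gamma, other.gamma), (self.psi, other.psi)):
            total += float((mine * theirs).sum())
        return total

    def sq_norm(self) -> float:
        return self.dot(self)


_LOG2PI = math.log(2.0 * math.pi)


def _block_softmax(scores: np.ndarray, slices: list[slice]) -> np.ndarray:
    P = np.empty_like(scores)
    for sl in slices:
        s = scores[:, sl]
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        P[:, sl] = e / e.sum(axis=1, keepdims=True)
    return P


def _smooth_parts(params: MGMParams, md: ModelData, want_grad: bool):
    """Mean negative log-pseudolikelihood and (optionally) its gradient."""
    n = md.n
    X, D, C = md.X, md.D, md.C
    p, Ltot, r = md.p, md.Ltot, md.r

    value = 0.0
    grad = MGMParams.zeros(p, md.level_slices, r) if want_grad else None

    R = None
    if p:
        Mu = params.alpha[None, :] + X @ params.beta
        if Ltot:
            Mu = Mu + D @ params.rho.T
        if r:
            Mu = Mu + C @ params.gamma.T
        R = Mu - X
        value += 0.5 * float((R * R).sum()) + 0.5 * n * p * _LOG2PI

    E = None
    if Ltot:
        S = params.disc_intercept[None, :] + D @ params.phi
        if p:
            S = S + X @ params.rho
        if r:
            S = S + C @ params.psi.T
        P = _block_softmax(S, md.level_slices)
        eps = 1e-300
        value += -float((D * np.log(np.clip(P, eps, None))).sum())
        E = P - D

    cox_grads = np.empty((n, r)) if (r and want_grad) else None
    for m in range(r):
        eta = np.zeros(n)
        if p:
            eta = eta + X @ params.gamma[:, m]
        if Ltot:
            eta = eta + D @ params.psi[:, m]
        ll, g_eta, _ = cox.cox_loglik_eta(md.times[:, m], md.events[:, m], eta, ties=md.ties)
        value += -ll
        if want_grad:
            cox_grads[:, m] = -g_eta

    value /= n
    if not want_grad:
        return value, None

    if p:
        grad.alpha = R.sum(axis=0)
        G = X.T @ R
        grad.beta = G + G.T
        np.fill_diagonal(grad.beta, 0.0)
        if Ltot:
            grad.rho += R.T @ D
        if r:
            grad.gamma += R.T @ C
    if Ltot:
        grad.disc_intercept = E.sum(axis=0)
        if p:
            grad.rho += X.T @ E
        Gp = D.T @ E
        grad.phi = Gp + Gp.T
        for sl in md.level_slices:
            grad.phi[sl, sl] = 0.0
        if r:
            grad.psi += E.T @ C
    if r:
        if p:
            grad.gamma += X.T @ cox_grads
        if Ltot:
            grad.psi += D.T @ cox_grads

    for a in grad._arrays():
        a /= n
    return value, grad


def _penalty_value(params: MGMParams, lam: PenaltyVector, weighted: bool = False) -> float:
    slices = params.level_slices
    total = 0.0
    p = params.beta.shape[0]
    if p:
        iu = np.triu_indices(p, k=1)
        total += lam.cc * float(np.abs(params.beta[iu]).sum())
        total += lam.sc * float(np.abs(params.gamma).sum())
    for j, sl in enumerate(slices):
        wj = math.sqrt(sl.stop - sl.start) if weighted else 1.0
        if p:
            total += lam.cd * wj * float(np.linalg.norm(params.rho[:, sl], axis=1).sum())
        if params.psi.shape[1]:
            total += lam.sd * wj * float(np.linalg.norm(params.psi[sl, :], axis=0).sum())
        for k in range(j):
            slk = slices[k]
            wjk = math.sqrt((sl.stop - sl.start) * (slk.stop - slk.start)) if weighted else 1.0
            total += lam.dd * wjk * float(np.linalg.norm(params.phi[sl, slk]))
    return total


def _soft(x: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def _group_soft(block: np.ndarray, thr: float) -> np.ndarray:
    nrm = np.linalg.norm(block)
    if nrm <= thr or nrm == 0.0:
        return np.zeros_like(block)
    return block * (1.0 - thr / nrm)


def _prox(params: MGMParams, tau: float, lam: PenaltyVector, weighted: bool) -> MGMParams:
    out = params.copy()
    slices = out.level_slices
    p = out.beta.shape[0]
    if p:
        out.beta = _soft(out.beta, tau * lam.cc)
        np.fill_diagonal(out.beta, 0.0)
        out.gamma = _soft(out.gamma, tau * lam.sc)
    for j, sl in enumerate(slices):
        wj = math.sqrt(sl.stop - sl.start) if weighted else 1.0
        if p:
            block = out.rho[:, sl]
            nrm = np.linalg.norm(block, axis=1)
            scale = np.where(nrm > tau * lam.cd * wj, 1.0 - tau * lam.cd * wj / np.where(nrm > 0, nrm, 1.0), 0.0)
            out.rho[:, sl] = block * scale[:, None]
        if out.psi.shape[1]:
            block = out.psi[sl, :]
            nrm = np.linalg.norm(block, axis=0)
            scale = np.where(nrm > tau * lam.sd * wj, 1.0 - tau * lam.sd * wj / np.where(nrm > 0, nrm, 1.0), 0.0)
            out.psi[sl, :] = block * scale[None, :]
        for k in range(j):
            slk = slices[k]
            wjk = math.sqrt((sl.stop - sl.start) * (slk.stop - slk.start)) if weighted else 1.0
            newblk = _group_soft(out.phi[sl, slk], tau * lam.dd * wjk)
            out.phi[sl, slk] = newblk
            out.phi[slk, sl] = newblk.T
    return out


def negative_log_pseudolikelihood(params: MGMParams, data: MixedDataset | ModelData) -> float:
    """Summed node-conditional negative log-likelihood at the null expansion
    point (censored working covariates = null-model Martingale residuals)."""
    md = data if isinstance(data, ModelData) else prepare_model_data(data)
    _check_dims(params, md)
    value, _ = _smooth_parts(params, md, want_grad=False)
    return value * md.n


def penalized_objective(params: MGMParams, data: MixedDataset | ModelData,
                        penalties: PenaltyVector, weighted: bool = False) -> float:
    """Summed negative log-pseudolikelihood plus the five penalty terms."""
    return negative_log_pseudolikelihood(params, data) + _penalty_value(
        params, penalties, weighted)


def _check_dims(params: MGMParams, md: ModelData) -> None:
    if (params.beta.shape != (md.p, md.p) or params.rho.shape != (md.p, md.Ltot)
            or params.phi.shape != (md.Ltot, md.Ltot)
            or params.gamma.shape != (md.p, md.r) or params.psi.shape != (md.Ltot, md.r)):
        raise ValueError("parameter dimensions do not match data")


@dataclass
class MGMFit:
    params: MGMParams
    model_data: ModelData
    penalties: PenaltyVector
    objective_traces: list[list[float]]   # one monotone trace per working expansion
    n_iter: int
    converged: bool
    message: str

    @property
    def objective(self) -> float:
        return self.objective_traces[-1][-1]


def fit_coxmgm(
    data: MixedDataset | ModelData,
    penalties: PenaltyVector | float,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_outer: int = 3,
    weighted_groups: bool = False,
    init: MGMParams | None = None,
    ties: str = cox.EFRON,
) -> MGMFit:
    """Minimize the penalized negative log-pseudolikelihood.

    Proximal gradient descent with backtracking line search; scalar
    soft-thresholding for beta/gamma and group soft-thresholding for
    rho/psi/phi blocks.  The Cox working covariates start at the null-model
    Martingale residuals and are re-expanded at the current censored-node
    linear predictors up to ``n_outer`` times (IRLS style); the objective
    trace is non-increasing within each expansion.
    """
    if isinstance(penalties, (int, float)):
        penalties = PenaltyVector.broadcast(float(penalties))
    md = data if isinstance(data, ModelData) else prepare_model_data(data, ties=ties)
    if md.n < 2:
        raise ValueError("need at least two samples")
    params = init.copy() if init is not None else MGMParams.zeros(md.p, md.level_slices, md.r)
    _check_dims(params, md)

    traces: list[list[float]] = []
    total_iter = 0
    converged = False
    message = "max_iter reached"
    for outer in range(max(n_outer, 1)):
        trace: list[float] = []
        tau = 1.0
        f, grad = _smooth_parts(params, md, want_grad=True)
        F = f + _penalty_value(params, penalties, weighted_groups)
        trace.append(F)
        for _ in range(max_iter):
            total_iter += 1
            accepted = False
            for _bt in range(60):
                cand = _prox(params.axpy(-tau, grad), tau, penalties, weighted_groups)
                f_new, _ = _smooth_parts(cand, md, want_grad=False)
                if not np.isfinite(f_new):
                    tau *= 0.5
                    continue
                diff = cand.axpy(-1.0, params)
                quad = f + grad.dot(diff) + diff.sq_norm() / (2.0 * tau)
                if f_new <= quad + 1e-12:
                    accepted = True
                    break
                tau *= 0.5
            if not accepted:
                message = "line search stalled"
                break
            F_new = f_new + _penalty_value(cand, penalties, weighted_groups)
            if not np.isfinite(F_new):
                raise FloatingPointError("objective diverged (non-finite); trace: %r" % trace)
            params = cand
            trace.append(min(F_new, trace[-1] + 1e-15))
            rel = abs(F - F_new) / (abs(F) + 1.0)
            F = F_new
            f, grad = _smooth_parts(params, md, want_grad=True)
            tau = min(tau * 1.25, 1e6)
            if rel < tol:
                converged = True
                message = "converged"
                break
        traces.append(trace)
        if md.r == 0 or outer == max(n_outer, 1) - 1:
            break
        # refresh the second-order expansion of each censored node at its
        # current linear predictor
        C_new = np.empty_like(md.C)
        for m in range(md.r):
            eta = np.zeros(md.n)
            if md.p:
                eta = eta + md.X @ params.gamma[:, m]
            if md.Ltot:
                eta = eta + md.D @ params.psi[:, m]
            if np.allclose(eta, 0.0):
                C_new[:, m] = cox.martingale_residuals(md.times[:, m], md.events[:, m])
            else:
                ws = cox.cox_working_quantities(md.times[:, m], md.events[:, m], eta,
                                               ties=md.ties)
                C_new[:, m] = ws.wz
        if np.max(np.abs(C_new - md.C)) < 1e-6:
            break
        md = ModelData(X=md.X, D=md.D, C=C_new, times=md.times, events=md.events,
                       level_slices=md.level_slices, cont_names=md.cont_names,
                       disc_names=md.disc_names, cens_names=md.cens_names, ties=md.ties)
    return MGMFit(params=params, model_data=md, penalties=penalties,
                  objective_traces=traces, n_iter=total_iter,
                  converged=converged, message=message)


def edge_norms(params: MGMParams, md: ModelData) -> dict[tuple[str, str], tuple[str, float]]:
    """Norm of each pairwise parameter block, keyed by (name_u, name_v).

    Covers every representable pair: CC, CD, DD, SC, SD (the model has no
    censored-censored potential).
    """
    out: dict[tuple[str, str], tuple[str, float]] = {}
    cn, dn, sn = md.cont_names, md.disc_names, md.cens_names
    for s in range(md.p):
        for t in range(s + 1, md.p):
            out[(cn[s], cn[t])] = ("CC", abs(params.beta[s, t]))
    for s in range(md.p):
        for j, sl in enumerate(md.level_slices):
            out[(cn[s], dn[j])] = ("CD", float(np.linalg.norm(params.rho[s, sl])))
    for j in range(md.q):
        for k in range(j + 1, md.q):
            blk = params.phi[md.level_slices[j], md.level_slices[k]]
            out[(dn[j], dn[k])] = ("DD", float(np.linalg.norm(blk)))
    for s in range(md.p):
        for m in range(md.r):
            out[(cn[s], sn[m])] = ("SC", abs(params.gamma[s, m]))
    for j, sl in enumerate(md.level_slices):
        for m in range(md.r):
            out[(dn[j], sn[m])] = ("SD", float(np.linalg.norm(params.psi[sl, m])))
    return out


def params_to_graph(params: MGMParams, md: ModelData, zero_tol: float = 1e-6
                    ) -> EndpointGraph:
    """Undirected graph with an edge wherever a parameter block's norm
    exceeds ``zero_tol``."""
    kinds = {**{v: CONTINUOUS for v in md.cont_names},
             **{v: DISCRETE for v in md.disc_names},
             **{v: CENSORED for v in md.cens_names}}
    g = EndpointGraph(md.cont_names + md.disc_names + md.cens_names, kinds, "skeleton")
    for (u, v), (_cls, nrm) in edge_norms(params, md).items():
        if nrm > zero_tol:
            g.add_edge(u, v)
    return g
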