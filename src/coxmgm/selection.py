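"""Penalty selection for the mixed graphical model: StEPS, StARS, and BIC.

Stability-based selection fits the model on B subsamples at every point of
a decreasing penalty path and measures, for each possible edge, the
selection frequency theta-hat; the edge's instability is 2 theta (1 - theta).
StARS averages instability over all possible edges and picks the smallest
penalty whose monotonized instability stays below a threshold; StEPS does
the same per edge type (CC, CD, DD, SC, SD), returning one penalty per
type.  BIC scores each path point's fit by
``2 * NLL + log(n) * #nonzero parameters``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import MixedDataset
from .mgm import (EDGE_CLASSES, MGMFit, MGMParams, ModelData, PenaltyVector,
                  edge_norms, fit_coxmgm, negative_log_pseudolikelihood,
                  prepare_model_data)

__all__ = [
    "StabilityProfile",
    "build_lambda_path",
    "stability_profile",
    "steps_select",
    "stars_select",
    "bic_score",
    "default_subsample_size",
]

logger = logging.getLogger(__name__)

ZERO_TOL = 1e-6


def default_subsample_size(n: int) -> int:
    """StARS-convention subsample size b = min(floor(10 sqrt(n)), floor(0.75 n))."""
    return int(min(np.floor(10.0 * np.sqrt(n)), np.floor(0.75 * n)))


@dataclass
class StabilityProfile:
    """Per-edge-type instability curves over a decreasing penalty path."""

    path: np.ndarray                        # strictly decreasing
    instability: dict[str, np.ndarray]      # class -> (K,) mean 2 theta (1-theta)
    n_possible: dict[str, int]              # possible edges per class
    B: int
    b: int
    seed: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.path) >= 0):
            raise ValueError("penalty path must be strictly decreasing")
        for cls, arr in self.instability.items():
            if np.any(arr < -1e-12) or np.any(arr > 0.5 + 1e-12):
                raise ValueError(f"instability for {cls} outside [0, 0.5]")

    def pooled(self) -> np.ndarray:
        """All-edge-type instability curve (possible-edge-weighted mean)."""
        total = np.zeros_like(self.path)
        count = 0
        for cls in EDGE_CLASSES:
            npos = self.n_possible.get(cls, 0)
            if npos:
                total += self.instability[cls] * npos
                count += npos
        return total / max(count, 1)

    def to_json(self, path: str) -> None:
        payload = {
            "path": self.path.tolist(),
            "instability": {k: v.tolist() for k, v in self.instability.items()},
            "n_possible": self.n_possible,
            "B": self.B, "b": self.b, "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _count_edges(fit: MGMFit, zero_tol: float = ZERO_TOL) -> int:
    return sum(1 for _cls, nrm in edge_norms(fit.params, fit.model_data).values()
               if nrm > zero_tol)


def build_lambda_path(data: MixedDataset | ModelData, K: int = 30,
                      ratio: float = 0.01, **fit_kwargs) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max down to lambda_max * ratio.

    lambda_max is the smallest power-of-two multiple of a small probe value
    at which the fitted graph is empty (doubling search).
    """
    if K < 2:
        raise ValueError("need at least two path points")
    md = data if isinstance(data, ModelData) else prepare_model_data(data)
    lam = 0.05
    fit_kwargs.setdefault("tol", 1e-5)
    fit_kwargs.setdefault("n_outer", 1)
    for _ in range(60):
        if _count_edges(fit_coxmgm(md, lam, **fit_kwargs)) == 0:
            break
        lam *= 2.0
    else:
        raise RuntimeError("doubling search for lambda_max did not terminate")
    return np.geomspace(lam, lam * ratio, K)


def _subsample_indices(md: ModelData, b: int, seed: int, index: int,
                       max_retry: int = 10) -> np.ndarray:
    """Draw b rows without replacement; retry if any censored node loses all
    its events (degenerate Cox conditional)."""
    for attempt in range(max_retry):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index, attempt)))
        idx = rng.choice(md.n, size=b, replace=False)
        if md.r == 0 or md.events[idx].sum(axis=0).min() > 0:
            return np.sort(idx)
        logger.warning("subsample %d attempt %d lost all events for a censored node; "
                       "resampling", index, attempt)
    raise RuntimeError("could not draw a subsample with events for every censored node")


def _subset_model_data(md: ModelData, idx: np.ndarray) -> ModelData:
    from . import cox
    from .datamodel import standardize
    C = np.empty((idx.size, md.r))
    times = md.times[idx]
    events = md.events[idx]
    for m in range(md.r):
        C[:, m] = cox.martingale_residuals(times[:, m], events[:, m])
    return ModelData(
        X=standardize(md.X[idx]) if md.p else md.X[idx],
        D=md.D[idx], C=C, times=times, events=events,
        level_slices=md.level_slices, cont_names=md.cont_names,
        disc_names=md.disc_names, cens_names=md.cens_names, ties=md.ties)


def stability_profile(
    data: MixedDataset | ModelData,
    path: np.ndarray,
    B: int = 20,
    b: int | None = None,
    seed: int = 0,
    zero_tol: float = ZERO_TOL,
    **fit_kwargs,
) -> StabilityProfile:
    """Edge-selection instability across subsamples along the penalty path.

    Fits are warm-started along the decreasing path within each subsample.
    Deterministic given ``seed`` (each subsample draws from a seed derived
    from the master seed by index, so subsample order is immaterial).
    """
    md = data if isinstance(data, ModelData) else prepare_model_data(data)
    path = np.asarray(path, dtype=float)
    if b is None:
        b = default_subsample_size(md.n)
    if b >= md.n:
        raise ValueError("subsample size must be < n")
    fit_kwargs.setdefault("tol", 1e-5)
    fit_kwargs.setdefault("n_outer", 1)

    K = path.size
    ref = edge_norms(MGMParams.zeros(md.p, md.level_slices, md.r), md)
    pair_keys = list(ref.keys())
    pair_class = np.array([ref[k][0] for k in pair_keys])
    counts = np.zeros((K, len(pair_keys)))

    for i in range(B):
        idx = _subsample_indices(md, b, seed, i)
        sub = _subset_model_data(md, idx)
        init = None
        for k, lam in enumerate(path):
            fit = fit_coxmgm(sub, lam, init=init, **fit_kwargs)
            init = fit.params
            nrms = edge_norms(fit.params, sub)
            counts[k] += np.array([nrms[key][1] > zero_tol for key in pair_keys])

    theta = counts / B
    xi = 2.0 * theta * (1.0 - theta)
    instability = {}
    n_possible = {}
    for cls in EDGE_CLASSES:
        mask = pair_class == cls
        n_possible[cls] = int(mask.sum())
        instability[cls] = xi[:, mask].mean(axis=1) if mask.any() else np.zeros(K)
    return StabilityProfile(path=path, instability=instability,
                            n_possible=n_possible, B=B, b=b, seed=seed)


def _monotonize(curve: np.ndarray) -> np.ndarray:
    """Running maximum in the direction of decreasing penalty."""
    return np.maximum.accumulate(curve)


def _select_from_curve(path: np.ndarray, curve: np.ndarray, threshold: float) -> float:
    mono = _monotonize(curve)
    ok = np.nonzero(mono <= threshold)[0]
    if ok.size == 0:
        logger.warning("no path point meets instability threshold %.3f; "
                       "returning the largest penalty", threshold)
        return float(path[0])
    return float(path[ok[-1]])          # smallest penalty still below threshold


def steps_select(profile: StabilityProfile, threshold: float = 0.05) -> PenaltyVector:
    """Per-edge-type stability selection: one penalty per edge type."""
    if not 0.0 < threshold < 0.5:
        raise ValueError("threshold must lie in (0, 0.5)")
    chosen = {}
    pooled = None
    for cls in EDGE_CLASSES:
        if profile.n_possible.get(cls, 0) > 0:
            chosen[cls] = _select_from_curve(profile.path, profile.instability[cls],
                                             threshold)
        else:
            if pooled is None:
                pooled = _select_from_curve(profile.path, profile.pooled(), threshold)
            chosen[cls] = pooled        # no edges of this type: any value works
    return PenaltyVector(cc=chosen["CC"], cd=chosen["CD"], dd=chosen["DD"],
                         sc=chosen["SC"], sd=chosen["SD"])


def stars_select(profile: StabilityProfile, threshold: float = 0.05) -> PenaltyVector:
    """Pooled stability selection: one penalty broadcast to all edge types."""
    if not 0.0 < threshold < 0.5:
        raise ValueError("threshold must lie in (0, 0.5)")
    lam = _select_from_curve(profile.path, profile.pooled(), threshold)
    return PenaltyVector.broadcast(lam)


def n_nonzero_params(params: MGMParams, zero_tol: float = ZERO_TOL) -> int:
    """Free nonzero parameters: intercept terms plus nonzero pairwise entries
    (each symmetric pair counted once)."""
    count = params.alpha.size + params.disc_intercept.size
    p = params.beta.shape[0]
    if p:
        iu = np.triu_indices(p, k=1)
        count += int((np.abs(params.beta[iu]) > zero_tol).sum())
        count += int((np.abs(params.gamma) > zero_tol).sum())
    count += int((np.abs(params.rho) > zero_tol).sum())
    count += int((np.abs(params.psi) > zero_tol).sum())
    slices = params.level_slices
    for j in range(len(slices)):
        for k in range(j):
            count += int((np.abs(params.phi[slices[j], slices[k]]) > zero_tol).sum())
    return count


def bic_score(data: MixedDataset | ModelData, params: MGMParams,
              zero_tol: float = ZERO_TOL) -> float:
    """Bayesian information criterion of a fitted parameter set."""
    md = data if isinstance(data, ModelData) else prepare_model_data(data)
    nll = negative_log_pseudolikelihood(params, md)
    return 2.0 * nll + np.log(md.n) * n_nonzero_params(params, zero_tol)


def bic_select(data: MixedDataset | ModelData, path: np.ndarray, **fit_kwargs
               ) -> tuple[PenaltyVector, list[float]]:
    """Fit along the path and return the BIC-minimizing penalty (broadcast)."""
    md = data if isinstance(data, ModelData) else prepare_model_data(data)
    fit_kwargs.setdefault("tol", 1e-5)
    fit_kwargs.setdefault("n_outer", 1)
    scores = []
    init = None
    for lam in path:
        fit = fit_coxmgm(md, lam, init=init, **fit_kwargs)
        init = fit.params
        scores.append(bic_score(md, fit.params))
    best = int(np.argmin(scores))
    return PenaltyVector.broadcast(float(path[best])), scores
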