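"""Markov-blanket Cox prediction and concordance evaluation.

Once a causal graph is learned, a parsimonious survival predictor for any
censored outcome is a Cox proportional-hazards model on the outcome's
Markov blanket.  Discrimination is measured with Harrell's concordance
index: the fraction of comparable pairs (the earlier time is an observed
event) whose predicted risk ordering matches the observed event ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import cox
from .causal import markov_blanket
from .datamodel import CENSORED, CONTINUOUS, DISCRETE, MixedDataset
from .graphs import EndpointGraph

__all__ = [
    "SurvivalPredictor",
    "fit_mb_cox",
    "risk_score",
    "harrell_concordance",
    "cross_validated_concordance",
]

logger = logging.getLogger(__name__)


@dataclass
class SurvivalPredictor:
    target: str
    features: list[str]               # MB variable names, sorted
    feature_columns: list[str]        # expanded design column names
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_events: int
    means: np.ndarray                 # training means used to centre the design

    def hazard_ratios(self) -> dict[str, tuple[float, float, float]]:
        """Per-column hazard ratio with a 95% Wald confidence interval."""
        out = {}
        z = stats.norm.ppf(0.975)
        for name, b, s in zip(self.feature_columns, self.coef, self.se):
            out[name] = (float(np.exp(b)), float(np.exp(b - z * s)),
                         float(np.exp(b + z * s)))
        return out


def _design_for(data: MixedDataset, features: list[str]) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    for f in features:
        kind = data.kind_of(f)
        if kind == CONTINUOUS:
            cols.append(np.asarray(data.column(f), float).reshape(-1, 1))
            names.append(f)
        elif kind == DISCRETE:
            L = data.n_levels(f)
            codes = np.asarray(data.column(f))
            out = np.zeros((codes.size, L))
            out[np.arange(codes.size), codes] = 1.0
            cols.append(out[:, 1:])
            names.extend(f"{f}={lv}" for lv in data.levels[data.discrete_names.index(f)][1:])
        else:
            t, e = data.column(f)
            cols.append(cox.martingale_residuals(t, e).reshape(-1, 1))
            names.append(f"{f}(resid)")
    if not cols:
        return np.empty((data.n, 0)), []
    return np.concatenate(cols, axis=1), names


def fit_mb_cox(data: MixedDataset, graph: EndpointGraph, target: str,
               ties: str = cox.EFRON) -> SurvivalPredictor:
    """Cox model on the Markov blanket of a censored outcome.

    Continuous blanket members enter directly, discrete members are
    reference-encoded, and censored members enter through their Martingale
    residuals.  An empty blanket yields the null model (all risk scores
    equal) with a warning.
    """
    if data.kind_of(target) != CENSORED:
        raise ValueError(f"target {target!r} is not a censored variable")
    t, e = data.column(target)
    mb = sorted(markov_blanket(graph, target))
    mb = [f for f in mb if f != target]
    if not mb:
        logger.warning("empty Markov blanket for %s: fitting the null model", target)
        return SurvivalPredictor(target, [], [], np.zeros(0), np.zeros(0),
                                 cox.cox_newton(np.empty((data.n, 0)), t, e).loglik,
                                 int(np.sum(e)), np.zeros(0))
    X, colnames = _design_for(data, mb)
    means = X.mean(axis=0)
    fit = cox.cox_newton(X - means, t, e, ties=ties)
    if not fit.converged:
        raise RuntimeError(f"Markov-blanket Cox fit for {target!r} did not converge")
    return SurvivalPredictor(target, mb, colnames, fit.coef,
                             np.sqrt(np.diag(fit.cov)), fit.loglik,
                             fit.n_events, means)


def risk_score(predictor: SurvivalPredictor, new_data: MixedDataset) -> np.ndarray:
    """Linear predictor on the blanket features; higher means higher hazard."""
    for f in predictor.features:
        if f not in new_data.names:
            raise KeyError(f"Markov-blanket feature {f!r} missing from new data")
    if not predictor.features:
        return np.zeros(new_data.n)
    X, _ = _design_for(new_data, predictor.features)
    return (X - predictor.means) @ predictor.coef


def harrell_concordance(scores, times, events, horizon: float | None = None) -> float:
    """Harrell's C: concordant fraction over comparable pairs.

    A pair (i, j) is comparable when the smaller time belongs to an
    observed event and the times differ; ties in score count one half.
    With a ``horizon``, pairs whose earlier time exceeds it are excluded.
    """
    s = np.asarray(scores, float)
    t = np.asarray(times, float)
    e = np.asarray(events)
    if not (s.size == t.size == e.size):
        raise ValueError("scores, times, events must have equal length")
    conc = 0.0
    n_pairs = 0
    for i in range(t.size):
        if e[i] != 1:
            continue
        if horizon is not None and t[i] > horizon:
            continue
        later = t > t[i]
        n_pairs += int(later.sum())
        conc += float((s[i] > s[later]).sum()) + 0.5 * float((s[i] == s[later]).sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    return conc / n_pairs


def cross_validated_concordance(
    data: MixedDataset,
    graph_learner,
    target: str,
    folds: int = 10,
    seed: int = 0,
    horizon: float | None = None,
) -> dict:
    """K-fold cross-validated concordance of Markov-blanket Cox predictors.

    ``graph_learner`` is a callable mapping a training MixedDataset to an
    EndpointGraph.  Held-out risk scores are pooled over folds before the
    concordance is computed.  Folds without an observed event are skipped.
    """
    if folds < 2:
        raise ValueError("need at least two folds")
    rng = np.random.default_rng(seed)
    n = data.n
    assign = rng.permutation(n) % folds
    t_all, e_all = data.column(target)
    pooled_scores = np.full(n, np.nan)
    used = np.zeros(n, dtype=bool)
    blankets = []
    for k in range(folds):
        test_idx = np.nonzero(assign == k)[0]
        train_idx = np.nonzero(assign != k)[0]
        if e_all[test_idx].sum() == 0 or e_all[train_idx].sum() == 0:
            logger.warning("fold %d has no observed events; skipped", k)
            continue
        train = data.subset(train_idx)
        test = data.subset(test_idx)
        graph = graph_learner(train)
        predictor = fit_mb_cox(train, graph, target)
        pooled_scores[test_idx] = risk_score(predictor, test)
        used[test_idx] = True
        blankets.append(sorted(predictor.features))
    if not used.any():
        raise RuntimeError("every fold was skipped")
    c = harrell_concordance(pooled_scores[used], t_all[used], e_all[used],
                            horizon=horizon)
    return {"concordance": float(c), "n_used": int(used.sum()),
            "fold_assignment": assign.tolist(), "blankets": blankets}
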