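"""Conditional-independence tests over mixed continuous/discrete/censored data.

The dispatcher :func:`ci_test` routes on the kinds of the two tested
variables:

* censored vs continuous — Cox regression of the censored variable on the
  other plus the conditioning set; Wald t-test on the tested coefficient.
* censored vs discrete — likelihood-ratio test between Cox models with and
  without the (reference-encoded) discrete variable.
* neither censored — partial-correlation t-test (both continuous),
  Gaussian likelihood-ratio test (continuous/discrete), or multinomial
  likelihood-ratio test (both discrete).

Censored variables *inside* the conditioning set are represented by their
null-model Martingale residuals instead of their raw observation times.
Raw censored times understate true event times, so using them directly as
covariates distorts coefficients (expansion bias), while dropping censored
rows throws away samples.  The residual column keeps every sample and
carries the observed-minus-expected event information of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from . import cox
from ._glm import fit_multinomial, ols_loglik
from .datamodel import CENSORED, CONTINUOUS, DISCRETE, MixedDataset, encode_discrete

__all__ = [
    "CITestConfig",
    "CITestResult",
    "martingale_residuals",
    "expand_conditioning_set",
    "test_censored_vs_continuous",
    "test_censored_vs_discrete",
    "test_noncensored",
    "ci_test",
]


@dataclass(frozen=True)
class CITestConfig:
    alpha: float = 0.05
    max_cond_size: int = 3
    ties: str = cox.EFRON

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class CITestResult:
    p_value: float
    statistic: float
    df: float
    family: str
    n_effective: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def martingale_residuals(times, events) -> np.ndarray:
    """Null-model Martingale residuals (Breslow/Nelson-Aalen cumulative hazard)."""
    return cox.martingale_residuals(times, events)


def expand_conditioning_set(S: Iterable[str], data: MixedDataset) -> np.ndarray:
    """Design-matrix encoding of a conditioning set; keeps all n rows.

    Continuous members pass through, discrete members are reference-encoded,
    and censored members are replaced by their null-model Martingale
    residual column.
    """
    cols: list[np.ndarray] = []
    for name in sorted(S):
        kind = data.kind_of(name)
        if kind == CONTINUOUS:
            cols.append(np.asarray(data.column(name), dtype=float).reshape(-1, 1))
        elif kind == DISCRETE:
            cols.append(encode_discrete(data.column(name), data.n_levels(name), reference=True))
        else:
            t, e = data.column(name)
            cols.append(martingale_residuals(t, e).reshape(-1, 1))
    if not cols:
        return np.empty((data.n, 0))
    return np.concatenate(cols, axis=1)


def _data_cache(data: MixedDataset) -> dict:
    """Per-dataset memo for null-model fits shared across tests.

    During constraint-based search the same (target, conditioning set) null
    model is refit for many candidate partners; caching it on the dataset
    object keeps the cache's lifetime tied to the data.
    """
    cache = getattr(data, "_citest_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(data, "_citest_cache", cache)
    return cache


def _wald_t_cox(times, events, design, config: CITestConfig, family: str) -> CITestResult:
    fit = cox.cox_newton(design, times, events, ties=config.ties)
    if not fit.converged:
        raise RuntimeError(f"Cox fit did not converge in {family} test")
    se = np.sqrt(fit.cov[0, 0])
    stat = fit.coef[0] / se
    df = max(fit.n_events - design.shape[1], 1)
    p = 2.0 * stats.t.sf(abs(stat), df)
    return CITestResult(float(min(p, 1.0)), float(stat), float(df), family, times.size)


def test_censored_vs_continuous(
    x_name: str, y_name: str, S: Iterable[str], data: MixedDataset, config: CITestConfig
) -> CITestResult:
    """Wald t-test on the continuous variable's Cox coefficient.

    The censored variable is the regression target; degrees of freedom are
    observed events minus fitted parameters.
    """
    t, e = data.column(x_name)
    y = np.asarray(data.column(y_name), dtype=float).reshape(-1, 1)
    design = np.concatenate([y, expand_conditioning_set(S, data)], axis=1)
    return _wald_t_cox(t, e, design, config, "cox-wald")


def test_censored_vs_discrete(
    x_name: str, y_name: str, S: Iterable[str], data: MixedDataset, config: CITestConfig
) -> CITestResult:
    """Likelihood-ratio test between Cox models with and without the discrete variable."""
    t, e = data.column(x_name)
    Z = expand_conditioning_set(S, data)
    L = data.n_levels(y_name)
    Y = encode_discrete(data.column(y_name), L, reference=True)
    cache = _data_cache(data)
    key = ("cox-null", x_name, frozenset(S), config.ties)
    null = cache.get(key)
    if null is None:
        null = cox.cox_newton(Z, t, e, ties=config.ties)
        cache[key] = null
    full = cox.cox_newton(np.concatenate([Y, Z], axis=1), t, e, ties=config.ties)
    if not (null.converged and full.converged):
        raise RuntimeError("Cox fit did not converge in cox-lrt test")
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    df = L - 1
    p = stats.chi2.sf(stat, df) if stat > 0 else 1.0
    return CITestResult(float(p), float(stat), float(df), "cox-lrt", data.n)


def _test_cc(x: np.ndarray, y: np.ndarray, Z: np.ndarray) -> CITestResult:
    n = x.size
    design = np.column_stack([np.ones(n), y, Z])
    coef, rss, _ = ols_loglik(design, x)
    k = design.shape[1]
    XtX_inv = np.linalg.inv(design.T @ design)
    df = n - k
    sigma2 = rss / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    stat = coef[1] / se
    p = 2.0 * stats.t.sf(abs(stat), df)
    return CITestResult(float(min(p, 1.0)), float(stat), float(df), "linear-wald", n)


def _test_cd(xc: np.ndarray, y_codes: np.ndarray, L: int, Z: np.ndarray,
             null_cache=None, null_key=None) -> CITestResult:
    """Gaussian LRT for adding a discrete variable to the continuous model."""
    n = xc.size
    base = np.column_stack([np.ones(n), Z])
    Yd = encode_discrete(y_codes, L, reference=True)
    ll0 = null_cache.get(null_key) if null_cache is not None else None
    if ll0 is None:
        _, _, ll0 = ols_loglik(base, xc)
        if null_cache is not None:
            null_cache[null_key] = ll0
    _, _, ll1 = ols_loglik(np.concatenate([base, Yd], axis=1), xc)
    stat = max(2.0 * (ll1 - ll0), 0.0)
    df = L - 1
    p = stats.chi2.sf(stat, df) if stat > 0 else 1.0
    return CITestResult(float(p), float(stat), float(df), "gaussian-lrt", n)


def _test_dd(x_codes, Lx: int, y_codes, Ly: int, Z: np.ndarray,
             null_cache=None, null_key=None) -> CITestResult:
    n = x_codes.size
    base = np.column_stack([np.ones(n), Z])
    Yd = encode_discrete(y_codes, Ly, reference=True)
    f0 = null_cache.get(null_key) if null_cache is not None else None
    if f0 is None:
        f0 = fit_multinomial(base, x_codes, Lx)
        if null_cache is not None:
            null_cache[null_key] = f0
    f1 = fit_multinomial(np.concatenate([base, Yd], axis=1), x_codes, Lx)
    if not (f0.converged and f1.converged):
        raise RuntimeError("multinomial fit did not converge in dd test")
    stat = max(2.0 * (f1.loglik - f0.loglik), 0.0)
    df = (Lx - 1) * (Ly - 1)
    p = stats.chi2.sf(stat, df) if stat > 0 else 1.0
    return CITestResult(float(p), float(stat), float(df), "multinomial-lrt", n)


def test_noncensored(
    x_name: str, y_name: str, S: Iterable[str], data: MixedDataset, config: CITestConfig
) -> CITestResult:
    """Mixed-type test when neither tested variable is censored.

    The conditioning set may contain censored variables; they enter through
    their Martingale-residual columns so every sample is retained.
    """
    kx, ky = data.kind_of(x_name), data.kind_of(y_name)
    if CENSORED in (kx, ky):
        raise ValueError("test_noncensored requires non-censored X and Y")
    Z = expand_conditioning_set(S, data)
    if kx == CONTINUOUS and ky == CONTINUOUS:
        # canonical target: exact (not just analytic) symmetry in X and Y
        a, b = sorted([x_name, y_name])
        return _test_cc(np.asarray(data.column(a), float),
                        np.asarray(data.column(b), float), Z)
    cache = _data_cache(data)
    if kx == DISCRETE and ky == DISCRETE:
        # canonical target keeps the dispatcher symmetric in its arguments
        a, b = sorted([x_name, y_name])
        return _test_dd(data.column(a), data.n_levels(a),
                        data.column(b), data.n_levels(b), Z,
                        null_cache=cache, null_key=("mn-null", a, frozenset(S)))
    cont, disc = (x_name, y_name) if kx == CONTINUOUS else (y_name, x_name)
    return _test_cd(np.asarray(data.column(cont), float),
                    data.column(disc), data.n_levels(disc), Z,
                    null_cache=cache, null_key=("ols-null", cont, frozenset(S)))


def _test_censored_pair(
    x_name: str, y_name: str, S: Iterable[str], data: MixedDataset, config: CITestConfig
) -> CITestResult:
    """Both variables censored: each serves as target once, the other entering
    as its Martingale-residual covariate; the larger p-value is returned."""
    results = []
    for target, other in ((x_name, y_name), (y_name, x_name)):
        t, e = data.column(target)
        to, eo = data.column(other)
        resid = martingale_residuals(to, eo).reshape(-1, 1)
        design = np.concatenate([resid, expand_conditioning_set(S, data)], axis=1)
        results.append(_wald_t_cox(t, e, design, config, "cox-wald-pair"))
    return max(results, key=lambda r: r.p_value)


def ci_test(
    x_name: str,
    y_name: str,
    S: Iterable[str],
    data: MixedDataset,
    config: CITestConfig | None = None,
) -> CITestResult:
    """Test X independent of Y given S; symmetric in X and Y by construction."""
    config = config or CITestConfig()
    S = frozenset(S)
    if x_name in S or y_name in S:
        raise ValueError("conditioning set must exclude the tested variables")
    kx, ky = data.kind_of(x_name), data.kind_of(y_name)
    if kx == CENSORED and ky == CENSORED:
        return _test_censored_pair(*sorted([x_name, y_name]), S, data, config)
    if kx == CENSORED:
        cens, other = x_name, y_name
    elif ky == CENSORED:
        cens, other = y_name, x_name
    else:
        return test_noncensored(x_name, y_name, S, data, config)
    if data.kind_of(other) == CONTINUOUS:
        return test_censored_vs_continuous(cens, other, S, data, config)
    return test_censored_vs_discrete(cens, other, S, data, config)
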