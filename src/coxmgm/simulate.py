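"""Synthetic benchmark generator: typed DAGs and mixed-type data with censoring.

The benchmark design places continuous, discrete, and censored variables on
random (Erdős–Rényi) or scale-free DAG topologies in 5/11 : 5/11 : 1/11
proportions, then draws data by ancestral sampling:

* continuous children are linear in their parents plus unit Gaussian noise;
* discrete children follow a multinomial-logistic response whose level
  scores are an ordered contrast times the summed parent contribution;
* censored children draw an event time from a Weibull proportional-hazards
  model (baseline scale 1, shape 1.5 by default) with the parent sum as
  linear predictor, and an independent exponential censoring time whose
  rate is calibrated so the expected censored fraction hits the requested
  condition: 30% under light censoring, 70% under heavy censoring.

A censored node acts on its children through its standardized negative log
latent event time (the pre-censoring risk ranking), so censoring degrades
the observable signal on such edges without touching the generating law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .datamodel import CENSORED, CONTINUOUS, DISCRETE, MixedDataset
from .graphs import ARROW, TAIL, EndpointGraph

__all__ = [
    "SimulationConfig",
    "GroundTruthModel",
    "generate_dag",
    "simulate_mixed_data",
    "calibrate_censoring",
    "TYPE_FRACTIONS",
]

TYPE_FRACTIONS = (5.0 / 11.0, 5.0 / 11.0, 1.0 / 11.0)
CENSORING_TARGETS = {"light": 0.30, "heavy": 0.70, "none": 0.0}


@dataclass(frozen=True)
class SimulationConfig:
    n_nodes: int = 110
    topology: str = "ER"
    avg_degree: float = 4.0
    type_fractions: tuple[float, float, float] = TYPE_FRACTIONS
    n_samples: int = 500
    censoring: str = "light"
    coef_range: tuple[float, float] = (0.3, 1.0)
    n_levels: int = 3
    weibull_shape: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology.upper() not in ("ER", "SF"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.avg_degree >= self.n_nodes:
            raise ValueError("average degree must be < number of nodes")
        if abs(sum(self.type_fractions) - 1.0) > 1e-9:
            raise ValueError("type fractions must sum to 1")
        if self.censoring not in CENSORING_TARGETS:
            raise ValueError(f"unknown censoring condition {self.censoring!r}")


@dataclass
class GroundTruthModel:
    """A typed DAG plus all generating parameters."""

    dag: EndpointGraph                      # tag "dag", kinds on nodes
    parents: dict[str, list[str]]
    weights: dict[tuple[str, str], np.ndarray]   # (parent, child) -> scalar or per-level array
    magnitudes: dict[tuple[str, str], float]
    config: SimulationConfig
    seed: int

    @property
    def node_kinds(self) -> dict[str, str]:
        return self.dag.kinds


def _type_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    floors = [int(np.floor(f * n)) for f in fractions]
    rem = n - sum(floors)
    fracparts = [f * n - fl for f, fl in zip(fractions, floors)]
    for idx in np.argsort(fracparts)[::-1][:rem]:
        floors[idx] += 1
    return tuple(floors)  # type: ignore[return-value]


def _er_edges(n: int, n_edges: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if n_edges > len(pairs):
        raise ValueError("requested edges exceed N(N-1)/2")
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    order = rng.permutation(n)          # random topological order
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    out = []
    for k in chosen:
        i, j = pairs[k]
        out.append((i, j) if pos[i] < pos[j] else (j, i))
    return out


def _sf_edges(n: int, n_edges: int, d: float, rng: np.random.Generator
              ) -> list[tuple[int, int]]:
    """Preferential attachment, oriented old -> new, topped up to n_edges."""
    m = max(1, int(round(d / 2)))
    if n_edges > n * (n - 1) // 2:
        raise ValueError("requested edges exceed N(N-1)/2")
    edges: set[tuple[int, int]] = set()
    targets = list(range(m))            # initial nodes
    repeated: list[int] = list(range(m))
    for v in range(m, n):
        chosen: set[int] = set()
        while len(chosen) < min(m, v):
            pick = repeated[rng.integers(len(repeated))] if repeated else int(rng.integers(v))
            if pick < v:
                chosen.add(pick)
        for u in chosen:
            edges.add((u, v))
            repeated.extend([u, v])
    # top up with degree-weighted non-adjacent pairs so |E| is exact
    while len(edges) < n_edges:
        deg = np.bincount(np.array([x for e in edges for x in e]), minlength=n) + 1.0
        prob = deg / deg.sum()
        u, v = rng.choice(n, size=2, replace=False, p=prob)
        a, b = (u, v) if u < v else (v, u)
        if (a, b) not in edges:
            edges.add((a, b))
    out = sorted(edges)
    if len(out) > n_edges:
        keep = rng.choice(len(out), size=n_edges, replace=False)
        out = [out[i] for i in sorted(keep)]
    return out


def generate_dag(config: SimulationConfig) -> GroundTruthModel:
    """Draw a typed ground-truth DAG with edge coefficients."""
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    n_edges = int(np.floor(n * config.avg_degree / 2))
    if config.topology.upper() == "ER":
        edges = _er_edges(n, n_edges, rng)
    else:
        edges = _sf_edges(n, n_edges, config.avg_degree, rng)

    n_cont, n_disc, n_cens = _type_counts(n, config.type_fractions)
    kinds_flat = ([CONTINUOUS] * n_cont + [DISCRETE] * n_disc + [CENSORED] * n_cens)
    assignment = rng.permutation(n)
    kind_of_idx = {}
    for slot, node_idx in enumerate(assignment):
        kind_of_idx[int(node_idx)] = kinds_flat[slot]

    counters = {CONTINUOUS: 0, DISCRETE: 0, CENSORED: 0}
    prefix = {CONTINUOUS: "C", DISCRETE: "D", CENSORED: "S"}
    names = []
    for i in range(n):
        k = kind_of_idx[i]
        counters[k] += 1
        names.append(f"{prefix[k]}{counters[k]}")
    kinds = {names[i]: kind_of_idx[i] for i in range(n)}

    dag = EndpointGraph(names, kinds, tag="dag")
    parents: dict[str, list[str]] = {v: [] for v in names}
    weights: dict[tuple[str, str], np.ndarray] = {}
    magnitudes: dict[tuple[str, str], float] = {}
    low, high = config.coef_range
    L = config.n_levels
    contrast = np.linspace(-1.0, 1.0, L)
    for i, j in edges:
        u, v = names[i], names[j]
        dag.add_edge(u, v, TAIL, ARROW)
        parents[v].append(u)
        w = float(rng.uniform(low, high)) * float(rng.choice((-1.0, 1.0)))
        magnitudes[(u, v)] = abs(w)
        if kinds[u] == DISCRETE:
            weights[(u, v)] = w * rng.permutation(contrast)
        else:
            weights[(u, v)] = np.asarray(w)
    return GroundTruthModel(dag=dag, parents=parents, weights=weights,
                            magnitudes=magnitudes, config=config, seed=config.seed)


def calibrate_censoring(event_times: np.ndarray, target_fraction: float,
                        tol: float = 1e-10) -> float:
    """Exponential censoring rate c with E[censored fraction] = target.

    ``event_times`` are draws (or the realized sample) of the event time T;
    for C ~ Exp(c) independent of T, P(T > C) = E[1 - exp(-c T)], which is
    continuous and increasing in c, so the root is found by bracketed
    root-finding with bound doubling.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target fraction must lie in (0, 1)")
    t = np.asarray(event_times, dtype=float)
    if t.size == 0 or np.any(t <= 0):
        raise ValueError("event times must be positive")

    def frac(c: float) -> float:
        return float(np.mean(-np.expm1(-c * t))) - target_fraction

    lo, hi = 1e-12, 1.0
    doublings = 0
    while frac(hi) < 0:
        hi *= 2.0
        doublings += 1
        if doublings > 200:
            raise RuntimeError("censoring-rate calibration failed to bracket the target")
    return float(brentq(frac, lo, hi, xtol=tol))


def _standardized(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def simulate_mixed_data(
    model: GroundTruthModel,
    n_samples: int | None = None,
    censoring: str | None = None,
    seed: int | None = None,
) -> tuple[MixedDataset, GroundTruthModel]:
    """Ancestral sampling from a ground-truth model.

    Returns the observed dataset (censored nodes as (time, event) pairs)
    together with the model.  Deterministic given ``seed`` (defaults to the
    model's own seed).
    """
    cfg = model.config
    n = int(n_samples if n_samples is not None else cfg.n_samples)
    if n < 1:
        raise ValueError("n_samples must be >= 1")
    cond = censoring if censoring is not None else cfg.censoring
    if cond not in CENSORING_TARGETS:
        raise ValueError(f"unknown censoring condition {cond!r}")
    base_seed = model.seed if seed is None else seed
    node_index = {v: i for i, v in enumerate(model.dag.nodes)}

    def node_rng(v: str) -> np.random.Generator:
        # per-node substream: the draw for a node never depends on the
        # order its ancestors were processed in
        return np.random.default_rng(
            np.random.SeedSequence(entropy=base_seed, spawn_key=(1, node_index[v])))

    kinds = model.node_kinds
    order = model.dag.topological_order()
    L = cfg.n_levels
    contrast = np.linspace(-1.0, 1.0, L)
    latent: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    obs_time: dict[str, np.ndarray] = {}
    obs_event: dict[str, np.ndarray] = {}

    for v in order:
        contrib = np.zeros(n)
        for u in model.parents[v]:
            w = model.weights[(u, v)]
            if kinds[u] == DISCRETE:
                contrib = contrib + w[codes[u]]
            else:
                contrib = contrib + float(w) * latent[u]
        kv = kinds[v]
        rng = node_rng(v)
        if kv == CONTINUOUS:
            val = contrib + rng.standard_normal(n)
            latent[v] = val
        elif kv == DISCRETE:
            scores = contrast[None, :] * contrib[:, None]
            scores = scores - scores.max(axis=1, keepdims=True)
            p = np.exp(scores)
            p /= p.sum(axis=1, keepdims=True)
            u01 = rng.random(n)
            codes[v] = (p.cumsum(axis=1) < u01[:, None]).sum(axis=1)
        else:
            E = rng.exponential(1.0, size=n)
            T = (E * np.exp(-contrib)) ** (1.0 / cfg.weibull_shape)
            if cond == "none":
                obs_time[v] = T
                obs_event[v] = np.ones(n, dtype=np.int64)
            else:
                rate = calibrate_censoring(T, CENSORING_TARGETS[cond])
                C = rng.exponential(1.0 / rate, size=n)
                obs_time[v] = np.minimum(T, C)
                obs_event[v] = (T <= C).astype(np.int64)
            latent[v] = _standardized(-np.log(T))

    cont_names = [v for v in model.dag.nodes if kinds[v] == CONTINUOUS]
    disc_names = [v for v in model.dag.nodes if kinds[v] == DISCRETE]
    cens_names = [v for v in model.dag.nodes if kinds[v] == CENSORED]
    level_names = tuple(f"l{i}" for i in range(L))
    ds = MixedDataset(
        sample_ids=[str(i) for i in range(n)],
        continuous=(np.column_stack([latent[v] for v in cont_names])
                    if cont_names else np.empty((n, 0))),
        discrete=(np.column_stack([codes[v] for v in disc_names])
                  if disc_names else np.empty((n, 0), dtype=np.int64)),
        times=(np.column_stack([obs_time[v] for v in cens_names])
               if cens_names else np.empty((n, 0))),
        events=(np.column_stack([obs_event[v] for v in cens_names])
                if cens_names else np.empty((n, 0), dtype=np.int64)),
        continuous_names=cont_names,
        discrete_names=disc_names,
        censored_names=cens_names,
        levels=[level_names] * len(disc_names),
    )
    return ds, model
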