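"""Graph-recovery evaluation: confusion matrices, F1, AUPRC, SHD.

Orientation accuracy and structural Hamming distance are measured against
the Markov equivalence class (CPDAG) of the true DAG, not the raw DAG:
observational data cannot distinguish Markov-equivalent orientations, so
an estimator is not penalized for leaving a reversible edge undirected.

Edge classes restrict pair universes by endpoint kinds: CC (both
continuous), CD (continuous-discrete), DD, SC (continuous-censored), SD
(discrete-censored), SS (both censored), and ALL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

from .causal import meek_closure
from .datamodel import CENSORED, CONTINUOUS, DISCRETE
from .graphs import ARROW, TAIL, EndpointGraph

__all__ = [
    "MetricsReport",
    "dag_to_cpdag",
    "adjacency_confusion",
    "orientation_confusion",
    "pr_curve_auprc",
    "shd",
    "evaluate_run",
    "EDGE_CLASS_NAMES",
]

EDGE_CLASS_NAMES = ("ALL", "CC", "CD", "DD", "SC", "SD", "SS")

_PAIR_CLASS = {
    frozenset((CONTINUOUS,)): "CC",
    frozenset((CONTINUOUS, DISCRETE)): "CD",
    frozenset((DISCRETE,)): "DD",
    frozenset((CONTINUOUS, CENSORED)): "SC",
    frozenset((DISCRETE, CENSORED)): "SD",
    frozenset((CENSORED,)): "SS",
}


def pair_class(g: EndpointGraph, u: str, v: str) -> str:
    ku = g.kinds.get(u)
    kv = g.kinds.get(v)
    if ku is None or kv is None:
        return "ALL"
    return _PAIR_CLASS[frozenset((ku, kv))]


def dag_to_cpdag(dag: EndpointGraph) -> EndpointGraph:
    """Canonical CPDAG of a DAG: skeleton plus compelled orientations.

    Orient the v-structures of the DAG, then close under Meek's rules; two
    Markov-equivalent DAGs map to the identical CPDAG.
    """
    dag.topological_order()          # raises on cycles
    g = dag.skeleton()
    g.tag = "cpdag"
    for z in dag.nodes:
        pa = sorted(dag.parents(z))
        for x, y in combinations(pa, 2):
            if not dag.has_edge(x, y):
                g.set_mark(x, z, ARROW)
                g.set_mark(y, z, ARROW)
                g.set_mark(z, x, TAIL)
                g.set_mark(z, y, TAIL)
    return meek_closure(g)


@dataclass
class Confusion:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
                "precision": self.precision, "recall": self.recall, "F1": self.f1}


def _check_nodes(est: EndpointGraph, truth: EndpointGraph) -> None:
    if set(est.nodes) != set(truth.nodes):
        raise ValueError("estimated and true graphs have different node sets")


def adjacency_confusion(est: EndpointGraph, truth_dag: EndpointGraph,
                        edge_class: str = "ALL") -> Confusion:
    """Adjacency TP/FP/TN/FN over unordered pairs of the given class."""
    _check_nodes(est, truth_dag)
    c = Confusion()
    for u, v in combinations(sorted(truth_dag.nodes), 2):
        if edge_class != "ALL" and pair_class(truth_dag, u, v) != edge_class:
            continue
        in_t = truth_dag.has_edge(u, v)
        in_e = est.has_edge(u, v)
        if in_t and in_e:
            c.tp += 1
        elif in_e:
            c.fp += 1
        elif in_t:
            c.fn += 1
        else:
            c.tn += 1
    return c


def _marks_match(est: EndpointGraph, mec: EndpointGraph, u: str, v: str) -> bool:
    return (est.mark_at(u, v) == mec.mark_at(u, v)
            and est.mark_at(v, u) == mec.mark_at(v, u))


def _est_asserts_orientation(est: EndpointGraph, u: str, v: str) -> bool:
    """True when the estimate commits to an orientation (any arrowhead)."""
    return ARROW in (est.mark_at(u, v), est.mark_at(v, u))


def orientation_confusion(est: EndpointGraph, truth_dag: EndpointGraph,
                          edge_class: str = "ALL") -> Confusion:
    """Orientation accuracy over pairs adjacent in both est and the MEC.

    TP: the estimate reproduces the marks of a compelled (directed) MEC
    edge.  FP: the estimate asserts an orientation that contradicts the
    MEC's marks (including orienting a reversible edge).  FN: a compelled
    MEC edge the estimate leaves unoriented or mis-oriented.  Circle marks
    count as unoriented unless both endpoints match.
    """
    _check_nodes(est, truth_dag)
    mec = truth_dag if truth_dag.tag == "cpdag" else dag_to_cpdag(truth_dag)
    c = Confusion()
    for u, v in combinations(sorted(mec.nodes), 2):
        if edge_class != "ALL" and pair_class(mec, u, v) != edge_class:
            continue
        if not (mec.has_edge(u, v) and est.has_edge(u, v)):
            continue
        match = _marks_match(est, mec, u, v)
        compelled = ARROW in (mec.mark_at(u, v), mec.mark_at(v, u))
        if match and compelled:
            c.tp += 1
        elif match:
            c.tn += 1               # reversible edge correctly left unoriented
        else:
            if _est_asserts_orientation(est, u, v):
                c.fp += 1
            if compelled:
                c.fn += 1
    return c


def pr_curve_auprc(points: list[tuple[float, float]]) -> float:
    """Area under a precision-recall curve by trapezoidal integration.

    Points are (recall, precision).  The curve is anchored at
    (0, precision of the lowest-recall point) and never extrapolated past
    the largest achieved recall; the area is reported on the full [0, 1]
    recall scale (conservative when max recall < 1).
    """
    if not points:
        raise ValueError("empty precision-recall point list")
    pts = sorted((float(r), float(p)) for r, p in points)
    for r, p in pts:
        if not (0 <= r <= 1 and 0 <= p <= 1):
            raise ValueError("recall and precision must lie in [0, 1]")
    pts = [(0.0, pts[0][1])] + pts
    area = 0.0
    for (r0, p0), (r1, p1) in zip(pts, pts[1:]):
        area += (r1 - r0) * (p0 + p1) / 2.0
    return float(area)


def shd(est: EndpointGraph, truth_dag: EndpointGraph) -> tuple[int, float]:
    """Structural Hamming distance from the MEC of the true DAG.

    +1 per missing adjacency, +1 per extra adjacency, +1 per shared
    adjacency whose endpoint marks differ.  Normalized by the MEC's edge
    count.
    """
    _check_nodes(est, truth_dag)
    mec = truth_dag if truth_dag.tag == "cpdag" else dag_to_cpdag(truth_dag)
    dist = 0
    for u, v in combinations(sorted(mec.nodes), 2):
        in_m = mec.has_edge(u, v)
        in_e = est.has_edge(u, v)
        if in_m != in_e:
            dist += 1
        elif in_m and not _marks_match(est, mec, u, v):
            dist += 1
    denom = max(mec.n_edges, 1)
    return dist, dist / denom


@dataclass
class MetricsReport:
    adjacency: dict[str, dict]
    orientation: dict[str, dict]
    shd: int
    normalized_shd: float
    pr_points: list[tuple[float, float]] | None = None
    auprc: float | None = None

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "adjacency": self.adjacency,
            "orientation": self.orientation,
            "shd": self.shd,
            "normalized_shd": self.normalized_shd,
            "pr_points": self.pr_points,
            "auprc": self.auprc,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        d = json.loads(text)
        pr = [tuple(p) for p in d["pr_points"]] if d.get("pr_points") else None
        return cls(adjacency=d["adjacency"], orientation=d["orientation"],
                   shd=d["shd"], normalized_shd=d["normalized_shd"],
                   pr_points=pr, auprc=d.get("auprc"))


def evaluate_run(est: EndpointGraph, truth_dag: EndpointGraph,
                 pr_points: list[tuple[float, float]] | None = None) -> MetricsReport:
    """Assemble adjacency/orientation confusions for every edge class plus SHD."""
    adjacency = {}
    orientation = {}
    for cls in EDGE_CLASS_NAMES:
        adjacency[cls] = adjacency_confusion(est, truth_dag, cls).as_dict()
        orientation[cls] = orientation_confusion(est, truth_dag, cls).as_dict()
    d, dn = shd(est, truth_dag)
    auprc = pr_curve_auprc(pr_points) if pr_points else None
    return MetricsReport(adjacency=adjacency, orientation=orientation,
                         shd=d, normalized_shd=dn, pr_points=pr_points, auprc=auprc)
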