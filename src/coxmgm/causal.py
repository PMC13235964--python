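"""Constraint-based orientation of a mixed-graphical-model skeleton.

The pipeline prunes an initial undirected adjacency estimate with
PC-Stable (order-independent, frozen adjacency sets per depth), orients
unshielded colliders by the majority rule over all separating sets found
within the frozen neighbourhoods (MPC-Stable), and completes orientations
with Meek's rules.  An FCI variant with possible-D-SEP pruning and Zhang's
complete orientation ruleset produces a partial ancestral graph robust to
latent confounders.

All conditional-independence decisions go through a caching tester so that
alpha sweeps and majority voting re-use p-values; an exact d-separation
tester over a known DAG can be substituted for the data-driven test to
check the algorithms' oracle behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from .citest import CITestConfig, ci_test
from .datamodel import MixedDataset
from .graphs import ARROW, CIRCLE, TAIL, EndpointGraph

__all__ = [
    "SepsetMap",
    "CachingTester",
    "DSeparationOracle",
    "pc_stable_skeleton",
    "orient_colliders_majority",
    "meek_closure",
    "fci",
    "markov_blanket",
    "causal_cox_mgm",
    "CausalConfig",
]

logger = logging.getLogger(__name__)


class SepsetMap:
    """Separating sets found per unordered node pair, with p-values."""

    def __init__(self) -> None:
        self._map: dict[frozenset, list[tuple[frozenset, float]]] = {}

    def record(self, x: str, y: str, S: frozenset, p: float) -> None:
        if x in S or y in S:
            raise ValueError("separating set must exclude its endpoints")
        entry = self._map.setdefault(frozenset((x, y)), [])
        if all(S != s for s, _ in entry):
            entry.append((S, p))

    def get(self, x: str, y: str) -> list[tuple[frozenset, float]]:
        return list(self._map.get(frozenset((x, y)), []))

    def has(self, x: str, y: str) -> bool:
        return frozenset((x, y)) in self._map


class CachingTester:
    """Wraps :func:`coxmgm.citest.ci_test` with a (pair, S) p-value cache."""

    def __init__(self, data: MixedDataset, config: CITestConfig | None = None):
        self.data = data
        self.config = config or CITestConfig()
        self.cache: dict[tuple[frozenset, frozenset], float] = {}
        self.n_failures = 0

    def __call__(self, x: str, y: str, S: frozenset) -> float:
        key = (frozenset((x, y)), frozenset(S))
        if key not in self.cache:
            try:
                self.cache[key] = ci_test(x, y, S, self.data, self.config).p_value
            except Exception as exc:  # conservative: failures look dependent
                logger.warning("CI test failed for (%s, %s | %s): %s", x, y, set(S), exc)
                self.n_failures += 1
                self.cache[key] = 0.0
        return self.cache[key]


class DSeparationOracle:
    """Exact d-separation tester over a known DAG (bitmask reachability).

    Callable with the same signature as :class:`CachingTester`; returns 1.0
    when x and y are d-separated by S among the *observed* nodes and 0.0
    otherwise.  ``latent`` nodes take part in the separation computation but
    may not be queried directly, which turns the oracle into an
    m-separation oracle over the latent projection.
    """

    def __init__(self, dag: EndpointGraph, latent: set[str] | None = None):
        self.dag = dag
        self.latent = set(latent or ())
        self._ix = {v: i for i, v in enumerate(dag.nodes)}
        n = len(dag.nodes)
        self._pa = [0] * n
        for v in dag.nodes:
            mask = 0
            for u in dag.parents(v):
                mask |= 1 << self._ix[u]
            self._pa[self._ix[v]] = mask
        self.observed = [v for v in dag.nodes if v not in self.latent]

    def __call__(self, x: str, y: str, S: frozenset) -> float:
        if {x, y} & self.latent or set(S) & self.latent:
            raise ValueError("latent nodes cannot be queried")
        return 1.0 if self.d_separated(x, y, S) else 0.0

    def d_separated(self, x: str, y: str, S: frozenset) -> bool:
        ix, pa = self._ix, self._pa
        n = len(self.dag.nodes)
        # ancestral closure of {x, y} | S
        target = (1 << ix[x]) | (1 << ix[y])
        for s in S:
            target |= 1 << ix[s]
        anc = target
        while True:
            new = anc
            for i in range(n):
                if (anc >> i) & 1:
                    new |= pa[i]
            if new == anc:
                break
            anc = new
        # moralize within the ancestral set
        adj = [0] * n
        for i in range(n):
            if not (anc >> i) & 1:
                continue
            ps = pa[i] & anc
            adj[i] |= ps
            js = ps
            while js:
                j = (js & -js).bit_length() - 1
                js &= js - 1
                adj[j] |= 1 << i
                adj[j] |= ps & ~(1 << j)
        # remove S and check connectivity
        smask = 0
        for s in S:
            smask |= 1 << ix[s]
        avail = anc & ~smask
        frontier = 1 << ix[x]
        reach = frontier
        while frontier:
            nxt = 0
            fs = frontier
            while fs:
                i = (fs & -fs).bit_length() - 1
                fs &= fs - 1
                nxt |= adj[i] & avail
            frontier = nxt & ~reach
            reach |= frontier
        return not (reach >> ix[y]) & 1


# ---------------------------------------------------------------------------
# PC-Stable skeleton


def pc_stable_skeleton(
    init: EndpointGraph,
    tester,
    alpha: float = 0.05,
    max_depth: int = 3,
) -> tuple[EndpointGraph, SepsetMap]:
    """Order-independent adjacency pruning.

    At each depth d the adjacency sets are frozen; an edge (x, y) is removed
    as soon as some conditioning set of size d drawn from either frozen
    neighbourhood yields p > alpha.  Every separating set found is recorded.
    """
    g = init.skeleton()
    sepsets = SepsetMap()
    depth = 0
    while True:
        adj_frozen = {v: sorted(g.neighbors(v)) for v in g.nodes}
        if max_depth is not None and depth > max_depth:
            break
        if all(len(adj_frozen[v]) - 1 < depth for v in g.nodes):
            break
        for u, v, _, _ in g.edges():
            if not g.has_edge(u, v):
                continue
            removed = False
            for a, b in ((u, v), (v, u)):
                candidates = [w for w in adj_frozen[a] if w != b]
                if len(candidates) < depth:
                    continue
                for S in combinations(candidates, depth):
                    p = tester(u, v, frozenset(S))
                    if p > alpha:
                        sepsets.record(u, v, frozenset(S), p)
                        if not removed:
                            g.remove_edge(u, v)
                            removed = True
                        break
                if removed:
                    break
            # edge retained at this depth otherwise
        depth += 1
    return g, sepsets


def _all_separating_sets(
    g: EndpointGraph, x: str, y: str, tester, alpha: float, max_depth: int
) -> list[frozenset]:
    """Exhaustive re-testing within the (final) adjacency sets of x and y."""
    found: set[frozenset] = set()
    for a, b in ((x, y), (y, x)):
        candidates = sorted(g.neighbors(a) - {b})
        for d in range(0, min(len(candidates), max_depth) + 1):
            for S in combinations(candidates, d):
                fs = frozenset(S)
                if fs in found:
                    continue
                if tester(x, y, fs) > alpha:
                    found.add(fs)
    return sorted(found, key=lambda s: (len(s), sorted(s)))


def _unshielded_triples(g: EndpointGraph):
    for z in g.nodes:
        nbrs = sorted(g.neighbors(z))
        for x, y in combinations(nbrs, 2):
            if not g.has_edge(x, y):
                yield x, z, y


def orient_colliders_majority(
    skeleton: EndpointGraph,
    sepsets: SepsetMap,
    tester,
    alpha: float = 0.05,
    max_depth: int = 3,
    circle_marks: bool = False,
) -> EndpointGraph:
    """Majority-rule v-structure orientation (MPC-Stable).

    A triple x - z - y with x, y nonadjacent becomes a collider x -> z <- y
    iff z appears in fewer than half of all separating sets of (x, y) found
    by exhaustive re-testing within the skeleton neighbourhoods.  An exact
    50/50 split leaves the triple unoriented (logged as ambiguous).
    """
    g = skeleton.copy()
    if circle_marks:
        for u, v, _, _ in g.edges():
            g.set_mark(u, v, CIRCLE)
            g.set_mark(v, u, CIRCLE)
        g.tag = "pag"
    else:
        g.tag = "cpdag"
    for x, z, y in _unshielded_triples(g):
        seps = _all_separating_sets(skeleton, x, y, tester, alpha, max_depth)
        if not seps:
            logger.warning("no separating set found for nonadjacent pair (%s, %s); "
                           "triple (%s, %s, %s) skipped", x, y, x, z, y)
            continue
        frac = sum(1 for S in seps if z in S) / len(seps)
        if frac < 0.5:
            g.set_mark(x, z, ARROW)
            g.set_mark(y, z, ARROW)
        elif frac == 0.5:
            logger.info("ambiguous collider (%s, %s, %s): z in exactly half of "
                        "separating sets", x, z, y)
    return g


# ---------------------------------------------------------------------------
# Meek closure (CPDAG completion)


def _meek_pass(g: EndpointGraph) -> bool:
    changed = False
    for u, v, _, _ in list(g.edges()):
        for a, b in ((u, v), (v, u)):
            if not g.has_edge(a, b) or not g.is_undirected(a, b):
                continue
            # R1: c -> a, a - b, c and b nonadjacent  =>  a -> b
            if any(g.is_directed(c, a) and not g.has_edge(c, b)
                   for c in g.neighbors(a) if c != b):
                _orient(g, a, b)
                changed = True
                continue
            # R2: a -> c -> b with a - b  =>  a -> b
            if any(g.is_directed(a, c) and g.is_directed(c, b)
                   for c in g.neighbors(a) & g.neighbors(b)):
                _orient(g, a, b)
                changed = True
                continue
            # R3: a - c -> b, a - d -> b, c, d nonadjacent  =>  a -> b
            cands = [c for c in g.neighbors(a) & g.neighbors(b)
                     if g.is_undirected(a, c) and g.is_directed(c, b)]
            if any(not g.has_edge(c, d) for c, d in combinations(sorted(cands), 2)):
                _orient(g, a, b)
                changed = True
                continue
            # R4: a - c, c -> d, d -> b, b and c nonadjacent  =>  a -> b
            r4 = False
            for c in g.neighbors(a):
                if c == b or not g.is_undirected(a, c) or g.has_edge(c, b):
                    continue
                if any(g.is_directed(c, d) and g.is_directed(d, b)
                       for d in g.neighbors(c) & g.neighbors(b)):
                    r4 = True
                    break
            if r4:
                _orient(g, a, b)
                changed = True
    return changed


def _orient(g: EndpointGraph, a: str, b: str) -> None:
    g.set_mark(b, a, TAIL)
    g.set_mark(a, b, ARROW)


def meek_closure(g: EndpointGraph) -> EndpointGraph:
    """Apply Meek's orientation rules to a fixpoint; idempotent."""
    out = g.copy()
    while _meek_pass(out):
        pass
    return out


# ---------------------------------------------------------------------------
# FCI


def _possible_dsep(g: EndpointGraph, x: str) -> set[str]:
    """Nodes reachable from x along paths whose interior vertices are either
    colliders on the path or part of a triangle with their path neighbours."""
    out: set[str] = set()
    frontier = [(x, v) for v in g.neighbors(x)]
    visited = set(frontier)
    while frontier:
        new_frontier = []
        for prev, cur in frontier:
            out.add(cur)
            for nxt in g.neighbors(cur):
                if nxt == prev or (prev, nxt) == (x, x):
                    continue
                collider = g.has_arrow_into(prev, cur) and g.has_arrow_into(nxt, cur)
                triangle = g.has_edge(prev, nxt)
                if (collider or triangle) and (cur, nxt) not in visited and nxt != x:
                    visited.add((cur, nxt))
                    new_frontier.append((cur, nxt))
        frontier = new_frontier
    out.discard(x)
    return out


def _is_uncovered(g: EndpointGraph, path: list[str]) -> bool:
    return all(not g.has_edge(path[i], path[i + 2]) for i in range(len(path) - 2))


def _pd_edge(g: EndpointGraph, u: str, v: str) -> bool:
    """Edge traversable from u to v on a possibly-directed path."""
    return (g.has_edge(u, v) and g.mark_at(v, u) != ARROW
            and g.mark_at(u, v) != TAIL)


def _uncovered_pd_paths(g: EndpointGraph, a: str, target: str, circle_only: bool = False):
    """Yield uncovered possibly-directed (or circle) paths from a to target."""
    def edge_ok(u, v):
        if circle_only:
            return (g.has_edge(u, v) and g.mark_at(u, v) == CIRCLE
                    and g.mark_at(v, u) == CIRCLE)
        return _pd_edge(g, u, v)

    stack = [[a, v] for v in sorted(g.neighbors(a)) if edge_ok(a, v)]
    while stack:
        path = stack.pop()
        cur = path[-1]
        if cur == target and len(path) >= 3:
            yield path
            continue
        if cur == target:
            continue
        for nxt in sorted(g.neighbors(cur)):
            if nxt in path:
                continue
            if not edge_ok(cur, nxt):
                continue
            if len(path) >= 2 and g.has_edge(path[-2], nxt):
                continue                    # keep the path uncovered
            stack.append(path + [nxt])


def _zhang_pass(g: EndpointGraph, sepsets: SepsetMap, tester, alpha: float) -> bool:
    changed = False
    nodes = g.nodes

    def arrow_at(u, v):
        # arrowhead at v on edge u-v
        nonlocal changed
        if g.mark_at(u, v) != ARROW:
            g.set_mark(u, v, ARROW)
            changed = True

    def tail_at(u, v):
        # tail at v on edge u-v
        nonlocal changed
        if g.mark_at(u, v) != TAIL:
            g.set_mark(u, v, TAIL)
            changed = True

    # R1: a *-> b o-* c, a and c nonadjacent  =>  b -> c
    for b in nodes:
        nbrs = sorted(g.neighbors(b))
        for a in nbrs:
            if not g.has_arrow_into(a, b):
                continue
            for c in nbrs:
                if c == a or g.has_edge(a, c):
                    continue
                if g.mark_at(c, b) == CIRCLE:
                    tail_at(c, b)
                    arrow_at(b, c)
        # R2: (a -> b *-> c) or (a *-> b -> c), a *-o c  =>  a *-> c
        for a in nbrs:
            for c in nbrs:
                if a == c or not g.has_edge(a, c):
                    continue
                if g.mark_at(a, c) != CIRCLE:
                    continue
                ab_arr = g.has_arrow_into(a, b)
                ab_dir = ab_arr and g.mark_at(b, a) == TAIL
                bc_arr = g.has_arrow_into(b, c)
                bc_dir = bc_arr and g.mark_at(c, b) == TAIL
                if (ab_dir and bc_arr) or (ab_arr and bc_dir):
                    arrow_at(a, c)

    # R3: a *-> b <-* c, a *-o d o-* c, a and c nonadjacent, d *-o b  =>  d *-> b
    for d in nodes:
        for b in sorted(g.neighbors(d)):
            if g.mark_at(d, b) != CIRCLE:
                continue
            common = sorted(g.neighbors(d) & g.neighbors(b))
            hit = False
            for a, c in combinations(common, 2):
                if g.has_edge(a, c):
                    continue
                if (g.has_arrow_into(a, b) and g.has_arrow_into(c, b)
                        and g.mark_at(a, d) == CIRCLE and g.mark_at(c, d) == CIRCLE):
                    arrow_at(d, b)
                    hit = True
                    break
            if hit:
                continue

    # R4: discriminating paths
    changed |= _rule4(g, sepsets)

    # R5: uncovered circle path <a, c, ..., d, b> with a,d and b,c nonadjacent
    #     =>  a - b and every path edge undirected
    for a in nodes:
        for b in sorted(g.neighbors(a)):
            if not (g.mark_at(a, b) == CIRCLE and g.mark_at(b, a) == CIRCLE):
                continue
            for path in _uncovered_pd_paths(g, a, b, circle_only=True):
                c, d = path[1], path[-2]
                if g.has_edge(a, d) or g.has_edge(b, c):
                    continue
                for u, v in zip(path, path[1:]):
                    tail_at(u, v)
                    tail_at(v, u)
                tail_at(a, b)
                tail_at(b, a)
                break

    # R6: a - b o-* c  =>  tail at b on (b, c)
    for b in nodes:
        if any(g.is_undirected(a, b) for a in g.neighbors(b)):
            for c in sorted(g.neighbors(b)):
                if g.mark_at(c, b) == CIRCLE:
                    tail_at(c, b)

    # R7: a -o b o-* c, a and c nonadjacent  =>  tail at b on (b, c)
    for b in nodes:
        nbrs = sorted(g.neighbors(b))
        for a in nbrs:
            if not (g.mark_at(b, a) == TAIL and g.mark_at(a, b) == CIRCLE):
                continue
            for c in nbrs:
                if c == a or g.has_edge(a, c):
                    continue
                if g.mark_at(c, b) == CIRCLE:
                    tail_at(c, b)

    # R8 - R10 resolve a o-> c into a -> c
    for a in nodes:
        for c in sorted(g.neighbors(a)):
            if not (g.mark_at(a, c) == ARROW and g.mark_at(c, a) == CIRCLE):
                continue
            done = False
            # R8: a -> b -> c or a -o b -> c
            for b in g.neighbors(a) & g.neighbors(c):
                ab_ok = (g.is_directed(a, b)
                         or (g.mark_at(b, a) == TAIL and g.mark_at(a, b) == CIRCLE))
                if ab_ok and g.is_directed(b, c):
                    tail_at(c, a)
                    done = True
                    break
            if done:
                continue
            # R9: uncovered possibly-directed path <a, b, ..., c>, b,c nonadjacent
            for path in _uncovered_pd_paths(g, a, c):
                if not g.has_edge(path[1], c):
                    tail_at(c, a)
                    done = True
                    break
            if done:
                continue
            # R10: two uncovered pd paths from a to distinct nonadjacent
            #      parents of c whose first steps differ
            parents_c = [b for b in g.neighbors(c) if g.is_directed(b, c) and b != a]
            hit = False
            for b, d in combinations(sorted(parents_c), 2):
                paths_b = list(_uncovered_pd_paths(g, a, b)) + (
                    [[a, b]] if _pd_edge(g, a, b) else [])
                paths_d = list(_uncovered_pd_paths(g, a, d)) + (
                    [[a, d]] if _pd_edge(g, a, d) else [])
                for p1 in paths_b:
                    for p2 in paths_d:
                        mu, nu = p1[1], p2[1]
                        if mu != nu and not g.has_edge(mu, nu):
                            tail_at(c, a)
                            hit = True
                            break
                    if hit:
                        break
                if hit:
                    break
    return changed


def _rule4(g: EndpointGraph, sepsets: SepsetMap) -> bool:
    """Discriminating-path rule.

    For a path <theta, ..., a, b, c> where theta and c are nonadjacent and
    every interior vertex (between theta and b) is a collider on the path
    and a parent of c: if b lies in a majority of the recorded separating
    sets of (theta, c), b is a noncollider on the path (orient b -> c);
    otherwise orient a <-> b <-> c.
    """
    changed = False
    for c in g.nodes:
        for b in sorted(g.neighbors(c)):
            if g.mark_at(c, b) != CIRCLE:
                continue
            starts = [a for a in g.neighbors(b)
                      if a != c and g.has_arrow_into(a, b) and g.has_edge(a, c)
                      and g.is_directed(a, c)]
            stack = [[b, a] for a in starts]
            found = None
            while stack and found is None:
                path = stack.pop()
                cur = path[-1]
                for w in sorted(g.neighbors(cur)):
                    if w in path or w == c:
                        continue
                    if not g.has_arrow_into(w, cur):
                        continue
                    if not g.has_edge(w, c):
                        found = [w] + path[::-1] + [c]   # <theta, ..., a, b, c>
                        break
                    if g.has_arrow_into(cur, w) and g.is_directed(w, c):
                        stack.append(path + [w])
            if found is None:
                continue
            theta = found[0]
            seps = sepsets.get(theta, c)
            in_sep = sum(1 for S, _ in seps if b in S)
            if seps and in_sep * 2 > len(seps):
                # b is a noncollider: orient b -> c
                if g.mark_at(c, b) != TAIL or g.mark_at(b, c) != ARROW:
                    g.set_mark(c, b, TAIL)
                    g.set_mark(b, c, ARROW)
                    changed = True
            else:
                a = found[-3]
                for u, v in ((a, b), (b, c)):
                    if g.mark_at(u, v) != ARROW or g.mark_at(v, u) != ARROW:
                        g.set_mark(u, v, ARROW)
                        g.set_mark(v, u, ARROW)
                        changed = True
    return changed


def fci(
    init: EndpointGraph,
    tester,
    alpha: float = 0.05,
    max_depth: int = 3,
) -> EndpointGraph:
    """FCI: PC-Stable skeleton, possible-D-SEP pruning, majority collider
    orientation, and Zhang's orientation rules to a fixpoint (PAG output)."""
    skel, sepsets = pc_stable_skeleton(init, tester, alpha, max_depth)
    pre = orient_colliders_majority(skel, sepsets, tester, alpha, max_depth,
                                    circle_marks=True)
    # possible-D-SEP pruning
    for u, v, _, _ in list(pre.edges()):
        if not pre.has_edge(u, v):
            continue
        removed = False
        for a, b in ((u, v), (v, u)):
            pds = sorted(_possible_dsep(pre, a) - {a, b})
            for d in range(0, min(len(pds), max_depth) + 1):
                for S in combinations(pds, d):
                    p = tester(u, v, frozenset(S))
                    if p > alpha:
                        sepsets.record(u, v, frozenset(S), p)
                        pre.remove_edge(u, v)
                        removed = True
                        break
                if removed:
                    break
            if removed:
                break
    skel2 = pre.skeleton()
    g = orient_colliders_majority(skel2, sepsets, tester, alpha, max_depth,
                                  circle_marks=True)
    while _zhang_pass(g, sepsets, tester, alpha):
        pass
    g.tag = "pag"
    return g


# ---------------------------------------------------------------------------
# Markov blanket


def markov_blanket(g: EndpointGraph, node: str) -> set[str]:
    """Markov blanket of a node.

    DAG/CPDAG: possible parents, possible children, and possible co-parents
    of possible children (undirected edges count both ways).  PAG: adjacent
    nodes plus spouses through a common arrowhead child.
    """
    if node not in g.nodes:
        raise KeyError(f"unknown node {node!r}")
    mb = set(g.neighbors(node))
    if g.tag in ("dag", "cpdag", "skeleton"):
        possible_children = {c for c in g.neighbors(node)
                             if g.is_directed(node, c) or g.is_undirected(node, c)
                             or g.mark_at(node, c) == ARROW}
        for c in possible_children:
            for w in g.neighbors(c):
                if w == node:
                    continue
                if g.is_directed(w, c) or g.is_undirected(w, c):
                    mb.add(w)
    else:  # pag
        for c in g.neighbors(node):
            if g.mark_at(node, c) == ARROW:
                for w in g.neighbors(c):
                    if w != node and g.mark_at(w, c) == ARROW:
                        mb.add(w)
    mb.discard(node)
    return mb


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass(frozen=True)
class CausalConfig:
    alpha: float = 0.05
    max_depth: int = 3
    method: str = "mpc"              # or "fci"
    selection: str = "steps"         # "steps" | "stars" | "bic"
    path_length: int = 30
    subsamples: int = 20
    stability_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("mpc", "fci"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.selection not in ("steps", "stars", "bic"):
            raise ValueError(f"unknown selection {self.selection!r}")


def causal_cox_mgm(data: MixedDataset, config: CausalConfig | None = None,
                   penalties=None, profile_B: int | None = None) -> EndpointGraph:
    """Two-step pipeline: stability-selected CoxMGM skeleton, then
    constraint-based pruning and orientation (MPC-Stable or FCI)."""
    from .mgm import fit_coxmgm, params_to_graph, prepare_model_data
    from .selection import (bic_select, build_lambda_path, stability_profile,
                            stars_select, steps_select)

    config = config or CausalConfig()
    md = prepare_model_data(data)
    if penalties is None:
        path = build_lambda_path(md, K=config.path_length)
        if config.selection == "bic":
            penalties, _ = bic_select(md, path)
        else:
            profile = stability_profile(md, path,
                                        B=profile_B or config.subsamples,
                                        seed=config.seed)
            select = steps_select if config.selection == "steps" else stars_select
            penalties = select(profile, config.stability_threshold)
    fit = fit_coxmgm(md, penalties)
    init = params_to_graph(fit.params, md)
    tester = CachingTester(data, CITestConfig(alpha=config.alpha,
                                              max_cond_size=config.max_depth))
    if config.method == "fci":
        return fci(init, tester, config.alpha, config.max_depth)
    skel, sepsets = pc_stable_skeleton(init, tester, config.alpha, config.max_depth)
    cpdag = orient_colliders_majority(skel, sepsets, tester, config.alpha,
                                      config.max_depth)
    return meek_closure(cpdag)
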