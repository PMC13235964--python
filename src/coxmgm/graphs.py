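"""Endpoint-marked graphs: one container for skeletons, DAGs, CPDAGs, PAGs.

Every edge stores a mark at each endpoint, drawn from tail ``-``, arrow
``>``, circle ``o``.  Undirected edges are tail-tail, directed edges
tail-arrow, bidirected arrow-arrow, and partially oriented edges carry
circles.  In a partial ancestral graph a bidirected edge X <-> Y means X
and Y share a latent confounder, X o-> Y means Y is not a cause of X, and
X o-o Y leaves the orientation open.

The text format is one edge per line, e.g. ``A o-> B``, with a header line
listing all node names (so isolated nodes survive a round trip) and an
optional header of node kinds.
"""

from __future__ import annotations

from typing import Iterable

__all__ = ["EndpointGraph", "read_graph", "write_graph", "TAIL", "ARROW", "CIRCLE"]

TAIL = "-"
ARROW = ">"
CIRCLE = "o"
MARKS = (TAIL, ARROW, CIRCLE)

_LEFT = {TAIL: "-", ARROW: "<", CIRCLE: "o"}
_RIGHT = {TAIL: "-", ARROW: ">", CIRCLE: "o"}
_LEFT_INV = {v: k for k, v in _LEFT.items()}
_RIGHT_INV = {v: k for k, v in _RIGHT.items()}


class EndpointGraph:
    """Simple graph whose edges carry endpoint marks.

    Parameters
    ----------
    nodes : node names, order fixed (used for canonical edge storage)
    kinds : optional mapping node -> variable kind
    tag : one of {"skeleton", "dag", "cpdag", "pag"}
    """

    def __init__(self, nodes: Iterable[str], kinds: dict[str, str] | None = None,
                 tag: str = "skeleton"):
        self.nodes: list[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self.kinds: dict[str, str] = dict(kinds) if kinds else {}
        self.tag = tag
        self._ix = {v: i for i, v in enumerate(self.nodes)}
        # canonical key (u, v) with index(u) < index(v); value (mark_at_u, mark_at_v)
        self._edges: dict[tuple[str, str], tuple[str, str]] = {}
        self._adj: dict[str, set[str]] = {v: set() for v in self.nodes}

    # -- basic structure ------------------------------------------------
    def _key(self, u: str, v: str) -> tuple[tuple[str, str], bool]:
        if u not in self._ix or v not in self._ix:
            raise KeyError(f"unknown node in edge ({u!r}, {v!r})")
        if u == v:
            raise ValueError("self-loops are not allowed")
        return ((u, v), False) if self._ix[u] < self._ix[v] else ((v, u), True)

    def add_edge(self, u: str, v: str, mark_u: str = TAIL, mark_v: str = TAIL) -> None:
        """Add edge u-v with ``mark_u`` at u's end and ``mark_v`` at v's end."""
        if mark_u not in MARKS or mark_v not in MARKS:
            raise ValueError(f"unknown endpoint mark in ({mark_u!r}, {mark_v!r})")
        key, swapped = self._key(u, v)
        if key in self._edges:
            raise ValueError(f"duplicate edge {u}-{v}")
        self._edges[key] = (mark_v, mark_u) if swapped else (mark_u, mark_v)
        self._adj[u].add(v)
        self._adj[v].add(u)

    def add_directed(self, u: str, v: str) -> None:
        self.add_edge(u, v, TAIL, ARROW)

    def remove_edge(self, u: str, v: str) -> None:
        key, _ = self._key(u, v)
        del self._edges[key]
        self._adj[u].discard(v)
        self._adj[v].discard(u)

    def has_edge(self, u: str, v: str) -> bool:
        key, _ = self._key(u, v)
        return key in self._edges

    def neighbors(self, u: str) -> set[str]:
        return set(self._adj[u])

    def edges(self) -> list[tuple[str, str, str, str]]:
        """All edges as (u, v, mark_at_u, mark_at_v), canonical node order."""
        return [(u, v, mu, mv) for (u, v), (mu, mv) in sorted(self._edges.items())]

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    # -- endpoint marks --------------------------------------------------
    def mark_at(self, u: str, v: str) -> str:
        """Mark at ``v`` on the edge u-v."""
        key, swapped = self._key(u, v)
        mu, mv = self._edges[key]
        return mu if swapped else mv

    def set_mark(self, u: str, v: str, mark: str) -> None:
        """Set the mark at ``v`` on the edge u-v."""
        if mark not in MARKS:
            raise ValueError(f"unknown endpoint mark {mark!r}")
        key, swapped = self._key(u, v)
        mu, mv = self._edges[key]
        self._edges[key] = (mark, mv) if swapped else (mu, mark)

    def is_directed(self, u: str, v: str) -> bool:
        """True iff the edge is exactly u -> v (tail at u, arrow at v)."""
        return (self.has_edge(u, v) and self.mark_at(u, v) == ARROW
                and self.mark_at(v, u) == TAIL)

    def is_undirected(self, u: str, v: str) -> bool:
        return (self.has_edge(u, v) and self.mark_at(u, v) == TAIL
                and self.mark_at(v, u) == TAIL)

    def has_arrow_into(self, u: str, v: str) -> bool:
        """True iff edge u *-> v exists (arrowhead at v)."""
        return self.has_edge(u, v) and self.mark_at(u, v) == ARROW

    def parents(self, v: str) -> set[str]:
        return {u for u in self._adj[v] if self.is_directed(u, v)}

    def children(self, v: str) -> set[str]:
        return {u for u in self._adj[v] if self.is_directed(v, u)}

    def undirected_neighbors(self, v: str) -> set[str]:
        return {u for u in self._adj[v] if self.is_undirected(u, v)}

    # -- utilities -------------------------------------------------------
    def copy(self) -> "EndpointGraph":
        g = EndpointGraph(self.nodes, self.kinds, self.tag)
        g._edges = dict(self._edges)
        g._adj = {v: set(a) for v, a in self._adj.items()}
        return g

    def skeleton(self) -> "EndpointGraph":
        g = EndpointGraph(self.nodes, self.kinds, "skeleton")
        for (u, v) in self._edges:
            g.add_edge(u, v, TAIL, TAIL)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EndpointGraph):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and {
            frozenset(k): tuple(sorted(zip(k, m))) for k, m in self._edges.items()
        } == {
            frozenset(k): tuple(sorted(zip(k, m))) for k, m in other._edges.items()
        }

    def __hash__(self):  # pragma: no cover - graphs are mutable; identity hash
        return id(self)

    def topological_order(self) -> list[str]:
        """Topological order over directed edges; raises on a cycle."""
        indeg = {v: 0 for v in self.nodes}
        for (u, v), (mu, mv) in self._edges.items():
            if mv == ARROW and mu == TAIL:
                indeg[v] += 1
            elif mu == ARROW and mv == TAIL:
                indeg[u] += 1
        queue = [v for v in self.nodes if indeg[v] == 0]
        out: list[str] = []
        while queue:
            v = queue.pop(0)
            out.append(v)
            for c in sorted(self.children(v)):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(out) != len(self.nodes):
            raise ValueError("graph contains a directed cycle")
        return out

    @classmethod
    def complete(cls, nodes: Iterable[str], kinds: dict[str, str] | None = None
                 ) -> "EndpointGraph":
        g = cls(nodes, kinds, "skeleton")
        ns = g.nodes
        for i, u in enumerate(ns):
            for v in ns[i + 1:]:
                g.add_edge(u, v, TAIL, TAIL)
        return g


def _token(mu: str, mv: str) -> str:
    return f"{_LEFT[mu]}-{_RIGHT[mv]}"


def write_graph(g: EndpointGraph, path: str) -> None:
    """Write the edge-list text format; canonical order, smaller node first."""
    lines = ["#nodes:\t" + "\t".join(g.nodes)]
    if g.kinds:
        lines.append("#kinds:\t" + "\t".join(g.kinds.get(v, "?") for v in g.nodes))
    lines.append(f"#tag:\t{g.tag}")
    for u, v, mu, mv in g.edges():
        if v < u:
            u, v, mu, mv = v, u, mv, mu
        lines.append(f"{u} {_token(mu, mv)} {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_graph(path: str) -> EndpointGraph:
    """Parse the edge-list format written by :func:`write_graph`."""
    nodes: list[str] | None = None
    kinds: dict[str, str] = {}
    tag = "skeleton"
    edges: list[tuple[str, str, str, str]] = []
    seen_nodes: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#nodes:"):
                nodes = line.split("\t")[1:]
                continue
            if line.startswith("#kinds:"):
                kind_list = line.split("\t")[1:]
                if nodes is None or len(kind_list) != len(nodes):
                    raise ValueError(f"line {lineno}: #kinds does not match #nodes")
                kinds = {v: k for v, k in zip(nodes, kind_list) if k != "?"}
                continue
            if line.startswith("#tag:"):
                tag = line.split("\t")[1]
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: malformed edge line {line!r}")
            u, token, v = parts
            if len(token) != 3 or token[1] != "-" or token[0] not in _LEFT_INV \
                    or token[2] not in _RIGHT_INV:
                raise ValueError(f"line {lineno}: unknown edge token {token!r}")
            mu = _LEFT_INV[token[0]]
            mv = _RIGHT_INV[token[2]]
            edges.append((u, v, mu, mv))
            for w in (u, v):
                if w not in seen_nodes:
                    seen_nodes.append(w)
    if nodes is None:
        nodes = seen_nodes
    g = EndpointGraph(nodes, kinds, tag)
    for lineno_offset, (u, v, mu, mv) in enumerate(edges):
        try:
            g.add_edge(u, v, mu, mv)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"invalid edge {u} {v}: {exc}") from exc
    return g
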