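"""Graphs with endpoint marks, and SIF / Cytoscape JSON export.

An :class:`EndpointGraph` stores at most one edge per unordered node pair,
each edge carrying two endpoint marks in {tail, arrow}:

* tail–tail   — undirected edge (conditional dependence),
* tail–arrow  — directed edge (tail end is the source),
* arrow–arrow — conflicted/ambiguous edge (two collider orientations
  disagreed; neither is overwritten).

The SIF dialect used on export is ``dir`` / ``undir`` / ``conf`` for the
three edge kinds; isolated nodes are written as bare node-name lines, and
all lines are sorted so output is byte-deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

TAIL = "tail"
ARROW = "arrow"

_REL_TO_MARKS = {
    "undir": (TAIL, TAIL),
    "conf": (ARROW, ARROW),
}


class EndpointGraph:
    """Mixed graph over named nodes with tail/arrow endpoint marks."""

    def __init__(self, nodes: Iterable[str] = ()) -> None:
        self._nodes: dict[str, None] = {}
        # key: (u, v) with u < v lexicographically; value: (mark_u, mark_v)
        self._edges: dict[tuple[str, str], tuple[str, str]] = {}
        for n in nodes:
            self.add_node(n)

    # -- nodes -----------------------------------------------------------
    def add_node(self, name: str) -> None:
        if not isinstance(name, str) or not name:
            raise ValueError("node names must be non-empty strings")
        self._nodes[name] = None

    @property
    def nodes(self) -> list[str]:
        return sorted(self._nodes)

    def __contains__(self, name: str) -> bool:
        return name in self._nodes

    # -- edges -----------------------------------------------------------
    @staticmethod
    def _key(u: str, v: str) -> tuple[str, str]:
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        return (u, v) if u < v else (v, u)

    def add_edge(self, u: str, v: str, mark_u: str = TAIL, mark_v: str = TAIL) -> None:
        for m in (mark_u, mark_v):
            if m not in (TAIL, ARROW):
                raise ValueError(f"bad endpoint mark {m!r}")
        if u not in self._nodes or v not in self._nodes:
            raise KeyError(f"unknown node in edge {u!r}-{v!r}")
        a, b = self._key(u, v)
        marks = (mark_u, mark_v) if (u, v) == (a, b) else (mark_v, mark_u)
        self._edges[(a, b)] = marks

    def add_directed(self, src: str, dst: str) -> None:
        """Add (or reorient) the edge src -> dst."""
        self.add_edge(src, dst, TAIL, ARROW)

    def remove_edge(self, u: str, v: str) -> None:
        del self._edges[self._key(u, v)]

    def has_edge(self, u: str, v: str) -> bool:
        try:
            return self._key(u, v) in self._edges
        except ValueError:
            return False

    def mark_at(self, u: str, v: str, at: str) -> str:
        """Endpoint mark of edge u-v at node ``at`` (one of u, v)."""
        a, b = self._key(u, v)
        ma, mb = self._edges[(a, b)]
        if at == a:
            return ma
        if at == b:
            return mb
        raise ValueError(f"{at!r} is not an endpoint of {u!r}-{v!r}")

    def set_mark(self, u: str, v: str, at: str, mark: str) -> None:
        a, b = self._key(u, v)
        ma, mb = self._edges[(a, b)]
        if at == a:
            self._edges[(a, b)] = (mark, mb)
        elif at == b:
            self._edges[(a, b)] = (ma, mark)
        else:
            raise ValueError(f"{at!r} is not an endpoint of {u!r}-{v!r}")

    def edges(self) -> Iterator[tuple[str, str, str, str]]:
        """Yield (u, v, mark_u, mark_v) sorted by (u, v), u < v."""
        for (a, b) in sorted(self._edges):
            ma, mb = self._edges[(a, b)]
            yield a, b, ma, mb

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edge_kind(self, u: str, v: str) -> str:
        """'undir', 'dir', or 'conf' for the edge u-v."""
        a, b = self._key(u, v)
        ma, mb = self._edges[(a, b)]
        if ma == TAIL and mb == TAIL:
            return "undir"
        if ma == ARROW and mb == ARROW:
            return "conf"
        return "dir"

    def is_directed_edge(self, src: str, dst: str) -> bool:
        """True iff the edge src -> dst exists with tail at src, arrow at dst."""
        if not self.has_edge(src, dst):
            return False
        return self.mark_at(src, dst, src) == TAIL and self.mark_at(src, dst, dst) == ARROW

    def is_undirected_edge(self, u: str, v: str) -> bool:
        return self.has_edge(u, v) and self.edge_kind(u, v) == "undir"

    def adjacent(self, node: str) -> list[str]:
        out = []
        for (a, b) in self._edges:
            if a == node:
                out.append(b)
            elif b == node:
                out.append(a)
        return sorted(out)

    def skeleton_edges(self) -> set[frozenset]:
        return {frozenset(k) for k in self._edges}

    # -- conversions -----------------------------------------------------
    def directed_subgraph(self) -> nx.DiGraph:
        """networkx DiGraph of the fully directed (tail->arrow) edges."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v, mu, mv in self.edges():
            if mu == TAIL and mv == ARROW:
                g.add_edge(u, v)
            elif mu == ARROW and mv == TAIL:
                g.add_edge(v, u)
        return g

    def copy(self) -> "EndpointGraph":
        g = EndpointGraph(self._nodes)
        g._edges = dict(self._edges)
        return g

    def relabel(self, mapping: dict[str, str]) -> "EndpointGraph":
        g = EndpointGraph(mapping.get(n, n) for n in self._nodes)
        for u, v, mu, mv in self.edges():
            g.add_edge(mapping.get(u, u), mapping.get(v, v), mu, mv)
        return g

    # -- equality / repr -------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, EndpointGraph):
            return NotImplemented
        return set(self._nodes) == set(other._nodes) and self._edges == other._edges

    def __hash__(self):  # graphs are mutable; identity hash
        return id(self)

    def __repr__(self) -> str:
        return f"EndpointGraph({len(self._nodes)} nodes, {len(self._edges)} edges)"


def complete_graph(nodes: Iterable[str]) -> EndpointGraph:
    g = EndpointGraph(nodes)
    ns = g.nodes
    for i, u in enumerate(ns):
        for v in ns[i + 1:]:
            g.add_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# SIF
# ---------------------------------------------------------------------------

def _sif_lines(graph: EndpointGraph) -> list[str]:
    lines = []
    connected: set[str] = set()
    for u, v, mu, mv in graph.edges():
        connected.update((u, v))
        kind = graph.edge_kind(u, v)
        if kind == "dir":
            src, dst = (u, v) if mu == TAIL else (v, u)
            lines.append(f"{src}\tdir\t{dst}")
        else:
            lines.append(f"{u}\t{kind}\t{v}")
    for n in graph.nodes:
        if n not in connected:
            lines.append(n)
    return sorted(lines)


def write_sif(graph: EndpointGraph, path: str | Path) -> None:
    """Write the graph in Cytoscape simple-interaction format.

    One tab-separated ``source relation target`` line per edge with relation
    ``dir`` (source is the tail end), ``undir`` or ``conf``; isolated nodes
    become bare node-name lines.  Lines are sorted lexicographically.
    """
    Path(path).write_text("".join(line + "\n" for line in _sif_lines(graph)))


def read_sif(path: str | Path) -> EndpointGraph:
    g = EndpointGraph()
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) == 1:
            g.add_node(parts[0])
        elif len(parts) == 3:
            src, rel, dst = parts
            g.add_node(src)
            g.add_node(dst)
            if rel == "dir":
                g.add_directed(src, dst)
            elif rel in _REL_TO_MARKS:
                g.add_edge(src, dst, *_REL_TO_MARKS[rel])
            else:
                raise ValueError(f"unknown SIF relation {rel!r}")
        else:
            raise ValueError(f"malformed SIF line {raw!r}")
    return g


# ---------------------------------------------------------------------------
# Cytoscape JSON (elements format)
# ---------------------------------------------------------------------------

def write_cytoscape_json(graph: EndpointGraph, path: str | Path) -> None:
    """Write the graph as a Cytoscape.js elements document.

    Nodes are ``{"data": {"id": name}}``; edges carry ``source`` (tail end
    for directed edges), ``target`` and ``interaction`` in
    {dir, undir, conf}.  Ordering matches :func:`write_sif`.
    """
    nodes = [{"data": {"id": n}} for n in graph.nodes]
    edges = []
    for u, v, mu, mv in graph.edges():
        kind = graph.edge_kind(u, v)
        if kind == "dir":
            src, dst = (u, v) if mu == TAIL else (v, u)
        else:
            src, dst = u, v
        edges.append({
            "data": {
                "id": f"{src} ({kind}) {dst}",
                "source": src,
                "target": dst,
                "interaction": kind,
            }
        })
    edges.sort(key=lambda e: e["data"]["id"])
    doc = {"elements": {"nodes": nodes, "edges": edges}}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_cytoscape_json(path: str | Path) -> EndpointGraph:
    doc = json.loads(Path(path).read_text())
    g = EndpointGraph()
    for nd in doc["elements"]["nodes"]:
        g.add_node(nd["data"]["id"])
    for ed in doc["elements"]["edges"]:
        d = ed["data"]
        src, dst, rel = d["source"], d["target"], d["interaction"]
        if rel == "dir":
            g.add_directed(src, dst)
        elif rel in _REL_TO_MARKS:
            g.add_edge(src, dst, *_REL_TO_MARKS[rel])
        else:
            raise ValueError(f"unknown interaction {rel!r}")
    return g
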