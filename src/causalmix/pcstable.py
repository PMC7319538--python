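"""Order-independent constraint-based orientation (PC-Stable).

The skeleton phase prunes an initial undirected graph — here typically the
mixed-graphical-model graph rather than the complete graph — by
conditional-independence tests of increasing conditioning-set size.  All
adjacency sets are snapshotted at the start of each depth, and both subset
enumeration and the candidate edge list use the snapshots, so the result
does not depend on variable order.  Orientation then (i) directs the
unshielded triples X–Z–Y whose separating set excludes Z as colliders
X→Z←Y, turning contradictory demands into explicit arrow–arrow
("conflicted") edges instead of overwriting, and (ii) propagates
orientations with the Meek rules R1–R3 (no new colliders, no directed
cycles) to a fixed point.

Assumptions for a causal reading of the output: acyclicity, the causal
Markov condition, faithfulness, and causal sufficiency (no unobserved
confounders or selection bias).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import networkx as nx
from sklearn.base import BaseEstimator

from .citests import ci_test
from .dataset import MixedDataset, as_mixed_dataset
from .graph import ARROW, TAIL, EndpointGraph, complete_graph
from .mgm import LambdaTriple, fit_mgm, extract_graph
from .steps import StabilityProfile, steps_select

SepsetTable = dict[frozenset, tuple[str, ...]]


@dataclass
class PCConfig:
    """PC-Stable settings."""

    alpha: float = 0.05
    max_depth: int | None = None
    initial_graph: EndpointGraph | None = None

    def validate(self) -> "PCConfig":
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        return self


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------

def pcs_skeleton(
    dataset: MixedDataset,
    config: PCConfig | None = None,
    test: Callable = ci_test,
) -> tuple[EndpointGraph, SepsetTable, int]:
    """Depth-wise edge pruning with start-of-depth adjacency snapshots.

    Returns the pruned skeleton, the separating-set table, and the number
    of tests performed.  Conditioning subsets are enumerated in
    lexicographic order from both endpoints' snapshot neighborhoods; the
    first separating set found is recorded.
    """
    config = (config or PCConfig()).validate()
    if config.initial_graph is None:
        g = complete_graph(dataset.names)
    else:
        if set(config.initial_graph.nodes) != set(dataset.names):
            raise ValueError("initial graph nodes must match dataset variables")
        g = config.initial_graph.copy()
        for u, v, _, _ in list(g.edges()):  # skeleton phase ignores marks
            g.add_edge(u, v, TAIL, TAIL)

    sepsets: SepsetTable = {}
    n_tests = 0
    depth = 0
    while True:
        snapshot = {node: g.adjacent(node) for node in g.nodes}
        if all(len(nb) < depth + 1 for nb in snapshot.values()):
            break
        if config.max_depth is not None and depth > config.max_depth:
            break
        edges = [(u, v) for u, v, _, _ in g.edges()]
        for x, y in edges:
            adj_x = [v for v in snapshot[x] if v != y]
            adj_y = [v for v in snapshot[y] if v != x]
            seen: set[tuple[str, ...]] = set()
            removed = False
            for pool in (adj_x, adj_y):
                if len(pool) < depth:
                    continue
                for S in combinations(pool, depth):  # pools sorted => lexicographic
                    if S in seen:
                        continue
                    seen.add(S)
                    res = test(dataset, x, y, S, alpha=config.alpha)
                    n_tests += 1
                    if res.independent:
                        g.remove_edge(x, y)
                        sepsets[frozenset((x, y))] = S
                        removed = True
                        break
                if removed:
                    break
        depth += 1
    return g, sepsets, n_tests


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def complete_sepsets(
    dataset: MixedDataset,
    skeleton: EndpointGraph,
    sepsets: SepsetTable,
    alpha: float = 0.05,
    max_depth: int | None = None,
    test: Callable = ci_test,
) -> tuple[SepsetTable, int]:
    """Fill in separating sets for unshielded-triple endpoint pairs that
    were nonadjacent from the start (e.g. absent from the MGM seed graph)
    and therefore never tested during pruning.

    Candidate sets are enumerated exactly as in the skeleton phase
    (increasing size, lexicographic, from both endpoints' adjacencies); the
    first separating set found is recorded.  Pairs for which no separating
    set exists stay absent, and the corresponding triples are left
    unoriented.  Returns the augmented table and the test count.
    """
    out = dict(sepsets)
    n_tests = 0
    pending: set[frozenset] = set()
    for z in skeleton.nodes:
        adj = skeleton.adjacent(z)
        for x, y in combinations(adj, 2):
            key = frozenset((x, y))
            if not skeleton.has_edge(x, y) and key not in out:
                pending.add(key)
    for key in sorted(pending, key=sorted):
        x, y = sorted(key)
        adj_x = [v for v in skeleton.adjacent(x) if v != y]
        adj_y = [v for v in skeleton.adjacent(y) if v != x]
        limit = max(len(adj_x), len(adj_y))
        if max_depth is not None:
            limit = min(limit, max_depth)
        found = False
        for depth in range(limit + 1):
            seen: set[tuple[str, ...]] = set()
            for pool in (adj_x, adj_y):
                if len(pool) < depth:
                    continue
                for S in combinations(pool, depth):
                    if S in seen:
                        continue
                    seen.add(S)
                    res = test(dataset, x, y, S, alpha=alpha)
                    n_tests += 1
                    if res.independent:
                        out[key] = S
                        found = True
                        break
                if found:
                    break
            if found:
                break
    return out, n_tests


def orient_colliders(skeleton: EndpointGraph, sepsets: SepsetTable) -> EndpointGraph:
    """Orient unshielded triples X–Z–Y with Z outside sepset(X, Y) as
    colliders.  Arrowhead demands are collected from all triples first and
    applied at once; an edge demanded at both ends becomes arrow–arrow
    (conflicted), which keeps the orientation phase order-independent."""
    g = skeleton.copy()
    demands: set[tuple[tuple[str, str], str]] = set()
    for z in g.nodes:
        adj = g.adjacent(z)
        for x, y in combinations(adj, 2):
            if g.has_edge(x, y):
                continue
            key = frozenset((x, y))
            if key not in sepsets:
                # pair was nonadjacent from the start (never tested): no
                # separating-set evidence, so no collider claim
                continue
            S = sepsets[key]
            if z not in S:
                demands.add((g._key(x, z), z))
                demands.add((g._key(y, z), z))

    by_edge: dict[tuple[str, str], set[str]] = {}
    for key, node in demands:
        by_edge.setdefault(key, set()).add(node)
    for (a, b), arrow_at in by_edge.items():
        if len(arrow_at) == 2:
            g.add_edge(a, b, ARROW, ARROW)
        else:
            (z,) = arrow_at
            src = b if z == a else a
            g.add_directed(src, z)
    return g


def apply_meek_rules(graph: EndpointGraph) -> EndpointGraph:
    """Propagate orientations to a fixed point.

    R1: A→B, B–C, A and C nonadjacent  ⇒  B→C  (else a new collider at B).
    R2: A→B→C with A–C                 ⇒  A→C  (else a directed cycle).
    R3: A–B, A–C, A–D, C→B, D→B, C and D nonadjacent ⇒ A→B.
    Conflicted (arrow–arrow) edges are never reoriented.
    """
    g = graph.copy()
    changed = True
    while changed:
        changed = False
        undirected = [(u, v) for u, v, mu, mv in g.edges()
                      if mu == TAIL and mv == TAIL]
        for u, v in undirected:
            if not g.has_edge(u, v) or g.edge_kind(u, v) != "undir":
                continue
            for b, c in ((u, v), (v, u)):
                # R1: some A with A->b, A not adjacent to c
                if any(
                    g.is_directed_edge(a, b) and not g.has_edge(a, c)
                    for a in g.adjacent(b) if a != c
                ):
                    g.add_directed(b, c)
                    changed = True
                    break
                # R2: b->w->c for some w, with b-c undirected => b->c
                if any(
                    g.is_directed_edge(b, w) and g.is_directed_edge(w, c)
                    for w in g.adjacent(b) if w != c
                ):
                    g.add_directed(b, c)
                    changed = True
                    break
                # R3: b-c undirected; b-w1, b-w2 undirected; w1->c, w2->c;
                # w1, w2 nonadjacent => b->c
                ws = [w for w in g.adjacent(b)
                      if w != c and g.is_undirected_edge(b, w)
                      and g.is_directed_edge(w, c)]
                if any(
                    not g.has_edge(w1, w2)
                    for i, w1 in enumerate(ws) for w2 in ws[i + 1:]
                ):
                    g.add_directed(b, c)
                    changed = True
                    break
    return g


def cpdag_of_dag(dag: EndpointGraph) -> EndpointGraph:
    """Markov-equivalence-class representation (CPDAG) of a DAG: keep the
    skeleton, orient the DAG's v-structures, close under the Meek rules."""
    skel = EndpointGraph(dag.nodes)
    for u, v, _, _ in dag.edges():
        skel.add_edge(u, v, TAIL, TAIL)
    demands: set[tuple[tuple[str, str], str]] = set()
    for z in dag.nodes:
        parents = [u for u in dag.adjacent(z) if dag.is_directed_edge(u, z)]
        for x, y in combinations(parents, 2):
            if not dag.has_edge(x, y):
                demands.add((skel._key(x, z), z))
                demands.add((skel._key(y, z), z))
    for (a, b), z in demands:
        src = b if z == a else a
        skel.add_directed(src, z)
    return apply_meek_rules(skel)


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

def skeleton_f1(truth: EndpointGraph, estimate: EndpointGraph) -> float:
    """F1 score of the estimated skeleton against the true skeleton."""
    t = truth.skeleton_edges()
    e = estimate.skeleton_edges()
    tp = len(t & e)
    if tp == 0:
        return 0.0
    prec = tp / len(e)
    rec = tp / len(t)
    return 2 * prec * rec / (prec + rec)


def shd_cpdag(a: EndpointGraph, b: EndpointGraph) -> int:
    """Structural Hamming distance between two partially directed graphs:
    one count per pair whose adjacency differs, plus one per shared edge
    whose endpoint marks differ."""
    dist = 0
    ea, eb = a.skeleton_edges(), b.skeleton_edges()
    dist += len(ea ^ eb)
    for key in ea & eb:
        u, v = sorted(key)
        if (a.mark_at(u, v, u), a.mark_at(u, v, v)) != \
                (b.mark_at(u, v, u), b.mark_at(u, v, v)):
            dist += 1
    return dist


# ---------------------------------------------------------------------------
# combined pipeline
# ---------------------------------------------------------------------------

@dataclass
class CausalDiscoveryResult:
    """Artifacts of the undirected + directed learning pipeline."""

    graph: EndpointGraph
    undirected: EndpointGraph
    skeleton: EndpointGraph
    sepsets: SepsetTable
    lambdas: LambdaTriple
    n_tests: int
    steps_profile: StabilityProfile | None = None


def mgm_pcstable(
    dataset: MixedDataset,
    lambdas: Sequence[float] | None = (0.25, 0.25, 0.25),
    use_steps: bool = False,
    alpha: float = 0.05,
    max_depth: int | None = None,
    tol: float = 1e-5,
    max_iter: int = 1000,
    steps_kwargs: dict | None = None,
) -> CausalDiscoveryResult:
    """Undirected learning (optionally with stability-selected penalties)
    followed by PC-Stable refinement and orientation."""
    profile = None
    if use_steps:
        profile = steps_select(dataset, **(steps_kwargs or {}))
        lam = profile.chosen
    else:
        lam = LambdaTriple(*lambdas).validate()
    fit = fit_mgm(dataset, lambdas=lam, tol=tol, max_iter=max_iter)
    undirected = extract_graph(fit.params)
    skeleton, sepsets, n_tests = pcs_skeleton(
        dataset, PCConfig(alpha=alpha, max_depth=max_depth, initial_graph=undirected)
    )
    sepsets, extra = complete_sepsets(
        dataset, skeleton, sepsets, alpha=alpha, max_depth=max_depth
    )
    n_tests += extra
    oriented = apply_meek_rules(orient_colliders(skeleton, sepsets))
    return CausalDiscoveryResult(
        graph=oriented, undirected=undirected, skeleton=skeleton,
        sepsets=sepsets, lambdas=lam, n_tests=n_tests, steps_profile=profile,
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class PCStable(BaseEstimator):
    """PC-Stable estimator: skeleton pruning + orientation.

    Attributes
    ----------
    graph_ : EndpointGraph  (oriented output)
    skeleton_ : EndpointGraph
    sepsets_ : dict
    n_tests_ : int
    """

    def __init__(self, alpha=0.05, max_depth=None, initial_graph=None,
                 max_levels=5):
        self.alpha = alpha
        self.max_depth = max_depth
        self.initial_graph = initial_graph
        self.max_levels = max_levels

    def fit(self, X, y=None):
        ds = as_mixed_dataset(X, max_levels=self.max_levels)
        cfg = PCConfig(alpha=self.alpha, max_depth=self.max_depth,
                       initial_graph=self.initial_graph)
        skel, sepsets, n_tests = pcs_skeleton(ds, cfg)
        sepsets, extra = complete_sepsets(
            ds, skel, sepsets, alpha=self.alpha, max_depth=self.max_depth
        )
        self.skeleton_ = skel
        self.sepsets_ = sepsets
        self.n_tests_ = n_tests + extra
        self.graph_ = apply_meek_rules(orient_colliders(skel, sepsets))
        return self


class MGMPCStable(BaseEstimator):
    """Two-step causal discovery: MGM undirected graph, then PC-Stable.

    Set ``use_steps=True`` to choose the penalty triple by subsampling
    stability instead of fixed ``lambda_*`` values.

    Attributes
    ----------
    graph_ : EndpointGraph       (oriented output)
    undirected_graph_ : EndpointGraph
    lambdas_ : LambdaTriple
    sepsets_ : dict
    n_tests_ : int
    steps_profile_ : StabilityProfile or None
    """

    def __init__(self, lambda_cc=0.25, lambda_cd=0.25, lambda_dd=0.25,
                 use_steps=False, alpha=0.05, max_depth=None,
                 gamma=0.05, n_subsamples=20, random_state=0, max_levels=5):
        self.lambda_cc = lambda_cc
        self.lambda_cd = lambda_cd
        self.lambda_dd = lambda_dd
        self.use_steps = use_steps
        self.alpha = alpha
        self.max_depth = max_depth
        self.gamma = gamma
        self.n_subsamples = n_subsamples
        self.random_state = random_state
        self.max_levels = max_levels

    def fit(self, X, y=None):
        ds = as_mixed_dataset(X, max_levels=self.max_levels)
        res = mgm_pcstable(
            ds,
            lambdas=(self.lambda_cc, self.lambda_cd, self.lambda_dd),
            use_steps=self.use_steps, alpha=self.alpha,
            max_depth=self.max_depth,
            steps_kwargs={"gamma": self.gamma, "N": self.n_subsamples,
                          "seed": self.random_state} if self.use_steps else None,
        )
        self.graph_ = res.graph
        self.undirected_graph_ = res.undirected
        self.lambdas_ = res.lambdas
        self.sepsets_ = res.sepsets
        self.n_tests_ = res.n_tests
        self.steps_profile_ = res.steps_profile
        return self


def has_directed_cycle(graph: EndpointGraph) -> bool:
    """True if the fully directed edges of the graph contain a cycle."""
    return not nx.is_directed_acyclic_graph(graph.directed_subgraph())
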