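"""Order-independent constraint-based structure learning (PC-stable).

Three phases produce a CPDAG-like pattern from a z-scored expression matrix:

1. **Skeleton** - start from the complete undirected graph; at conditioning
   level l, freeze every node's adjacency set, then delete edge i-j as soon as
   some subset S of adj(i)\\{j} (or adj(j)\\{i}) of size l makes i and j
   conditionally independent; record S as the separating set.  Freezing the
   adjacency sets per level is what makes the result independent of variable
   order; additionally all enumeration here is lexicographic in the node ids,
   so runs are bit-reproducible.
2. **v-structures** - orient i->k<-j for every unshielded triple i-k-j whose
   separating set excludes k (the only orientations identifiable from
   independence constraints alone).
3. **Meek rules** - propagate orientations (rules R1-R4) to a fixed point,
   yielding the maximally oriented pattern.  Directed edges are the "guided"
   relations, the remaining undirected ones the "undetermined" relations.

`dag_to_cpdag` provides an *independent* route to the same object - the
compelled-edge labelling of Chickering's transformational characterisation -
and is used to cross-validate the PC path on enumerable graphs.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable

import networkx as nx
import numpy as np

from .ci_test import GaussianCITest, OracleCITest
from .errors import InternalConsistencyError, StageError
from .graph import MixedGraph
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# phase 1: skeleton
# ---------------------------------------------------------------------------

def _stable_skeleton(ci, nodes: list[str], max_cond_size: int | None) -> MixedGraph:
    nodes = sorted(nodes)
    adj: dict[str, set[str]] = {v: set(nodes) - {v} for v in nodes}
    sepsets: dict[frozenset, frozenset] = {}
    level = 0
    while True:
        if max_cond_size is not None and level > max_cond_size:
            break
        if not any(len(adj[v]) - 1 >= level for v in nodes):
            break
        frozen = {v: frozenset(adj[v]) for v in nodes}  # PC-stable freeze
        for i in nodes:
            for j in sorted(frozen[i]):
                if j not in adj[i]:
                    continue  # removed earlier at this level
                candidates = sorted(frozen[i] - {j})
                if len(candidates) < level:
                    continue
                for S in itertools.combinations(candidates, level):
                    if ci.test(i, j, S).independent:
                        adj[i].discard(j)
                        adj[j].discard(i)
                        sepsets[frozenset((i, j))] = frozenset(S)
                        break
        level += 1
    undirected = {
        frozenset((i, j)) for i in nodes for j in adj[i] if i < j
    }
    g = MixedGraph(nodes=nodes, undirected=undirected, sepsets=sepsets)
    g.meta["skeleton_levels"] = level
    return g


def learn_skeleton(
    data: ExpressionMatrix,
    alpha: float = 0.01,
    max_cond_size: int | None = None,
    corr_method: str = "pearson",
) -> MixedGraph:
    """PC-stable skeleton phase on a z-scored expression matrix."""
    if data.stage != "zscored":
        raise StageError(f"learn_skeleton expects stage 'zscored', got {data.stage!r}")
    if data.n_samples < 4:
        raise StageError("need at least 4 samples")
    ci = GaussianCITest(data.values, data.protein_ids, alpha, corr_method)
    g = _stable_skeleton(ci, data.protein_ids, max_cond_size)
    g.meta.update(
        alpha=alpha, n=data.n_samples, p=data.n_proteins,
        n_ci_tests=ci.n_tests, n_ci_skipped=ci.n_skipped,
    )
    return g


def oracle_skeleton(dag: nx.DiGraph, max_cond_size: int | None = None) -> MixedGraph:
    """Skeleton phase driven by the d-separation oracle of a known DAG."""
    ci = OracleCITest(dag)
    return _stable_skeleton(ci, list(dag.nodes), max_cond_size)


# ---------------------------------------------------------------------------
# phase 2: v-structures
# ---------------------------------------------------------------------------

def orient_v_structures(skeleton: MixedGraph) -> MixedGraph:
    """Orient unshielded colliders; conservative conflict policy.

    For each unshielded triple i-k-j (i, j non-adjacent) with
    k not in sepset(i, j), propose i->k and j->k.  A later proposal never
    overwrites an existing arrowhead: if the contrary orientation is already
    present the edge is reset to undirected, logged, and locked for the rest
    of this phase (keeps the output a valid pattern).
    """
    g = skeleton.copy()
    proposals: list[tuple[str, str]] = []
    for k in sorted(g.nodes):
        nbrs = sorted(g.neighbors(k))
        for i, j in itertools.combinations(nbrs, 2):
            if g.adjacent(i, j):
                continue
            pair = frozenset((i, j))
            if pair not in g.sepsets:
                raise InternalConsistencyError(
                    f"non-adjacent pair {{{i},{j}}} has no recorded separating set"
                )
            if k not in g.sepsets[pair]:
                proposals.append((i, k))
                proposals.append((j, k))
    conflicted: set[frozenset] = set()
    n_conflicts = 0
    for a, b in proposals:
        e = frozenset((a, b))
        if e in conflicted or (a, b) in g.directed:
            continue
        if (b, a) in g.directed:
            logger.warning("conflicting v-structure orientations on %s-%s; reset to undirected", a, b)
            g.unorient(a, b)
            conflicted.add(e)
            n_conflicts += 1
        elif e in g.undirected:
            g.orient(a, b)
    g.meta["v_structure_conflicts"] = n_conflicts
    return g


# ---------------------------------------------------------------------------
# phase 3: Meek rules
# ---------------------------------------------------------------------------

def _meek_applies(g: MixedGraph, a: str, b: str) -> bool:
    """Would some Meek rule orient the undirected edge a-b as a->b?"""
    # R1: c -> a - b with c, b non-adjacent  =>  a -> b
    for c in g.parents(a):
        if not g.adjacent(c, b):
            return True
    # R2: a -> c -> b with a - b  =>  a -> b
    if g.children(a) & g.parents(b):
        return True
    # R3: a - c, a - d, c -> b, d -> b, c and d non-adjacent  =>  a -> b
    und = g.undirected_neighbors(a)
    into_b = g.parents(b)
    cands = sorted(und & into_b)
    for c, d in itertools.combinations(cands, 2):
        if not g.adjacent(c, d):
            return True
    # R4: a - b, a adjacent to c and d, d -> c -> b, b and d non-adjacent => a -> b
    for c in sorted(g.parents(b)):
        if not g.adjacent(a, c):
            continue
        for d in sorted(g.parents(c)):
            if d == b or d == a:
                continue
            if g.adjacent(a, d) and not g.adjacent(b, d):
                return True
    return False


def apply_meek_rules(g: MixedGraph) -> MixedGraph:
    """Propagate orientations with Meek rules R1-R4 to a fixed point.

    Orientations that would close a directed cycle are refused, logged and
    blocked (they indicate inconsistent independence answers on finite data).
    """
    g = g.copy()
    blocked: set[tuple[str, str]] = set()
    changed = True
    while changed:
        changed = False
        for e in sorted(g.undirected, key=sorted):
            x, y = sorted(e)
            for a, b in ((x, y), (y, x)):
                if (a, b) in blocked or e not in g.undirected:
                    continue
                if _meek_applies(g, a, b):
                    if g.has_directed_path(b, a):
                        logger.warning(
                            "Meek orientation %s->%s would create a directed cycle; skipped",
                            a, b,
                        )
                        blocked.add((a, b))
                        continue
                    g.orient(a, b)
                    changed = True
                    break
    g.meta["meek_blocked"] = len(blocked)
    return g


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def learn_cpdag(
    data: ExpressionMatrix,
    alpha: float = 0.01,
    max_cond_size: int | None = None,
    corr_method: str = "pearson",
) -> MixedGraph:
    """Full PC-stable run: skeleton, colliders, Meek completion.

    The returned graph's ``meta`` records alpha, the sample/variable counts
    and the edge census (directed = "guided", undirected = "undetermined").
    """
    skel = learn_skeleton(data, alpha, max_cond_size, corr_method)
    g = apply_meek_rules(orient_v_structures(skel))
    g.meta.update(skel.meta)
    g.meta["edge_census"] = g.edge_census()
    g.validate()
    return g


def oracle_cpdag(dag: nx.DiGraph, max_cond_size: int | None = None) -> MixedGraph:
    """PC-stable run answered by the d-separation oracle of ``dag``."""
    g = apply_meek_rules(orient_v_structures(oracle_skeleton(dag, max_cond_size)))
    g.meta["edge_census"] = g.edge_census()
    g.validate()
    return g


# ---------------------------------------------------------------------------
# independent oracle: DAG -> CPDAG by compelled-edge labelling
# ---------------------------------------------------------------------------

def dag_to_cpdag(dag: nx.DiGraph) -> MixedGraph:
    """CPDAG of a DAG's Markov equivalence class (compelled-edge labelling).

    Implements the classical order-and-label procedure: edges are processed in
    an order derived from a topological node order, and each is labelled
    *compelled* (same orientation in every equivalent DAG -> directed edge of
    the CPDAG) or *reversible* (-> undirected edge).  Deliberately shares no
    code with the PC phases so the two constructions can check each other.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("input graph is cyclic")
    topo = {v: k for k, v in enumerate(nx.lexicographical_topological_sort(dag))}
    ordered = _order_edges(dag, topo)
    label: dict[tuple[str, str], str] = {}

    for x, y in ordered:
        if (x, y) in label:
            continue
        aborted = False
        for w in sorted(dag.predecessors(x), key=lambda v: topo[v]):
            if label.get((w, x)) != "compelled":
                continue
            if not dag.has_edge(w, y):
                for z in dag.predecessors(y):
                    label[(z, y)] = "compelled"
                aborted = True
                break
            label[(w, y)] = "compelled"
        if aborted:
            continue
        exists_z = any(
            z != x and not dag.has_edge(z, x) for z in dag.predecessors(y)
        )
        mark = "compelled" if exists_z else "reversible"
        for z in dag.predecessors(y):
            if (z, y) not in label:
                label[(z, y)] = mark

    g = MixedGraph(nodes=sorted(dag.nodes))
    for (t, h), mark in label.items():
        if mark == "compelled":
            g.directed.add((t, h))
        else:
            g.undirected.add(frozenset((t, h)))
    g.validate()
    return g


def _order_edges(dag: nx.DiGraph, topo: dict[str, int]) -> list[tuple[str, str]]:
    """Edge processing order for the compelled-edge labelling."""
    unordered = set(dag.edges)
    ordered: list[tuple[str, str]] = []
    while unordered:
        y = min((h for _, h in unordered), key=lambda v: topo[v])
        x = max((t for t, h in unordered if h == y), key=lambda v: topo[v])
        ordered.append((x, y))
        unordered.remove((x, y))
    return ordered


# ---------------------------------------------------------------------------
# d-separation (oracle plumbing)
# ---------------------------------------------------------------------------

def d_separated(dag: nx.DiGraph, i: str, j: str, S: Iterable[str] = ()) -> bool:
    """Is ``i`` d-separated from ``j`` given ``S`` in ``dag``?

    Thin wrapper over the reachability-based d-separation algorithm; adjacent
    nodes are never separated.
    """
    S = set(S)
    if i == j:
        raise ValueError("i and j must differ")
    if i in S or j in S:
        raise ValueError("i and j must not be in S")
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("d-separation requires an acyclic digraph")
    return nx.is_d_separator(dag, {i}, {j}, S)


# ---------------------------------------------------------------------------
# evaluation helpers
# ---------------------------------------------------------------------------

def skeleton_f1(estimated: MixedGraph, truth: nx.DiGraph) -> float:
    """F1 of the estimated skeleton against a true DAG's skeleton."""
    est = {frozenset(e) for e in estimated.undirected}
    est |= {frozenset(e) for e in estimated.directed}
    true = {frozenset((t, h)) for t, h in truth.edges}
    tp = len(est & true)
    if tp == 0:
        return 0.0
    precision = tp / len(est)
    recall = tp / len(true)
    return 2 * precision * recall / (precision + recall)
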