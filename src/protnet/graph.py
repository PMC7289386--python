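"""Partially directed graphs (CPDAG-like) with directed and undirected edges.

The structure learner outputs a pattern: edges whose orientation is
identifiable are directed ("guided"); the rest stay undirected
("undetermined").  ``MixedGraph`` stores both edge sets, the separating sets
found during skeleton learning, and run metadata, and writes the two
interchange formats network-visualisation tools read (SIF and GraphML).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .errors import InternalConsistencyError


@dataclass
class MixedGraph:
    nodes: list[str]
    directed: set[tuple[str, str]] = field(default_factory=set)
    undirected: set[frozenset] = field(default_factory=set)
    sepsets: dict[frozenset, frozenset] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    # -- basic queries ----------------------------------------------------
    def adjacent(self, a: str, b: str) -> bool:
        return (
            (a, b) in self.directed
            or (b, a) in self.directed
            or frozenset((a, b)) in self.undirected
        )

    def neighbors(self, v: str) -> set[str]:
        """All nodes adjacent to v, regardless of edge type/orientation."""
        out = {h for t, h in self.directed if t == v}
        out |= {t for t, h in self.directed if h == v}
        for e in self.undirected:
            if v in e:
                out |= e - {v}
        return out

    def parents(self, v: str) -> set[str]:
        return {t for t, h in self.directed if h == v}

    def children(self, v: str) -> set[str]:
        return {h for t, h in self.directed if t == v}

    def undirected_neighbors(self, v: str) -> set[str]:
        out: set[str] = set()
        for e in self.undirected:
            if v in e:
                out |= e - {v}
        return out

    def edge_census(self) -> dict:
        return {
            "directed": len(self.directed),
            "undirected": len(self.undirected),
            "total": len(self.directed) + len(self.undirected),
        }

    # -- mutation ---------------------------------------------------------
    def orient(self, a: str, b: str) -> None:
        """Turn the undirected edge a-b into a->b."""
        e = frozenset((a, b))
        if e not in self.undirected:
            raise InternalConsistencyError(f"no undirected edge {a}-{b} to orient")
        self.undirected.discard(e)
        self.directed.add((a, b))

    def unorient(self, a: str, b: str) -> None:
        """Turn a directed edge (either orientation) back into a-b."""
        self.directed.discard((a, b))
        self.directed.discard((b, a))
        self.undirected.add(frozenset((a, b)))

    def has_directed_path(self, a: str, b: str) -> bool:
        """Is there a directed path a -> ... -> b (over directed edges only)?"""
        stack, seen = [a], {a}
        while stack:
            v = stack.pop()
            if v == b:
                return True
            for c in self.children(v):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def copy(self) -> "MixedGraph":
        return MixedGraph(
            list(self.nodes),
            set(self.directed),
            set(self.undirected),
            dict(self.sepsets),
            dict(self.meta),
        )

    def validate(self) -> None:
        node_set = set(self.nodes)
        for t, h in self.directed:
            if t == h:
                raise InternalConsistencyError(f"self-loop {t}->{h}")
            if t not in node_set or h not in node_set:
                raise InternalConsistencyError(f"edge endpoint outside node set: {t}->{h}")
            if (h, t) in self.directed:
                raise InternalConsistencyError(f"2-cycle between {t} and {h}")
            if frozenset((t, h)) in self.undirected:
                raise InternalConsistencyError(
                    f"pair {{{t},{h}}} both directed and undirected"
                )
        for e in self.undirected:
            if len(e) != 2:
                raise InternalConsistencyError(f"bad undirected edge {set(e)}")
            if not e <= node_set:
                raise InternalConsistencyError(f"edge endpoint outside node set: {set(e)}")
        for pair in self.sepsets:
            a, b = tuple(pair)
            if self.adjacent(a, b):
                raise InternalConsistencyError(
                    f"pair {{{a},{b}}} adjacent yet present in sepsets"
                )

    # -- conversions ------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        """DiGraph with every edge carrying a boolean 'directed' attribute.

        Undirected edges are stored once, tail = lexicographically smaller
        endpoint, with directed=False.
        """
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for t, h in sorted(self.directed):
            g.add_edge(t, h, directed=True)
        for e in sorted(self.undirected, key=sorted):
            a, b = sorted(e)
            g.add_edge(a, b, directed=False)
        return g

    def to_undirected_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((t, h) for t, h in self.directed)
        g.add_edges_from(tuple(e) for e in self.undirected)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "MixedGraph":
        mg = cls(nodes=sorted(g.nodes))
        for t, h, attrs in g.edges(data=True):
            if _truthy(attrs.get("directed", True)):
                mg.directed.add((t, h))
            else:
                mg.undirected.add(frozenset((t, h)))
        mg.validate()
        return mg

    # -- writers / readers ------------------------------------------------
    def write_sif(self, path) -> None:
        """Simple-interaction format: one edge per line, relation encodes type."""
        with open(path, "w") as fh:
            for t, h in sorted(self.directed):
                fh.write(f"{t}\tdirected\t{h}\n")
            for e in sorted(self.undirected, key=sorted):
                a, b = sorted(e)
                fh.write(f"{a}\tundirected\t{b}\n")
            connected = {v for t, h in self.directed for v in (t, h)}
            connected |= {v for e in self.undirected for v in e}
            for v in sorted(set(self.nodes) - connected):
                fh.write(f"{v}\n")

    def write_graphml(self, path) -> None:
        nxg = self.to_networkx()
        for k, v in self.meta.items():
            nxg.graph[str(k)] = "" if v is None else str(v)
        nx.write_graphml(nxg, path)

    @classmethod
    def read_graphml(cls, path) -> "MixedGraph":
        return cls.from_networkx(nx.read_graphml(path))

    @classmethod
    def read_sif(cls, path) -> "MixedGraph":
        directed, undirected, nodes = set(), set(), set()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    nodes.add(parts[0])
                elif len(parts) == 3:
                    t, rel, h = parts
                    nodes |= {t, h}
                    if rel == "directed":
                        directed.add((t, h))
                    else:
                        undirected.add(frozenset((t, h)))
        mg = cls(sorted(nodes), directed, undirected)
        mg.validate()
        return mg


def _truthy(value) -> bool:
    if isinstance(value, str):
        return value.lower() in ("true", "1", "yes")
    return bool(value)
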