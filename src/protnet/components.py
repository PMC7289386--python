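"""Connected components of the learned pattern and their size census.

Every edge, directed or undirected, counts as a connection; isolated proteins
form size-1 components.  Components are conventionally named after their node
count ("Component 13"), with letter suffixes when two components tie in size.
Small components carry little functional signal, so a minimum-size filter
(default 9 nodes) selects the ones worth annotating.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .graph import MixedGraph


@dataclass(frozen=True)
class Component:
    id: str
    members: tuple[str, ...]
    internal_directed: int = 0
    internal_undirected: int = 0
    major_function: str | None = None
    function_source: str | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.members)

    @property
    def internal_edges(self) -> int:
        return self.internal_directed + self.internal_undirected


def _suffixes(n: int):
    """'a', 'b', ..., 'z', 'aa', 'ab', ... — enough for any tie."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    out, k = [], 0
    while len(out) < n:
        s, i = "", k
        while True:
            s = letters[i % 26] + s
            i = i // 26 - 1
            if i < 0:
                break
        out.append(s)
        k += 1
    return out


def connected_components(g: MixedGraph) -> list[Component]:
    """Components of the mixed graph, ordered by (size desc, smallest member).

    Edge direction is ignored for connectivity; each component's internal
    directed/undirected edge counts are tallied so that summing them over all
    components recovers the graph's edge census exactly.
    """
    ug = g.to_undirected_networkx()
    member_sets = [tuple(sorted(c)) for c in nx.connected_components(ug)]
    member_sets.sort(key=lambda m: (-len(m), m[0]))

    comps: list[Component] = []
    by_size = Counter(len(m) for m in member_sets)
    suffix_iters = {
        size: iter(_suffixes(count)) for size, count in by_size.items() if count > 1
    }
    for members in member_sets:
        size = len(members)
        cid = f"Component {size}"
        if size in suffix_iters:
            cid += next(suffix_iters[size])
        mset = set(members)
        n_dir = sum(1 for t, h in g.directed if t in mset)
        n_und = sum(1 for e in g.undirected if e <= mset)
        comps.append(
            Component(
                id=cid,
                members=members,
                internal_directed=n_dir,
                internal_undirected=n_und,
            )
        )
    return comps


def size_distribution(components: list[Component]) -> dict[int, int]:
    """Map component size -> number of components of that size."""
    return dict(sorted(Counter(c.n_nodes for c in components).items()))


def filter_components(
    components: list[Component],
    min_nodes: int = 9,
    max_nodes: int | None = None,
) -> list[Component]:
    """Keep components with min_nodes <= n_nodes (<= max_nodes when given)."""
    if min_nodes < 1:
        raise ValueError("min_nodes must be >= 1")
    out = [c for c in components if c.n_nodes >= min_nodes]
    if max_nodes is not None:
        out = [c for c in out if c.n_nodes <= max_nodes]
    return out


# -- tabular I/O -----------------------------------------------------------

def components_to_frame(components: list[Component]) -> pd.DataFrame:
    """Long-format membership table (component_id, protein_id)."""
    rows = [
        {"component_id": c.id, "protein_id": p} for c in components for p in c.members
    ]
    return pd.DataFrame(rows, columns=["component_id", "protein_id"])


def components_from_frame(df: pd.DataFrame) -> list[Component]:
    comps = []
    for cid, grp in df.groupby("component_id", sort=False):
        comps.append(Component(id=str(cid), members=tuple(sorted(grp["protein_id"]))))
    comps.sort(key=lambda c: (-c.n_nodes, c.members[0]))
    return comps


def size_distribution_to_frame(dist: dict[int, int]) -> pd.DataFrame:
    """Two-row census: sizes and the number of components of each size."""
    sizes = sorted(dist)
    return pd.DataFrame(
        [[dist[s] for s in sizes]],
        index=["n_components"],
        columns=pd.Index(sizes, name="n_nodes"),
    )
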