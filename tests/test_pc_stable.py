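"""PC-stable phases, Meek rules, CPDAG construction, d-separation."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from protnet.errors import InternalConsistencyError, StageError
from protnet.graph import MixedGraph
from protnet.pc_stable import (
    apply_meek_rules,
    d_separated,
    dag_to_cpdag,
    learn_cpdag,
    learn_skeleton,
    oracle_cpdag,
    oracle_skeleton,
    orient_v_structures,
    skeleton_f1,
)
from protnet.preprocess import ExpressionMatrix
from protnet.synthetic import generate_random_dag, make_truth, sample_sem

COLLIDER = nx.DiGraph([("A", "C"), ("B", "C")])
CHAIN = nx.DiGraph([("A", "B"), ("B", "C")])


# ---------------------------------------------------------------------------
# skeleton phase
# ---------------------------------------------------------------------------

class TestSkeleton:
    def test_oracle_collider_skeleton_and_sepset(self):
        g = oracle_skeleton(COLLIDER)
        assert g.undirected == {frozenset("AC"), frozenset("BC")}
        assert g.sepsets[frozenset("AB")] == frozenset()

    def test_oracle_chain_skeleton_and_sepset(self):
        g = oracle_skeleton(CHAIN)
        assert g.undirected == {frozenset("AB"), frozenset("BC")}
        assert g.sepsets[frozenset("AC")] == frozenset("B")

    def test_independent_columns_give_empty_skeleton(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((2, 500))
        vals = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=["X", "Y"], columns=[f"S{i}" for i in range(500)]),
            "zscored",
        )
        g = learn_skeleton(m, alpha=0.01)
        assert g.undirected == set()

    def test_requires_zscored_stage(self):
        m = ExpressionMatrix(
            pd.DataFrame(np.ones((2, 5)), index=["a", "b"]), "imputed"
        )
        with pytest.raises(StageError):
            learn_skeleton(m)

    def test_max_cond_size_caps_levels(self):
        dag = generate_random_dag(8, 0.4, seed=3)
        capped = oracle_skeleton(dag, max_cond_size=0)
        full = oracle_skeleton(dag)
        # level-0 testing alone can only remove marginally independent pairs
        full_edges = full.undirected
        assert full_edges <= capped.undirected


# ---------------------------------------------------------------------------
# orientation phases
# ---------------------------------------------------------------------------

class TestOrientation:
    def test_collider_oriented(self):
        g = orient_v_structures(oracle_skeleton(COLLIDER))
        assert g.directed == {("A", "C"), ("B", "C")}
        assert g.undirected == set()

    def test_chain_not_oriented_at_collider_phase(self):
        g = orient_v_structures(oracle_skeleton(CHAIN))
        assert g.directed == set()
        assert g.undirected == {frozenset("AB"), frozenset("BC")}

    def test_triangle_unchanged(self):
        g = MixedGraph(
            nodes=["A", "B", "C"],
            undirected={frozenset("AB"), frozenset("BC"), frozenset("AC")},
        )
        out = orient_v_structures(g)
        assert out.directed == set()
        assert out.undirected == g.undirected

    def test_missing_sepset_raises(self):
        g = MixedGraph(
            nodes=["A", "B", "C"],
            undirected={frozenset("AC"), frozenset("BC")},
            sepsets={},
        )
        with pytest.raises(InternalConsistencyError):
            orient_v_structures(g)

    def test_conflict_resets_edge_to_undirected(self):
        # two triples demand opposite arrowheads on B-C
        g = MixedGraph(
            nodes=["A", "B", "C", "D"],
            undirected={frozenset("AB"), frozenset("BC"), frozenset("CD")},
            sepsets={frozenset("AC"): frozenset(), frozenset("BD"): frozenset(),
                     frozenset("AD"): frozenset("BC")},
        )
        out = orient_v_structures(g)
        assert frozenset("BC") in out.undirected
        assert out.meta["v_structure_conflicts"] >= 1
        out.validate()

    def test_meek_r1(self):
        g = MixedGraph(
            nodes=["A", "B", "C"],
            directed={("A", "B")},
            undirected={frozenset("BC")},
        )
        out = apply_meek_rules(g)
        assert out.directed == {("A", "B"), ("B", "C")}

    def test_meek_r2(self):
        g = MixedGraph(
            nodes=["A", "B", "C"],
            directed={("A", "C"), ("C", "B")},
            undirected={frozenset("AB")},
        )
        out = apply_meek_rules(g)
        assert ("A", "B") in out.directed

    def test_meek_r3(self):
        g = MixedGraph(
            nodes=["A", "B", "C", "D"],
            directed={("C", "B"), ("D", "B")},
            undirected={frozenset("AB"), frozenset("AC"), frozenset("AD")},
        )
        out = apply_meek_rules(g)
        assert ("A", "B") in out.directed

    def test_fixed_point_is_stable(self):
        dag = generate_random_dag(7, 0.35, seed=11)
        g = oracle_cpdag(dag)
        again = apply_meek_rules(g)
        assert again.directed == g.directed
        assert again.undirected == g.undirected


# ---------------------------------------------------------------------------
# dag_to_cpdag (independent construction)
# ---------------------------------------------------------------------------

class TestDagToCpdag:
    def test_chain_fully_undirected(self):
        g = dag_to_cpdag(CHAIN)
        assert g.directed == set()
        assert g.undirected == {frozenset("AB"), frozenset("BC")}

    def test_collider_stays_directed(self):
        g = dag_to_cpdag(COLLIDER)
        assert g.directed == {("A", "C"), ("B", "C")}

    def test_single_edge_undirected(self):
        g = dag_to_cpdag(nx.DiGraph([("A", "B")]))
        assert g.directed == set()
        assert g.undirected == {frozenset("AB")}

    def test_cyclic_input_rejected(self):
        with pytest.raises(ValueError):
            dag_to_cpdag(nx.DiGraph([("A", "B"), ("B", "A")]))

    def test_matches_oracle_pc_on_small_dags(self):
        for seed in range(40):
            dag = generate_random_dag(2 + seed % 6, 0.3, seed=seed)
            a = oracle_cpdag(dag)
            b = dag_to_cpdag(dag)
            assert a.directed == b.directed, f"seed {seed}"
            assert a.undirected == b.undirected, f"seed {seed}"


# ---------------------------------------------------------------------------
# d-separation vs brute-force path enumeration
# ---------------------------------------------------------------------------

def _blocked(dag, path, S):
    """Is an undirected path blocked by S (classical criterion)?"""
    for k in range(1, len(path) - 1):
        prev, node, nxt = path[k - 1], path[k], path[k + 1]
        is_collider = dag.has_edge(prev, node) and dag.has_edge(nxt, node)
        if is_collider:
            desc = nx.descendants(dag, node) | {node}
            if not (desc & S):
                return True
        elif node in S:
            return True
    return False


def _dsep_brute(dag, i, j, S):
    ug = dag.to_undirected()
    for path in nx.all_simple_paths(ug, i, j):
        if not _blocked(dag, path, set(S)):
            return False
    return True


class TestDSeparation:
    def test_collider_definition(self):
        assert d_separated(COLLIDER, "A", "B", ())
        assert not d_separated(COLLIDER, "A", "B", ("C",))

    def test_chain_blocked_by_middle(self):
        assert d_separated(CHAIN, "A", "C", ("B",))
        assert not d_separated(CHAIN, "A", "C", ())

    def test_adjacent_never_separated(self):
        dag = generate_random_dag(6, 0.5, seed=2)
        for t, h in dag.edges:
            others = [v for v in dag.nodes if v not in (t, h)]
            assert not d_separated(dag, t, h, tuple(others))

    def test_agrees_with_path_enumeration(self):
        rng = np.random.default_rng(5)
        for seed in range(25):
            p = 4 + seed % 4
            dag = generate_random_dag(p, 0.35, seed=100 + seed)
            nodes = sorted(dag.nodes)
            for _ in range(10):
                i, j = rng.choice(len(nodes), size=2, replace=False)
                i, j = nodes[i], nodes[j]
                rest = [v for v in nodes if v not in (i, j)]
                k = int(rng.integers(0, len(rest) + 1))
                S = tuple(rng.choice(rest, size=k, replace=False)) if k else ()
                assert d_separated(dag, i, j, S) == _dsep_brute(dag, i, j, S)


# ---------------------------------------------------------------------------
# full learner
# ---------------------------------------------------------------------------

class TestLearnCpdag:
    def test_oracle_collider_and_chain_cpdags(self):
        g = oracle_cpdag(COLLIDER)
        assert g.directed == {("A", "C"), ("B", "C")}
        g = oracle_cpdag(CHAIN)
        assert g.directed == set()
        assert g.undirected == {frozenset("AB"), frozenset("BC")}

    def test_census_conservation_and_acyclicity(self):
        truth = make_truth(p=20, edge_prob=0.12, seed=4)
        z = sample_sem(truth, 800, seed=5)
        g = learn_cpdag(z, alpha=0.01)
        census = g.edge_census()
        assert census["directed"] + census["undirected"] == census["total"]
        sub = nx.DiGraph(list(g.directed))
        assert nx.is_directed_acyclic_graph(sub)
        g.validate()

    def test_order_independence(self):
        truth = make_truth(p=20, edge_prob=0.12, seed=8)
        z = sample_sem(truth, 500, seed=9)
        g1 = learn_cpdag(z, alpha=0.01)
        perm = np.random.default_rng(1).permutation(z.n_proteins)
        z2 = ExpressionMatrix(z.data.iloc[perm], "zscored")
        g2 = learn_cpdag(z2, alpha=0.01)
        assert g1.directed == g2.directed
        assert g1.undirected == g2.undirected

    def test_finite_sample_recovery(self):
        truth = make_truth(p=15, edge_prob=0.2, seed=1)
        z = sample_sem(truth, 5000, seed=2)
        g = learn_cpdag(z, alpha=0.01)
        assert skeleton_f1(g, truth.dag) >= 0.85

    def test_metadata_recorded(self):
        truth = make_truth(p=10, edge_prob=0.1, seed=6)
        z = sample_sem(truth, 200, seed=7)
        g = learn_cpdag(z, alpha=0.05)
        assert g.meta["alpha"] == 0.05
        assert g.meta["n"] == 200
        assert g.meta["p"] == 10
        assert g.meta["edge_census"] == g.edge_census()


# ---------------------------------------------------------------------------
# MixedGraph container & formats
# ---------------------------------------------------------------------------

class TestMixedGraphIO:
    def _graph(self):
        return MixedGraph(
            nodes=["A", "B", "C", "D", "E"],
            directed={("A", "B"), ("B", "C")},
            undirected={frozenset("CD")},
        )

    def test_graphml_roundtrip(self, tmp_path):
        g = self._graph()
        path = tmp_path / "g.graphml"
        g.write_graphml(path)
        back = MixedGraph.read_graphml(path)
        assert back.directed == g.directed
        assert back.undirected == g.undirected
        assert set(back.nodes) == set(g.nodes)

    def test_sif_roundtrip(self, tmp_path):
        g = self._graph()
        path = tmp_path / "g.sif"
        g.write_sif(path)
        back = MixedGraph.read_sif(path)
        assert back.directed == g.directed
        assert back.undirected == g.undirected
        assert set(back.nodes) == set(g.nodes)  # isolated node E preserved

    def test_validate_rejects_two_cycles(self):
        g = MixedGraph(nodes=["A", "B"], directed={("A", "B"), ("B", "A")})
        with pytest.raises(InternalConsistencyError):
            g.validate()
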