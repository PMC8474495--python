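import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from microcore.go_collapse import (
    circos_export,
    collapse_terms,
    enrich,
    hit_lists,
    reference_nodes,
    unique_gene_counts,
)
from microcore.io_formats import AnnotationTable, OntologyGraph
from conftest import random_dag


def exact_hypergeom_tail(k, N, K, n):
    """Enumeration oracle: P(X >= k) by summing the pmf."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / denom


def _flat_ontology(terms):
    g = nx.DiGraph()
    g.add_node("root", name="root")
    for t in terms:
        g.add_node(t, name=t)
        g.add_edge(t, "root")
    return OntologyGraph(graph=g, root="root")


class TestEnrich:
    def test_closed_form_p(self):
        """All 5 annotated genes drawn in a 5-gene set from a background of
        20: p = 1/C(20,5)."""
        bg = {f"g{i}" for i in range(20)}
        ann = AnnotationTable({f"g{i}": frozenset({"T"}) for i in range(5)})
        ont = _flat_ontology(["T"])
        res = enrich({f"g{i}" for i in range(5)}, bg, ann, ont, propagate=False,
                     p_max=1.1, q_max=1.1)
        assert res.tested.loc["T", "p"] == pytest.approx(1 / math.comb(20, 5))

    def test_ubiquitous_term_not_significant(self):
        bg = {f"g{i}" for i in range(12)}
        ann = AnnotationTable({g: frozenset({"T"}) for g in bg})
        res = enrich({"g0", "g1"}, bg, ann, _flat_ontology(["T"]), propagate=False)
        assert res.tested.loc["T", "p"] == pytest.approx(1.0)
        assert "T" not in res.significant.index

    def test_gene_set_equals_background(self):
        bg = {f"g{i}" for i in range(8)}
        ann = AnnotationTable({g: frozenset({"T"}) for g in list(bg)[:4]})
        res = enrich(bg, bg, ann, _flat_ontology(["T"]), propagate=False,
                     p_max=1.1, q_max=1.1)
        assert res.tested.loc["T", "k"] == res.tested.loc["T", "K"]
        assert res.tested.loc["T", "p"] == pytest.approx(1.0)

    def test_gene_set_outside_background_rejected(self):
        ann = AnnotationTable({"a": frozenset({"T"})})
        with pytest.raises(ValueError):
            enrich({"stray"}, {"a"}, ann, _flat_ontology(["T"]))

    def test_matches_enumeration_oracle_small_n(self):
        """Hypergeometric p equals exact enumeration for N <= 15 over many
        random configurations."""
        rng = np.random.default_rng(3)
        ont = _flat_ontology(["T"])
        for _ in range(100):
            N = int(rng.integers(3, 16))
            bg = {f"g{i}" for i in range(N)}
            K = int(rng.integers(1, N + 1))
            ann = AnnotationTable({f"g{i}": frozenset({"T"}) for i in range(K)})
            n = int(rng.integers(1, N + 1))
            gene_set = {f"g{i}" for i in rng.choice(N, n, replace=False)}
            k = len([g for g in gene_set if g in ann.annotations])
            if k == 0:
                continue
            res = enrich(gene_set, bg, ann, ont, propagate=False,
                         p_max=1.1, q_max=1.1)
            assert res.tested.loc["T", "p"] == pytest.approx(
                exact_hypergeom_tail(k, N, K, n), rel=1e-9
            )

    def test_propagation_counts_ancestors(self, chain_ontology):
        bg = {"x", "y", "z", "w"}
        ann = AnnotationTable({"x": frozenset({"C"}), "y": frozenset({"A"})})
        res = enrich({"x"}, bg, ann, chain_ontology, propagate=True,
                     p_max=1.1, q_max=1.1)
        # x's annotation to C counts for B and A as well; root excluded
        assert set(res.tested.index) == {"A", "B", "C"}


class TestReferenceNodes:
    def test_chain(self, chain_ontology):
        assert reference_nodes(chain_ontology) == {"A", "B"}

    def test_star(self):
        ont = _flat_ontology([f"c{i}" for i in range(5)])
        assert reference_nodes(ont) == {f"c{i}" for i in range(5)}

    def test_bfs_oracle_on_random_dags(self):
        """reference_nodes equals a breadth-first shortest-path filter on
        100 random rooted DAGs."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            ont = random_dag(rng, int(rng.integers(4, 40)))
            expect = {
                t
                for t in ont.terms
                if t != ont.root
                and nx.shortest_path_length(ont.graph, t, ont.root) <= 2
            }
            assert reference_nodes(ont) == expect


class TestCollapse:
    def test_reference_term_maps_to_itself(self, chain_ontology):
        ref = reference_nodes(chain_ontology)
        col = collapse_terms(["A"], chain_ontology, ref)
        assert col.mapping.loc["A", "reference"] == "A"
        assert col.mapping.loc["A", "distance"] == 0

    def test_chain_deep_term(self, chain_ontology):
        """C sits three levels down; its nearest reference ancestor is B."""
        ref = reference_nodes(chain_ontology)
        col = collapse_terms(["C"], chain_ontology, ref)
        assert col.mapping.loc["C", "reference"] == "B"
        assert col.mapping.loc["C", "distance"] == 1
        assert not col.mapping.loc["C", "deep"]

    def test_nearest_reference_wins(self):
        """X has a reference ancestor at distance 1 (L2b) and others at
        distance 2 (L2a via the non-reference node P); the nearer wins."""
        g = nx.DiGraph()
        for t in ["root", "L1a", "L1b", "L2a", "L2b", "P", "X"]:
            g.add_node(t, name=t)
        for child, parent in [("L1a", "root"), ("L1b", "root"),
                              ("L2a", "L1a"), ("L2b", "L1b"),
                              ("P", "L2a"), ("X", "P"), ("X", "L2b")]:
            g.add_edge(child, parent)
        ont = OntologyGraph(graph=g, root="root")
        ref = reference_nodes(ont)
        assert ref == {"L1a", "L1b", "L2a", "L2b"}
        col = collapse_terms(["X"], ont, ref)
        assert col.mapping.loc["X", "reference"] == "L2b"
        assert col.mapping.loc["X", "distance"] == 1

    def test_tie_breaks_deterministic(self):
        g = nx.DiGraph()
        for t in ["root", "r1", "r2", "X"]:
            g.add_node(t, name=t)
        g.add_edge("r1", "root")
        g.add_edge("r2", "root")
        g.add_edge("X", "r1")
        g.add_edge("X", "r2")
        ont = OntologyGraph(graph=g, root="root")
        ref = {"r1", "r2"}
        # larger annotated background wins; equal sizes fall back to term id
        assert collapse_terms(["X"], ont, ref, term_sizes={"r1": 5, "r2": 9}
                              ).mapping.loc["X", "reference"] == "r2"
        assert collapse_terms(["X"], ont, ref, term_sizes={}
                              ).mapping.loc["X", "reference"] == "r1"

    def test_unknown_term_rejected(self, chain_ontology):
        with pytest.raises(KeyError):
            collapse_terms(["nope"], chain_ontology, {"A"})

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            ont = random_dag(rng, 25)
            ref = reference_nodes(ont)
            terms = [t for t in ont.terms if t != ont.root][:10]
            once = collapse_terms(terms, ont, ref)
            twice = collapse_terms(sorted(once.reference_terms), ont, ref)
            assert (twice.mapping["reference"] == twice.mapping.index).all()


class TestUniqueGenesAndCircos:
    def test_union_counting(self, chain_ontology):
        ref = reference_nodes(chain_ontology)
        col = collapse_terms(["B", "C"], chain_ontology, ref)
        hits = {"B": frozenset({"a", "b"}), "C": frozenset({"b", "c"})}
        counts = unique_gene_counts(col, hits)
        assert counts == {"B": 3}

    def test_single_contributor(self, chain_ontology):
        col = collapse_terms(["A"], chain_ontology, {"A"})
        assert unique_gene_counts(col, {"A": frozenset({"x"})}) == {"A": 1}

    def test_membership_conserved_random(self):
        """Union of genes over reference terms equals union over the
        original enriched terms."""
        rng = np.random.default_rng(6)
        for _ in range(30):
            ont = random_dag(rng, 30)
            ref = reference_nodes(ont)
            terms = [t for t in sorted(ont.terms - {ont.root})
                     if rng.random() < 0.5]
            if not terms:
                continue
            hits = {
                t: frozenset(f"g{i}" for i in rng.choice(20, rng.integers(1, 6),
                                                         replace=False))
                for t in terms
            }
            col = collapse_terms(terms, ont, ref)
            counts = unique_gene_counts(col, hits)
            union_ref = set()
            for r, contributing in col.contributors.items():
                genes = set().union(*(hits[t] for t in contributing))
                assert counts[r] == len(genes)
                assert counts[r] <= sum(len(hits[t]) for t in contributing)
                union_ref |= genes
            assert union_ref == set().union(*hits.values())

    def test_circos_widths(self):
        df = circos_export({"sp": {"T1": 10, "T2": 30, "T3": 0}})
        assert list(df["width"]) == [0.25, 0.75]
        assert "T3" not in set(df["reference_term"])
        two = circos_export({"a": {"T": 1}, "b": {"T": 2, "U": 2}})
        assert (two.groupby("species")["width"].sum() == 1.0).all()
        assert len(two[two["reference_term"] == "T"]) == 2
        with pytest.raises(ValueError):
            circos_export({})


def test_hit_lists_propagation_switch(chain_ontology):
    ann = AnnotationTable({"x": frozenset({"C"})})
    raw = hit_lists({"x"}, ann, chain_ontology, propagate=False)
    assert set(raw) == {"C"}
    prop = hit_lists({"x"}, ann, chain_ontology, propagate=True)
    assert set(prop) == {"C", "B", "A", "R"}
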