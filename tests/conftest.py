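import numpy as np
import pandas as pd
import pytest

from microcore.io_formats import CountTable, GeneLengthTable, OntologyGraph
import networkx as nx


@pytest.fixture
def toy_counts() -> CountTable:
    """3 genes x 4 samples, two cohorts."""
    df = pd.DataFrame(
        {
            "s1": [10, 0, 5],
            "s2": [12, 1, 4],
            "m1": [100, 50, 5],
            "m2": [90, 60, 6],
        },
        index=["g1", "g2", "g3"],
    )
    return CountTable(
        counts=df,
        cohort_of={"s1": "tissue", "s2": "tissue", "m1": "mg", "m2": "mg"},
    )


@pytest.fixture
def toy_lengths() -> GeneLengthTable:
    return GeneLengthTable({"g1": 1000, "g2": 2000, "g3": 500})


@pytest.fixture
def chain_ontology() -> OntologyGraph:
    """root <- A <- B <- C (is_a chains point child -> parent)."""
    g = nx.DiGraph()
    for t, name in [("R", "root"), ("A", "a"), ("B", "b"), ("C", "c")]:
        g.add_node(t, name=name)
    g.add_edge("A", "R")
    g.add_edge("B", "A")
    g.add_edge("C", "B")
    return OntologyGraph(graph=g, root="R")


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyGraph:
    """Rooted random DAG: node i > 0 gets 1-2 parents among lower-ids."""
    g = nx.DiGraph()
    g.add_node("T0", name="root")
    for i in range(1, n_terms):
        g.add_node(f"T{i}", name=f"term {i}")
        k = int(rng.integers(1, min(3, i + 1)))
        parents = rng.choice(i, size=k, replace=False)
        for p in parents:
            g.add_edge(f"T{i}", f"T{int(p)}")
    return OntologyGraph(graph=g, root="T0")
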