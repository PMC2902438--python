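import networkx as nx
import numpy as np
import pytest

from icemod import AnnotationMap, ExpressionMatrix, Ontology


@pytest.fixture
def toy_ontology():
    """root -> A -> B chain (is_a pointing child -> parent)."""
    return Ontology.from_parent_map({"root": [], "A": ["root"], "B": ["A"]})


@pytest.fixture
def toy_annotations():
    """10 annotated genes: 2 on the leaf B, 8 directly on the root."""
    ann = {f"g{i}": {"root"} for i in range(1, 9)}
    ann["g9"] = {"B"}
    ann["g10"] = {"B"}
    return AnnotationMap({g: frozenset(t) for g, t in ann.items()})


def overlapping_cliques_graph():
    """A 12-clique and an 11-clique sharing exactly 3 nodes."""
    g = nx.Graph()
    big = [f"a{i:02d}" for i in range(12)]
    small = big[:3] + [f"b{i:02d}" for i in range(8)]
    for grp in (big, small):
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                g.add_edge(grp[i], grp[j])
    return g, set(big), set(small)


@pytest.fixture
def k12_k11():
    return overlapping_cliques_graph()


@pytest.fixture
def std_matrix():
    """Small standardized matrix with a perfectly correlated pair."""
    rng = np.random.default_rng(42)
    base = rng.standard_normal(8)
    values = np.vstack([base, 2 * base + 1, rng.standard_normal(8)])
    values = (values - values.mean(axis=1, keepdims=True)) / values.std(
        axis=1, ddof=1, keepdims=True
    )
    return ExpressionMatrix(["gA", "gB", "gC"], [f"s{i}" for i in range(8)],
                            values, standardized=True)
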