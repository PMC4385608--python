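import numpy as np
import pytest

from recrwr import (
    AssociationRecord,
    MulticonceptGraph,
    SyntheticGraphParams,
    build_graph,
    generate_graph,
)


def random_multilayer_graph(
    rng: np.random.Generator,
    n_nodes: int,
    edge_prob: float = 0.4,
    layers: tuple[str, ...] = ("gene", "disease", "go"),
) -> MulticonceptGraph:
    """A small random graph with nodes spread over the given layers.

    Ensures at least one edge; weights uniform in [1, 1000].
    """
    names = [f"N{i:03d}" for i in range(n_nodes)]
    assignment = {names[i]: layers[i % len(layers)] for i in range(n_nodes)}
    pairs: dict[tuple[str, str], list[AssociationRecord]] = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                a, b = names[i], names[j]
                key = (assignment[a], assignment[b])
                pairs.setdefault(key, []).append(
                    AssociationRecord(a, b, int(rng.integers(1, 1001)))
                )
    if not any(pairs.values()):
        key = (assignment[names[0]], assignment[names[1]])
        pairs = {key: [AssociationRecord(names[0], names[1], 500)]}
    return build_graph(pairs)


@pytest.fixture
def two_gene_graph() -> MulticonceptGraph:
    return build_graph({("gene", "gene"): [AssociationRecord("A", "B", 500)]})


@pytest.fixture
def chain_graph() -> MulticonceptGraph:
    """Three genes in a path A - B - C with unit-like weights."""
    return build_graph(
        {
            ("gene", "gene"): [
                AssociationRecord("A", "B", 1000),
                AssociationRecord("B", "C", 1000),
            ]
        }
    )


@pytest.fixture
def three_layer_graph() -> MulticonceptGraph:
    """Tiny handmade graph with all three layers."""
    return build_graph(
        {
            ("gene", "gene"): [
                AssociationRecord("G1", "G2", 800),
                AssociationRecord("G2", "G3", 600),
                AssociationRecord("G1", "G3", 700),
                AssociationRecord("G3", "G4", 300),
            ],
            ("gene", "disease"): [
                AssociationRecord("G1", "MIM:1", 1000),
                AssociationRecord("G2", "MIM:1", 1000),
                AssociationRecord("G4", "MIM:2", 1000),
            ],
            ("gene", "go"): [
                AssociationRecord("G1", "GO:1", 1000),
                AssociationRecord("G3", "GO:2", 1000),
            ],
            ("go", "go"): [AssociationRecord("GO:1", "GO:2", 1000)],
        }
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """One modest planted-module graph shared by read-only tests."""
    params = SyntheticGraphParams(
        n_genes=200,
        n_diseases=8,
        genes_per_disease=10,
        n_go_terms=30,
        background_edge_prob=0.02,
        within_module_edge_prob=0.9,
        go_annotations_per_gene=2,
        rng_seed=42,
    )
    graph, truth = generate_graph(params)
    return params, graph, truth
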