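"""Multiconcept graph: parsing dialects, construction, masks, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recrwr import (
    AssociationRecord,
    GraphBuildError,
    ParseError,
    build_graph,
    column_normalize,
    extract_block,
    hits_reweight,
    load_graph,
    normalize_columns,
    parse_association_table,
    save_graph,
)
from conftest import random_multilayer_graph


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class TestParsing:
    def test_generic_tsv_maps_fields_directly(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("# comment\nP04637\tP00533\t900\n")
        recs = parse_association_table(f, "generic-tsv")
        assert recs == [AssociationRecord("P04637", "P00533", 900)]

    def test_self_association_is_a_parse_error(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("A\tA\t500\n")
        with pytest.raises(ParseError, match="line 1"):
            parse_association_table(f, "generic-tsv")

    def test_weight_out_of_range_is_an_error_not_clamped(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("A\tB\t1001\n")
        with pytest.raises(ParseError, match="1001"):
            parse_association_table(f, "generic-tsv")

    def test_malformed_line_names_its_number(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("A\tB\t10\nA\tB\n")
        with pytest.raises(ParseError, match="line 2"):
            parse_association_table(f, "generic-tsv")

    def test_empty_file_yields_empty_list(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("")
        assert parse_association_table(f, "generic-tsv") == []

    def test_morbidmap_defaults_weight_and_prefixes_mim(self, tmp_path):
        f = tmp_path / "mm.tsv"
        f.write_text("G1\t114480\nG2\tMIM:114480\n")
        recs = parse_association_table(f, "morbidmap")
        # oracle for the default-weight rule: scoreless dialects carry 1000
        assert recs == [
            AssociationRecord("G1", "MIM:114480", 1000),
            AssociationRecord("G2", "MIM:114480", 1000),
        ]

    def test_string_links_header_prefix_and_threshold(self, tmp_path):
        f = tmp_path / "links.txt"
        f.write_text(
            "protein1 protein2 combined_score\n"
            "9606.P04637 9606.P00533 900\n"
            "9606.P04637 9606.Q92698 150\n"
        )
        recs = parse_association_table(
            f, "string-links", strip_species_prefix=True, score_threshold=400
        )
        assert recs == [AssociationRecord("P04637", "P00533", 900)]

    def test_gaf_uses_columns_two_and_five(self, tmp_path):
        f = tmp_path / "ann.gaf"
        f.write_text(
            "!gaf-version: 2.2\n"
            "UniProtKB\tP04637\tTP53\t\tGO:0006915\tPMID:1\tIDA\t\tP\n"
        )
        recs = parse_association_table(f, "gaf")
        assert recs == [AssociationRecord("P04637", "GO:0006915", 1000)]

    def test_go_isa_pairs(self, tmp_path):
        f = tmp_path / "isa.tsv"
        f.write_text("GO:0006915\tGO:0008219\n")
        recs = parse_association_table(f, "go-isa")
        assert recs == [AssociationRecord("GO:0006915", "GO:0008219", 1000)]

    def test_unknown_dialect_rejected(self, tmp_path):
        f = tmp_path / "x.tsv"
        f.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            parse_association_table(f, "xml")


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

class TestBuildGraph:
    def test_single_edge_gives_symmetric_adjacency_and_mask(self, two_gene_graph):
        g = two_gene_graph
        assert g.node_ids == ["A", "B"]
        assert g.adjacency.toarray().tolist() == [[0, 500], [500, 0]]
        assert g.masks["gene"].bits.tolist() == [1, 1]

    def test_duplicate_edges_keep_maximum_weight(self):
        g = build_graph(
            {
                ("gene", "gene"): [
                    AssociationRecord("A", "B", 500),
                    AssociationRecord("B", "A", 700),
                ]
            }
        )
        # brute-force pairwise scan: the max of all weights seen for {A,B}
        assert g.adjacency[g.index_of("A"), g.index_of("B")] == 700
        assert g.adjacency[g.index_of("B"), g.index_of("A")] == 700

    def test_masks_partition_the_node_set(self):
        g = build_graph(
            {
                ("gene", "disease"): [AssociationRecord("G1", "MIM:1", 1000)],
                ("gene", "gene"): [AssociationRecord("G1", "G2", 400)],
            }
        )
        assert g.n_nodes == 3
        assert int(g.masks["gene"].bits.sum()) == 2
        assert int(g.masks["disease"].bits.sum()) == 1
        total = sum(m.bits for m in g.masks.values())
        assert np.array_equal(total, np.ones(g.n_nodes, dtype=np.int8))

    def test_cross_layer_identifier_conflict_lists_offenders(self):
        with pytest.raises(GraphBuildError, match="X1"):
            build_graph(
                {
                    ("gene", "gene"): [AssociationRecord("X1", "G2", 10)],
                    ("disease", "disease"): [AssociationRecord("X1", "MIM:2", 10)],
                }
            )

    def test_no_records_is_an_error(self):
        with pytest.raises(GraphBuildError):
            build_graph({})

    def test_order_invariance_under_record_permutation(self):
        recs = [
            AssociationRecord("C", "A", 100),
            AssociationRecord("B", "C", 200),
            AssociationRecord("A", "B", 300),
        ]
        g1 = build_graph({("gene", "gene"): recs})
        g2 = build_graph({("gene", "gene"): recs[::-1]})
        assert g1.node_ids == g2.node_ids
        assert (g1.adjacency != g2.adjacency).nnz == 0

    def test_node_order_sorted_by_layer_then_id(self, three_layer_graph):
        g = three_layer_graph
        assert g.node_layers == sorted(g.node_layers)
        for layer in g.layers:
            ids = [n for n, l in zip(g.node_ids, g.node_layers) if l == layer]
            assert ids == sorted(ids)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_adjacency_always_symmetric_with_zero_diagonal(self, seed):
        g = random_multilayer_graph(np.random.default_rng(seed), 8)
        A = g.adjacency.toarray()
        assert np.array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)


# ---------------------------------------------------------------------------
# Normalization and masking
# ---------------------------------------------------------------------------

class TestColumnNormalize:
    def test_two_node_single_entry_columns(self, two_gene_graph):
        W = column_normalize(two_gene_graph)
        assert W.matrix.toarray().tolist() == [[0.0, 1.0], [1.0, 0.0]]

    def test_all_zero_adjacency_becomes_identity(self):
        W = normalize_columns(np.zeros((2, 2)))
        assert W.matrix.toarray().tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_star_column_entries_are_half(self):
        A = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        W = normalize_columns(A).matrix.toarray()
        assert W[1, 0] == 0.5 and W[2, 0] == 0.5
        np.testing.assert_allclose(W.sum(axis=0), 1.0, atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_columns_sum_to_one_on_random_graphs(self, seed):
        g = random_multilayer_graph(np.random.default_rng(seed), 9, edge_prob=0.2)
        W = column_normalize(g).matrix
        np.testing.assert_allclose(
            np.asarray(W.sum(axis=0)).ravel(), 1.0, atol=1e-12
        )


class TestExtractBlock:
    def test_same_layer_masks_leave_that_block_unchanged(self, two_gene_graph):
        B = extract_block(two_gene_graph, "gene", "gene")
        assert (B != two_gene_graph.adjacency).nnz == 0

    def test_cross_block_zeroes_out_of_layer_entries(self, three_layer_graph):
        g = three_layer_graph
        B = extract_block(g, "gene", "disease").toarray()
        gene_rows = g.masks["gene"].bits.astype(bool)
        disease_cols = g.masks["disease"].bits.astype(bool)
        assert np.all(B[~gene_rows, :] == 0)
        assert np.all(B[:, ~disease_cols] == 0)
        assert B.shape == (g.n_nodes, g.n_nodes)  # full-size, not compacted

    def test_transpose_duality_on_symmetric_adjacency(self, three_layer_graph):
        g = three_layer_graph
        B_gd = extract_block(g, "gene", "disease").toarray()
        B_dg = extract_block(g, "disease", "gene").toarray()
        assert np.array_equal(B_gd.T, B_dg)

    def test_unknown_layer_errors(self, two_gene_graph):
        with pytest.raises(KeyError):
            extract_block(two_gene_graph, "gene", "disease")

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_masked_product(self, seed):
        rng = np.random.default_rng(seed)
        g = random_multilayer_graph(rng, int(rng.integers(4, 11)))
        layers = g.layers
        la = layers[int(rng.integers(len(layers)))]
        lb = layers[int(rng.integers(len(layers)))]
        B = extract_block(g, la, lb).toarray()
        A = g.adjacency.toarray()
        mi, mj = g.masks[la].bits, g.masks[lb].bits
        expected = np.empty_like(A)
        for r in range(A.shape[0]):
            for c in range(A.shape[1]):
                expected[r, c] = mi[r] * A[r, c] * mj[c]
        assert np.array_equal(B, expected)


# ---------------------------------------------------------------------------
# HITS-style reweighting
# ---------------------------------------------------------------------------

class TestHitsReweight:
    def test_disabled_is_a_pass_through(self, three_layer_graph):
        g = hits_reweight(three_layer_graph, enabled=False)
        assert g is three_layer_graph

    def test_single_edge_rescales_to_max(self, two_gene_graph):
        g = hits_reweight(two_gene_graph, enabled=True)
        A = g.adjacency.toarray()
        assert A[0, 1] == 1000 and A[1, 0] == 1000

    def test_star_centrality_matches_dense_eigendecomposition(self):
        recs = [AssociationRecord("HUB", f"L{i}", 500) for i in range(3)]
        g = build_graph({("gene", "gene"): recs})
        A = g.adjacency.toarray().astype(float)
        w, v = np.linalg.eigh(A)
        c = np.abs(v[:, np.argmax(w)])
        hub = g.index_of("HUB")
        leaves = [g.index_of(f"L{i}") for i in range(3)]
        assert all(c[hub] > c[l] for l in leaves)
        out = hits_reweight(g, enabled=True).adjacency.toarray()
        # all edges touch the hub, so by symmetry they share one weight
        vals = {out[hub, l] for l in leaves}
        assert vals == {1000}
        assert np.array_equal(out, out.T)

    def test_preserves_symmetry_on_random_graphs(self):
        g = random_multilayer_graph(np.random.default_rng(1), 10)
        out = hits_reweight(g, enabled=True).adjacency.toarray()
        assert np.array_equal(out, out.T)
        assert out.max() <= 1000


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

class TestSerialization:
    def test_round_trip_preserves_everything(self, tmp_path, three_layer_graph):
        p = tmp_path / "g.tsv"
        save_graph(three_layer_graph, p)
        g2 = load_graph(p)
        assert g2.node_ids == three_layer_graph.node_ids
        assert g2.node_layers == three_layer_graph.node_layers
        assert (g2.adjacency != three_layer_graph.adjacency).nnz == 0

    def test_save_is_byte_deterministic(self, tmp_path, three_layer_graph):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        save_graph(three_layer_graph, p1)
        save_graph(three_layer_graph, p2)
        assert p1.read_bytes() == p2.read_bytes()
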