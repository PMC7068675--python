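import io

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncffl.network import (
    EdgeListError,
    FFLNetwork,
    InteractionEdge,
    LncFFL,
    degree_distribution,
    enumerate_ffls,
    read_edge_lists,
    restrict_to_ffls,
    scale_free_fit,
)

from .conftest import brute_force_ffls, motif_edges


class TestReadEdgeLists:
    def test_duplicates_collapse(self):
        src = io.StringIO("source\ttarget\tlayer\nG1\tM1\tgene-miRNA\nG1\tM1\tgene-miRNA\n")
        assert len(read_edge_lists([src])) == 1

    def test_empty_file_is_empty_set(self, caplog):
        src = io.StringIO("source\ttarget\tlayer\n")
        with caplog.at_level("WARNING"):
            assert read_edge_lists([src]) == []
        assert "empty" in caplog.text

    def test_fixture_hand_count(self, edges_fixture_path):
        edges = read_edge_lists([edges_fixture_path])
        assert len(edges) == 12
        by_layer = pd.Series([e.layer for e in edges]).value_counts()
        assert by_layer["gene-miRNA"] == 6
        assert by_layer["gene-lncRNA"] == 3
        assert by_layer["miRNA-lncRNA"] == 3

    def test_case_insensitive_matching_preserves_first_casing(self):
        src = io.StringIO(
            "source\ttarget\tlayer\n"
            "Sp1\tmiR-1\tgene-miRNA\n"
            "SP1\tMIR-1\tgene-miRNA\n"
        )
        edges = read_edge_lists([src])
        assert len(edges) == 1
        assert edges[0].source == "Sp1" and edges[0].target == "miR-1"

    def test_malformed_row_names_file_and_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("source\ttarget\tlayer\nG1\t\tgene-miRNA\n")
        with pytest.raises(EdgeListError, match="line 2"):
            read_edge_lists([p])

    def test_layer_per_file(self):
        src = io.StringIO("source\ttarget\nG1\tM1\n")
        edges = read_edge_lists([src], layers=["gene-miRNA"])
        assert edges[0].layer == "gene-miRNA"

    def test_type_contradiction_rejected(self):
        # X is a miRNA target in one layer and a gene source in another
        src = io.StringIO(
            "source\ttarget\tlayer\nG1\tX\tgene-miRNA\nX\tL1\tgene-lncRNA\n"
        )
        with pytest.raises(EdgeListError, match="contradictory"):
            read_edge_lists([src])

    def test_self_edge_rejected(self):
        src = io.StringIO("source\ttarget\tlayer\nA\ta\tgene-miRNA\n")
        with pytest.raises(EdgeListError, match="self-edge"):
            read_edge_lists([src])


def _random_edges(rng, n_per_side=15, p=0.15):
    edges = []
    for layer, (ns, nt) in (
        ("gene-miRNA", ("G", "M")),
        ("gene-lncRNA", ("G", "L")),
        ("miRNA-lncRNA", ("M", "L")),
    ):
        mask = rng.random((n_per_side, n_per_side)) < p
        for i, j in np.argwhere(mask):
            edges.append(InteractionEdge(f"{ns}{i}", f"{nt}{j}", layer))
    return edges


class TestEnumerateFFLs:
    def test_minimal_motif(self):
        net = enumerate_ffls(motif_edges("G", "M", "L"))
        assert net.ffls == [LncFFL("G", "M", "L")]

    def test_incomplete_motif(self):
        edges = motif_edges("G", "M", "L")[:2]  # missing miRNA->lncRNA
        assert enumerate_ffls(edges).ffls == []

    def test_empty_input(self):
        assert enumerate_ffls([]).ffls == []

    def test_non_participants_dropped(self):
        edges = motif_edges("G", "M", "L") + [
            InteractionEdge("G2", "M9", "gene-miRNA")
        ]
        net = enumerate_ffls(edges)
        assert set(net.nodes) == {"G", "M", "L"}
        assert len(net.edges) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        edges = _random_edges(np.random.default_rng(seed))
        net = enumerate_ffls(edges)
        assert {f.key() for f in net.ffls} == brute_force_ffls(edges)

    def test_idempotent(self):
        edges = _random_edges(np.random.default_rng(3))
        net = enumerate_ffls(edges)
        again = enumerate_ffls(net.edges)
        assert again.ffls == net.ffls

    def test_deterministic_lexicographic_order(self):
        edges = _random_edges(np.random.default_rng(4))
        ffls = enumerate_ffls(edges).ffls
        assert ffls == sorted(ffls)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.booleans())
    def test_adding_edges_never_removes_ffls(self, seed, denser):
        rng = np.random.default_rng(seed)
        edges = _random_edges(rng, n_per_side=8, p=0.2)
        before = {f.key() for f in enumerate_ffls(edges).ffls}
        extra = _random_edges(
            np.random.default_rng(seed + 1), n_per_side=8, p=0.3 if denser else 0.1
        )
        merged = list({(e.layer, e.source, e.target): e for e in edges + extra}.values())
        after = {f.key() for f in enumerate_ffls(merged).ffls}
        assert before <= after


class TestDegreeDistribution:
    def test_star(self):
        edges = [InteractionEdge("G0", f"M{i}", "gene-miRNA") for i in range(5)]
        star = FFLNetwork(
            nodes={"G0": "gene", **{f"M{i}": "miRNA" for i in range(5)}},
            edges=edges,
            ffls=[],
        )
        dist = degree_distribution(star)
        assert dict(zip(dist.degree, dist.n_nodes)) == {1: 5, 5: 1}

    def test_single_ffl_all_degree_two(self):
        net = enumerate_ffls(motif_edges("G", "M", "L"))
        dist = degree_distribution(net)
        assert dict(zip(dist.degree, dist.n_nodes)) == {2: 3}

    def test_counts_sum_to_node_count_on_random_network(self):
        edges = _random_edges(np.random.default_rng(8))
        net = enumerate_ffls(edges)
        dist = degree_distribution(net)
        assert dist.n_nodes.sum() == len(net.nodes)
        # independent per-node recount
        g = net.undirected_graph()
        recount = pd.Series([d for _, d in g.degree()]).value_counts().sort_index()
        assert dict(zip(dist.degree, dist.n_nodes)) == recount.to_dict()

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            degree_distribution(FFLNetwork(nodes={}, edges=[], ffls=[]))


class TestScaleFreeFit:
    def test_exact_power_law(self):
        k = np.arange(1, 11)
        dist = pd.DataFrame({"degree": k, "n_nodes": 1000 * k.astype(float) ** -2})
        slope, intercept, r2 = scale_free_fit(dist)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(-2.0, abs=1e-12)
        assert intercept == pytest.approx(3.0, abs=1e-12)

    def test_constant_counts_r2_zero(self):
        dist = pd.DataFrame({"degree": [1, 2, 3, 4, 5], "n_nodes": [7] * 5})
        slope, _, r2 = scale_free_fit(dist)
        assert slope == 0.0 and r2 == 0.0

    def test_too_few_degrees_error(self):
        dist = pd.DataFrame({"degree": [1, 2], "n_nodes": [5, 3]})
        with pytest.raises(ValueError):
            scale_free_fit(dist)

    def test_preferential_attachment_fits_well(self):
        g = nx.barabasi_albert_graph(500, 2, seed=1)
        degs = pd.Series([d for _, d in g.degree()]).value_counts().sort_index()
        dist = pd.DataFrame({"degree": degs.index, "n_nodes": degs.to_numpy()})
        _, _, r2 = scale_free_fit(dist)
        assert r2 >= 0.8


def test_restrict_to_ffls_keeps_only_motif_edges():
    edges = _random_edges(np.random.default_rng(12))
    net = enumerate_ffls(edges)
    if net.n_ffls < 2:
        pytest.skip("random draw too sparse")
    sub = restrict_to_ffls(net, net.ffls[:1])
    assert sub.ffls == net.ffls[:1]
    assert len(sub.edges) == 3 and len(sub.nodes) == 3
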