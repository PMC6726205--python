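"""Synthetic generators and file readers."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from netattack.generators import (
    BAParams,
    GRGParams,
    generate_ba,
    generate_grg,
    read_edge_list,
    read_gml,
    write_edge_list,
)


# ---- Barabási–Albert growth ---------------------------------------------------

@pytest.mark.parametrize("n", [2, 3, 10, 257, 1000])
def test_ba_edge_count_closed_form_m2(n):
    # growth from one node: node k attaches min(2, k) edges -> 1 + 2(n-2)
    g = generate_ba(BAParams(n=n, m=2, seed=n))
    assert g.number_of_edges() == 1 + 2 * (n - 2) if n >= 2 else 0
    assert g.number_of_nodes() == n


def test_ba_trivia():
    assert generate_ba(BAParams(n=1, m=2, seed=0)).number_of_edges() == 0
    k3 = generate_ba(BAParams(n=3, m=2, seed=0))
    assert nx.utils.graphs_equal(k3, nx.complete_graph(3))


@pytest.mark.parametrize("m", [1, 2, 3])
def test_ba_general_edge_count_and_min_degree(m):
    n = 200
    g = generate_ba(BAParams(n=n, m=m, seed=7))
    expected = sum(min(m, k) for k in range(1, n))
    assert g.number_of_edges() == expected
    # every node added after the m-th has degree >= m, no self-loops
    assert all(g.degree(v) >= m for v in range(m + 1, n))
    assert all(u != v for u, v in g.edges)


def test_ba_is_simple_and_reproducible():
    a = generate_ba(BAParams(n=300, m=2, seed=11))
    b = generate_ba(BAParams(n=300, m=2, seed=11))
    assert nx.utils.graphs_equal(a, b)
    c = generate_ba(BAParams(n=300, m=2, seed=12))
    assert not nx.utils.graphs_equal(a, c)


def test_ba_hubs_are_early_nodes():
    # preferential attachment: early nodes accumulate far higher degree
    g = generate_ba(BAParams(n=2000, m=2, seed=3))
    early = np.mean([g.degree(v) for v in range(10)])
    late = np.mean([g.degree(v) for v in range(1990, 2000)])
    assert early > 5 * late


# ---- geometric random graphs --------------------------------------------------

def test_grg_extremes():
    g = generate_grg(GRGParams(n=2, radius=math.sqrt(2), seed=0))
    assert g.number_of_edges() == 1
    g = generate_grg(GRGParams(n=100, radius=0.0, seed=0))
    assert g.number_of_edges() == 0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_grg_edges_match_distance_predicate_exhaustively(seed):
    g = generate_grg(GRGParams(n=150, radius=0.1, seed=seed))
    pos = nx.get_node_attributes(g, "pos")
    for u, v in itertools.combinations(range(150), 2):
        d = math.dist(pos[u], pos[v])
        assert g.has_edge(u, v) == (d <= 0.1)


def test_grg_mean_edges_match_boundary_corrected_expectation():
    # closed form: P(two uniform points within r) = pi r^2 - (8/3) r^3 + r^4/2
    n, r, reps = 400, 0.08, 60
    p = math.pi * r**2 - (8 / 3) * r**3 + r**4 / 2
    expect = math.comb(n, 2) * p
    counts = [
        generate_grg(GRGParams(n=n, radius=r, seed=s)).number_of_edges()
        for s in range(reps)
    ]
    se = np.std(counts, ddof=1) / math.sqrt(reps)
    assert abs(np.mean(counts) - expect) < 4 * se


def test_grg_require_connected_retries_and_caps():
    g = generate_grg(GRGParams(n=30, radius=0.35, seed=5, require_connected=True))
    assert nx.is_connected(g)
    with pytest.raises(RuntimeError, match="connected"):
        generate_grg(
            GRGParams(n=50, radius=0.01, seed=5, require_connected=True, max_retries=3)
        )


# ---- readers / writer ---------------------------------------------------------

def test_edge_list_reader_symmetrizes_and_skips_comments(tmp_path):
    f = tmp_path / "g.txt"
    f.write_text("# a comment\n0\t1\n1\t0\n2 3\n")
    g = read_edge_list(f)
    assert g.number_of_nodes() == 4
    assert g.number_of_edges() == 2


def test_edge_list_reader_empty_and_errors(tmp_path):
    f = tmp_path / "only_comments.txt"
    f.write_text("# nothing\n# here\n")
    assert read_edge_list(f).number_of_nodes() == 0
    bad = tmp_path / "bad.txt"
    bad.write_text("0 x\n")
    with pytest.raises(ValueError, match="non-integer"):
        read_edge_list(bad)


def test_edge_list_round_trip(tmp_path):
    g = generate_ba(BAParams(n=50, m=2, seed=9))
    path = tmp_path / "ba.txt"
    write_edge_list(g, path)
    h = read_edge_list(path)
    assert set(map(frozenset, h.edges)) == set(map(frozenset, g.edges))


def test_gml_reader_drops_duplicates_and_loops(tmp_path, caplog):
    gml = (
        "graph [\n"
        "  node [ id 0 label \"a\" ]\n"
        "  node [ id 1 label \"b\" ]\n"
        "  node [ id 2 label \"c\" ]\n"
        "  edge [ source 0 target 1 ]\n"
        "  edge [ source 1 target 0 ]\n"
        "  edge [ source 1 target 2 ]\n"
        "  edge [ source 2 target 2 ]\n"
        "]\n"
    )
    f = tmp_path / "toy.gml"
    f.write_text(gml)
    import logging

    with caplog.at_level(logging.WARNING):
        g = read_gml(f)
    assert g.number_of_nodes() == 3
    assert g.number_of_edges() == 2
    assert "dropped" in caplog.text


def test_gml_reader_signals_parse_failure(tmp_path):
    f = tmp_path / "broken.gml"
    f.write_text("graph [ node [ id ] \n")
    with pytest.raises(ValueError, match="parse"):
        read_gml(f)


def test_param_validation():
    with pytest.raises(ValueError):
        BAParams(n=0)
    with pytest.raises(ValueError):
        BAParams(n=5, m=0)
    with pytest.raises(ValueError):
        GRGParams(n=5, radius=2.0)
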