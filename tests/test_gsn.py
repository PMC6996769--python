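"""Transplant-flow network construction and structural statistics."""
import itertools
import math

import networkx as nx
import numpy as np
import pytest
import scipy.sparse.csgraph as csgraph

from donorsense import gsn
from donorsense.errors import ValidationError
from donorsense.records import TransplantRecord


def _rec(dz, rz, group="white", lat=34.0, lon=-118.0):
    return TransplantRecord(dz, rz, group, group, lat, lon, lat, lon)


def _graph_from_edges(edges, directed=False):
    g = nx.DiGraph() if directed else nx.Graph()
    for a, b in edges:
        g.add_edge(a, b, weight=1)
    for n in g.nodes:
        g.nodes[n]["lat"] = 0.0
        g.nodes[n]["lon"] = 0.0
    return g


# ---------------------------------------------------------------- build_gsn

def test_build_gsn_collapses_parallel_transplants_into_weights():
    g = gsn.build_gsn([_rec("A", "B"), _rec("A", "B"), _rec("B", "C")])
    assert g.number_of_nodes() == 3
    assert g.number_of_edges() == 2
    assert g["A"]["B"]["weight"] == 2
    assert g["B"]["C"]["weight"] == 1


def test_build_gsn_recipient_filter_keeps_any_donor_origin():
    records = [
        _rec("A", "B", "hispanic"),
        TransplantRecord("C", "D", "white", "hispanic", 0, 0, 0, 0),
        _rec("E", "F", "white"),
    ]
    g = gsn.build_gsn(records, recipient_group="hispanic")
    assert set(g.edges) == {("A", "B"), ("C", "D")}  # white donor C retained


def test_build_gsn_empty_and_unknown_group():
    g = gsn.build_gsn([])
    assert g.number_of_nodes() == 0 and g.number_of_edges() == 0
    with pytest.raises(ValidationError):
        gsn.build_gsn([_rec("A", "B")], recipient_group="martian")


# ----------------------------------------------------- clustering / paths

def test_clustering_closed_forms():
    triangle = _graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
    path = _graph_from_edges([("a", "b"), ("b", "c")])
    assert gsn.clustering_coefficient(triangle) == 1.0
    assert gsn.clustering_coefficient(path) == 0.0


def test_average_path_length_closed_forms():
    complete4 = _graph_from_edges(itertools.combinations("abcd", 2))
    path = _graph_from_edges([("a", "b"), ("b", "c")])
    assert gsn.average_path_length(complete4) == 1.0
    assert gsn.average_path_length(path) == pytest.approx(4 / 3)
    with pytest.raises(ValidationError):
        gsn.average_path_length(nx.Graph([("a", "a")]))


def _brute_force_transitivity(g):
    """O(n^3) triangle/triple enumeration."""
    nodes = list(g.nodes)
    triangles = triples = 0
    for a, b, c in itertools.combinations(nodes, 3):
        ab, bc, ac = g.has_edge(a, b), g.has_edge(b, c), g.has_edge(a, c)
        n_edges = ab + bc + ac
        if n_edges == 3:
            triangles += 1
            triples += 3
        elif n_edges == 2:
            triples += 1
    return 3 * triangles / triples if triples else 0.0


def _bfs_average_path_length(g):
    nodes = list(max(nx.connected_components(g), key=len))
    idx = {n: i for i, n in enumerate(g.nodes)}
    a = nx.to_scipy_sparse_array(g, weight=None)
    d = csgraph.shortest_path(a, method="BF", unweighted=True)
    sub = np.ix_([idx[n] for n in nodes], [idx[n] for n in nodes])
    dm = d[sub]
    n = len(nodes)
    return dm[~np.eye(n, dtype=bool)].mean()


@pytest.mark.parametrize("seed", range(8))
def test_metrics_match_bruteforce_on_random_graphs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 26))
    g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31)))
    g.remove_edges_from(nx.selfloop_edges(g))
    for u, v in g.edges:
        g[u][v]["weight"] = 1
    assert gsn.clustering_coefficient(g) == pytest.approx(
        _brute_force_transitivity(g), abs=1e-12
    )
    if len(max(nx.connected_components(g), key=len)) >= 2:
        assert gsn.average_path_length(g) == pytest.approx(
            _bfs_average_path_length(g), abs=1e-12
        )


def test_duplicate_records_change_weights_only():
    base = [_rec("A", "B"), _rec("B", "C"), _rec("C", "A"), _rec("C", "D")]
    g1 = gsn.build_gsn(base)
    g2 = gsn.build_gsn(base + base)  # every transplant duplicated
    assert g1.number_of_nodes() == g2.number_of_nodes()
    assert gsn.clustering_coefficient(g1) == gsn.clustering_coefficient(g2)
    assert gsn.average_path_length(g1) == gsn.average_path_length(g2)


# ------------------------------------------------------------- communities

def test_two_disjoint_triangles_two_communities():
    g = _graph_from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
    )
    part = gsn.detect_communities(g, seed=0)
    assert part.n_communities == 2
    assert len({part.membership[n] for n in "abc"}) == 1
    assert len({part.membership[n] for n in "xyz"}) == 1
    assert part.membership["a"] == 0  # ids ordered by smallest node label


def _partitions(collection):
    if len(collection) == 1:
        yield [collection]
        return
    first, rest = collection[0], collection[1:]
    for smaller in _partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
        yield [[first]] + smaller


def test_bridged_triangles_match_exhaustive_modularity_maximum():
    """Louvain finds the global modularity optimum on two bridged triangles
    (checked against enumeration of all 203 partitions of 6 nodes)."""
    g = _graph_from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("x", "y"), ("y", "z"), ("x", "z"), ("c", "x")]
    )
    best_q, best_part = max(
        (nx.community.modularity(g, [set(s) for s in p]), p)
        for p in _partitions(list(g.nodes))
    )
    part = gsn.detect_communities(g, seed=0)
    assert part.n_communities == len(best_part) == 2
    assert part.modularity == pytest.approx(best_q, abs=1e-12)


def test_detect_communities_deterministic_and_beats_trivial_partition():
    g = nx.gnp_random_graph(30, 0.15, seed=42)
    for u, v in g.edges:
        g[u][v]["weight"] = 1
    p1 = gsn.detect_communities(g, seed=5)
    p2 = gsn.detect_communities(g, seed=5)
    assert p1.membership == p2.membership
    trivial = nx.community.modularity(g, [set(g.nodes)])
    assert p1.modularity >= trivial


# ---------------------------------------------------------------- summary

def test_network_summary_two_disjoint_triangles():
    records = [_rec("a", "b"), _rec("b", "c"), _rec("c", "a"),
               _rec("x", "y"), _rec("y", "z"), _rec("z", "x")]
    s = gsn.network_summary(gsn.build_gsn(records), seed=0)
    assert (s.n_nodes, s.n_links) == (6, 6)
    assert s.avg_degree == 1.0
    assert s.clustering == 1.0
    assert s.avg_path_length == 1.0
    assert s.n_communities == 2


def test_network_summary_single_edge():
    s = gsn.network_summary(gsn.build_gsn([_rec("A", "B")]), seed=0)
    assert (s.n_nodes, s.n_links) == (2, 1)
    assert s.avg_degree == 0.5
    assert s.clustering == 0.0
    assert s.avg_path_length == 1.0
    assert s.n_communities == 1  # a single dyad maximizes modularity as one block


# -------------------------------------------------------------- dispersion

def test_community_dispersion_closed_forms():
    g = nx.Graph()
    g.add_node("p", lat=0.0, lon=0.0)
    g.add_node("q", lat=0.0, lon=1.0)
    g.add_node("r", lat=10.0, lon=10.0)
    g.add_edge("p", "q", weight=1)
    part = gsn.CommunityPartition({"p": 0, "q": 0, "r": 1}, 0.0, 0)
    disp = gsn.community_dispersion(part, g)
    assert disp[1] == 0.0  # singleton
    # one degree of longitude on the equator: 6371 km * pi / 180
    assert disp[0] == pytest.approx(6371.0 * math.pi / 180, abs=0.01)
    g.nodes["q"]["lat"] = 0.0
    g.nodes["q"]["lon"] = 0.0
    assert gsn.community_dispersion(part, g)[0] == 0.0


def test_community_dispersion_requires_coordinates():
    g = nx.Graph()
    g.add_node("p")
    with pytest.raises(ValidationError):
        gsn.community_dispersion(gsn.CommunityPartition({"p": 0}, 0.0, 0), g)
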