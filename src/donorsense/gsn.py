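"""Geographical social networks (GSNs) of organ-transplant flow.

A GSN is a directed graph whose nodes are home zip codes and whose edges
point from a donor's zip code to a recipient's zip code, weighted by the
number of transplants between that zip pair.  Separate ethnoracial GSNs are
built by filtering on the recipient's ethnoracial group while leaving donor
origins unrestricted, so each network describes where one group's organs
come from.

Structural disparity between groups is summarized by six statistics: node
count ``N_n``, link count ``M`` (distinct zip pairs), average degree
``M/N_n``, clustering coefficient ``CC``, average path length ``L`` and the
number of communities ``N_c`` found by modularity maximization.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .errors import ValidationError
from .records import ETHNORACIAL_GROUPS, TransplantRecord

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class NetworkSummary:
    """The six structural-disparity statistics of one GSN.

    ``avg_path_length`` is ``nan`` for networks whose largest connected
    component has fewer than two nodes.
    """

    group: str
    n_nodes: int
    n_links: int
    avg_degree: float
    clustering: float
    avg_path_length: float
    n_communities: int


@dataclass(frozen=True)
class CommunityPartition:
    """A node -> community assignment with its modularity score.

    Community ids are contiguous integers from 0, ordered by the smallest
    node label each community contains.
    """

    membership: Mapping[str, int]
    modularity: float
    seed: int

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values())) if self.membership else 0


def build_gsn(records: Iterable[TransplantRecord], recipient_group: str = "all") -> nx.DiGraph:
    """Build the transplant-flow graph for one recipient group.

    Records whose recipient belongs to ``recipient_group`` (or all records
    when the filter is ``"all"``) contribute a directed edge
    donor_zip -> recipient_zip; repeated zip pairs accumulate into the edge
    ``weight``.  Donor zips of any group may appear as origins.  Same-zip
    transplants produce self-loops, which are kept.
    """
    if recipient_group != "all" and recipient_group not in ETHNORACIAL_GROUPS:
        raise ValidationError(
            f"unknown recipient group {recipient_group!r}; "
            f"expected 'all' or one of {ETHNORACIAL_GROUPS}"
        )
    g = nx.DiGraph(recipient_group=recipient_group)
    for rec in records:
        if recipient_group != "all" and rec.recipient_group != recipient_group:
            continue
        if not g.has_node(rec.donor_zip):
            g.add_node(rec.donor_zip, lat=rec.donor_lat, lon=rec.donor_lon)
        if not g.has_node(rec.recipient_zip):
            g.add_node(rec.recipient_zip, lat=rec.recipient_lat, lon=rec.recipient_lon)
        if g.has_edge(rec.donor_zip, rec.recipient_zip):
            g[rec.donor_zip][rec.recipient_zip]["weight"] += 1
        else:
            g.add_edge(rec.donor_zip, rec.recipient_zip, weight=1)
    return g


def undirected_projection(gsn: nx.DiGraph) -> nx.Graph:
    """Undirected weighted projection; antiparallel edge weights sum."""
    u = nx.Graph()
    u.add_nodes_from(gsn.nodes(data=True))
    for a, b, data in gsn.edges(data=True):
        if u.has_edge(a, b):
            u[a][b]["weight"] += data["weight"]
        else:
            u.add_edge(a, b, weight=data["weight"])
    return u


def clustering_coefficient(gsn: nx.DiGraph | nx.Graph, method: str = "transitivity") -> float:
    """Clustering coefficient of the undirected, unweighted projection.

    The default is the global transitivity 3*triangles / connected triples
    (the probability that two nodes sharing a neighbor are themselves
    connected); ``method="average_local"`` gives the mean local clustering
    instead.  Graphs with no connected triple score 0.  Self-loops are
    ignored, as neither definition is meaningful for them.
    """
    u = undirected_projection(gsn) if gsn.is_directed() else gsn.copy()
    u.remove_edges_from(nx.selfloop_edges(u))
    if method == "transitivity":
        return nx.transitivity(u)
    if method == "average_local":
        return nx.average_clustering(u) if u.number_of_nodes() else 0.0
    raise ValueError(f"unknown clustering method {method!r}")


def average_path_length(gsn: nx.DiGraph | nx.Graph) -> float:
    """Mean shortest-path hop count within the largest connected component.

    Computed on the undirected unweighted projection over all ordered pairs
    of distinct nodes.  Raises :class:`ValidationError` when the largest
    component has fewer than two nodes (the quantity is undefined).
    """
    u = undirected_projection(gsn) if gsn.is_directed() else gsn
    if u.number_of_nodes() == 0:
        raise ValidationError("average path length undefined on an empty graph")
    giant = max(nx.connected_components(u), key=len)
    if len(giant) < 2:
        raise ValidationError(
            "average path length undefined: largest component has < 2 nodes"
        )
    return nx.average_shortest_path_length(u.subgraph(giant))


def detect_communities(gsn: nx.DiGraph | nx.Graph, seed: int = 0) -> CommunityPartition:
    """Louvain modularity maximization on the weighted undirected projection.

    Deterministic for a fixed seed.  Community ids are renumbered
    contiguously from 0 in order of each community's smallest node label.
    """
    u = undirected_projection(gsn) if gsn.is_directed() else gsn
    if u.number_of_nodes() < 1:
        raise ValidationError("community detection requires at least one node")
    comms = nx.community.louvain_communities(u, weight="weight", seed=seed)
    comms = sorted(comms, key=min)
    membership = {node: cid for cid, comm in enumerate(comms) for node in comm}
    q = nx.community.modularity(u, comms, weight="weight") if u.number_of_edges() else 0.0
    return CommunityPartition(membership=membership, modularity=q, seed=seed)


def network_summary(gsn: nx.DiGraph, seed: int = 0) -> NetworkSummary:
    """Compute the six-statistic structural summary of one GSN.

    ``n_links`` counts distinct weighted zip-pair edges, not raw
    transplants.  ``avg_path_length`` is ``nan`` when undefined.
    """
    n_nodes = gsn.number_of_nodes()
    n_links = gsn.number_of_edges()
    avg_degree = n_links / n_nodes if n_nodes else 0.0
    cc = clustering_coefficient(gsn)
    try:
        length = average_path_length(gsn)
    except ValidationError:
        length = math.nan
    n_c = detect_communities(gsn, seed=seed).n_communities if n_nodes else 0
    return NetworkSummary(
        group=gsn.graph.get("recipient_group", "all"),
        n_nodes=n_nodes,
        n_links=n_links,
        avg_degree=avg_degree,
        clustering=cc,
        avg_path_length=length,
        n_communities=n_c,
    )


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres (spherical Earth, R = 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def community_dispersion(partition: CommunityPartition, gsn: nx.Graph) -> dict[int, float]:
    """Mean pairwise great-circle distance (km) of each community's nodes.

    Geographic dispersion distinguishes compact communities from ones whose
    members are scattered across the map.  Singleton communities score 0.
    """
    by_comm: dict[int, list[tuple[float, float]]] = {}
    for node, cid in partition.membership.items():
        data = gsn.nodes[node]
        if "lat" not in data or "lon" not in data:
            raise ValidationError(f"node {node!r} is missing coordinates")
        by_comm.setdefault(cid, []).append((data["lat"], data["lon"]))
    out: dict[int, float] = {}
    for cid, coords in sorted(by_comm.items()):
        n = len(coords)
        if n < 2:
            out[cid] = 0.0
            continue
        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                total += haversine_km(*coords[i], *coords[j])
        out[cid] = total / (n * (n - 1) / 2)
    return out
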