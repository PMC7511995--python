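"""Community-aware backbone extractors for weighted networks.

Two extractors are provided.  The *ego* backbone keeps the overlapping
nodes of a community cover together with their one-step neighbors; the
*hubs* backbone keeps the overlapping nodes together with an equally sized
set of the strongest remaining nodes.  Both then drop the weakest edges
while preserving connectivity and finally cut the node set down to a
fraction ``s`` of the original network, privileging top-ranked nodes.
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .community_slpa import CommunityCover, overlapping_nodes
from .graph_io import node_sort_key, weighted_degree

__all__ = [
    "Backbone",
    "NoOverlapError",
    "ego_subnetwork",
    "hubs_subnetwork",
    "prune_edges",
    "apply_size_threshold",
    "extract_backbone",
]


class NoOverlapError(ValueError):
    """The cover has no overlapping nodes, so the method is undefined."""


@dataclass
class Backbone:
    """A backbone subgraph plus the provenance of its extraction."""

    subgraph: nx.Graph
    method: str  # ego | hubs | disparity
    s: Optional[float] = None
    alpha: Optional[float] = None
    seed: Optional[int] = None
    m: Optional[int] = None  # overlapping-node count
    k: Optional[int] = None  # neighbor-set size
    t: Optional[int] = None  # hub count

    @property
    def nodes(self) -> set:
        return set(self.subgraph.nodes)

    def __repr__(self) -> str:  # provenance-first, subgraph summarized
        return (
            f"Backbone(method={self.method!r}, n={self.subgraph.number_of_nodes()}, "
            f"e={self.subgraph.number_of_edges()}, s={self.s}, alpha={self.alpha}, "
            f"m={self.m}, k={self.k}, t={self.t})"
        )


def _overlap_and_neighbors(g: nx.Graph, cover: CommunityCover):
    cover.validate_cover(g)
    v_o = overlapping_nodes(cover) & set(g.nodes)
    if not v_o:
        raise NoOverlapError("no overlap in cover: every node has a single community")
    v_no = set()
    for v in v_o:
        v_no.update(g.neighbors(v))
    v_no -= v_o
    return v_o, v_no


def ego_subnetwork(g: nx.Graph, cover: CommunityCover) -> nx.Graph:
    """Induced subgraph on the overlapping nodes and their neighbors."""
    v_o, v_no = _overlap_and_neighbors(g, cover)
    return g.subgraph(v_o | v_no).copy()


def hubs_subnetwork(g: nx.Graph, cover: CommunityCover) -> nx.Graph:
    """Induced subgraph on the overlapping nodes and the top-strength hubs.

    The hub count t equals the neighbor-set size of the ego variant, so both
    subnetworks have the same number of nodes; hubs are drawn from outside
    the overlapping set (clamped to the whole graph when t exceeds it).
    """
    v_o, v_no = _overlap_and_neighbors(g, cover)
    t = len(v_no)
    candidates = sorted(
        set(g.nodes) - v_o,
        key=lambda v: (-weighted_degree(g, v), node_sort_key(v)),
    )
    v_h = set(candidates[:t])
    return g.subgraph(v_o | v_h).copy()


def _edge_order(sub: nx.Graph):
    # ascending weight; ties broken on the lexicographic endpoint pair
    def key(e):
        u, v, data = e
        a, b = sorted((node_sort_key(u), node_sort_key(v)))
        return (data["weight"], a, b)

    return sorted(sub.edges(data=True), key=key)


def prune_edges(sub: nx.Graph) -> nx.Graph:
    """Remove low-weight edges as long as no component is split.

    Edges are visited in ascending weight order; an edge is deleted iff its
    endpoints remain connected without it.  The survivors therefore contain
    a maximum-weight spanning forest of ``sub``.
    """
    if sub.number_of_nodes() == 0:
        raise ValueError("empty subgraph")
    h = sub.copy()
    for u, v, data in _edge_order(sub):
        h.remove_edge(u, v)
        if not nx.has_path(h, u, v):
            h.add_edge(u, v, **data)
    return h


def apply_size_threshold(sub: nx.Graph, g: nx.Graph, s: float) -> nx.Graph:
    """Trim ``sub`` to at most ``floor(s * N_g)`` nodes.

    Greedily removes the node with the lowest weighted degree in the
    original graph ``g`` whose removal does not split any component of
    ``sub``.  If every candidate would split a component but the subgraph is
    still too large, the lowest-degree node is removed anyway and only the
    largest connected component is kept.
    """
    if not (0 < s <= 1):
        raise ValueError(f"s must be in (0, 1], got {s}")
    target = max(1, math.floor(s * g.number_of_nodes()))
    h = sub.copy()

    def removal_order():
        return sorted(h.nodes, key=lambda v: (weighted_degree(g, v), node_sort_key(v)))

    while h.number_of_nodes() > target:
        base = nx.number_connected_components(h)
        removed = False
        for v in removal_order():
            incident = [(v, u, h[v][u]) for u in h.neighbors(v)]
            h.remove_node(v)
            if nx.number_connected_components(h) <= base:
                removed = True
                break
            h.add_node(v)
            for a, b, data in incident:
                h.add_edge(a, b, **data)
        if not removed:
            h.remove_node(removal_order()[0])
            comps = sorted(
                nx.connected_components(h),
                key=lambda c: (-len(c), min(node_sort_key(v) for v in c)),
            )
            h = h.subgraph(comps[0]).copy()
    return h


def extract_backbone(
    g: nx.Graph,
    cover: Optional[CommunityCover] = None,
    method: str = "ego",
    s: float = 1.0,
    seed: Optional[int] = None,
    alpha: Optional[float] = None,
) -> Backbone:
    """Full extraction pipeline for one method.

    For ``ego`` and ``hubs``: build the subnetwork, prune low-weight edges
    under the connectivity constraint, apply the size threshold ``s``
    (weighted degree measured on the original graph), and re-prune to drop
    dangling low-weight edges reintroduced by node deletion.  ``disparity``
    delegates to :mod:`netbackbone.disparity_filter` (``alpha`` explicit, or
    calibrated to match ``floor(s * N)`` nodes).
    """
    if method == "disparity":
        from . import disparity_filter

        if alpha is None:
            alpha = disparity_filter.calibrate_alpha(g, target_fraction=s)
        bb = disparity_filter.disparity_backbone(g, alpha)
        bb.s = s
        bb.seed = seed
        return bb
    if method not in ("ego", "hubs"):
        raise ValueError(f"unknown method {method!r}")
    if cover is None:
        raise ValueError(f"method {method!r} requires a community cover")

    v_o, v_no = _overlap_and_neighbors(g, cover)
    sub = ego_subnetwork(g, cover) if method == "ego" else hubs_subnetwork(g, cover)
    pruned = prune_edges(sub)
    cut = apply_size_threshold(pruned, g, s)
    final = prune_edges(cut)
    if not nx.is_connected(final):
        # the subnetwork itself may come in several components; the backbone
        # is defined as a single component, so keep the largest one
        comps = sorted(
            nx.connected_components(final),
            key=lambda c: (-len(c), min(node_sort_key(v) for v in c)),
        )
        final = final.subgraph(comps[0]).copy()
    return Backbone(
        subgraph=final,
        method=method,
        s=s,
        seed=seed,
        m=len(v_o),
        k=len(v_no),
        t=len(v_no),
    )
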