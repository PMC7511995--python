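"""Synthetic weighted graphs with planted overlapping communities, plus the
two bundled real fixtures (karate, lesmis) stored as plain edge lists."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import FrozenSet, Hashable

import networkx as nx
import numpy as np

from .community_slpa import CommunityCover
from .graph_io import node_sort_key, read_graph

__all__ = ["PlantedOverlapSpec", "generate", "load_fixture", "FIXTURES"]

FIXTURES = {"karate": "karate.edgelist", "lesmis": "lesmis.edgelist"}


@dataclass(frozen=True)
class PlantedOverlapSpec:
    """Parameters of the planted-overlap generator.

    Communities are arranged in a ring; each adjacent pair shares
    ``overlap_per_pair`` nodes, which belong to both communities and draw
    intra-community edges into each.  ``community_size`` counts shared
    nodes, so two communities of 10 sharing 2 yield 18 distinct nodes.
    Weights are discretized log-normals: intra-community edges use
    ``weight_in_mean``, sparser inter-community edges the lower
    ``weight_out_mean``.
    """

    n_communities: int = 3
    community_size: int = 20
    overlap_per_pair: int = 2
    p_in: float = 0.3
    p_out: float = 0.02
    weight_in_mean: float = 6.0
    weight_out_mean: float = 2.0
    weight_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_communities < 2:
            raise ValueError("need at least two communities")
        if self.community_size < 1 or self.overlap_per_pair < 0:
            raise ValueError("sizes must be positive")
        if not (0 < self.p_in <= 1) or not (0 <= self.p_out <= 1):
            raise ValueError("edge probabilities must lie in (0, 1]")
        if self.p_out >= self.p_in:
            raise ValueError("p_out must be smaller than p_in")
        pairs_per_community = 1 if self.n_communities == 2 else 2
        if self.overlap_per_pair * pairs_per_community >= self.community_size:
            raise ValueError("overlap exceeds community size")
        if self.weight_in_mean <= 0 or self.weight_out_mean <= 0:
            raise ValueError("weight means must be positive")
        if self.weight_out_mean > self.weight_in_mean:
            raise ValueError("inter-community weights must not exceed intra")


def _draw_weight(rng: np.random.Generator, mean: float, sigma: float) -> float:
    # log-normal with the requested continuous mean, rounded to an integer
    # count (floored at 1) to resemble co-appearance/message-count data
    mu = np.log(mean) - sigma**2 / 2
    return float(max(1, round(rng.lognormal(mu, sigma))))


def generate(spec: PlantedOverlapSpec) -> tuple[nx.Graph, CommunityCover]:
    """Draw a weighted planted-overlap graph and its ground-truth cover.

    Deterministic under ``spec.seed``; the result is always connected
    (components are deterministically bridged if sampling leaves gaps).
    """
    rng = np.random.default_rng(spec.seed)
    c = spec.n_communities
    pairs = [(0, 1)] if c == 2 else [(i, (i + 1) % c) for i in range(c)]

    counter = 0

    def new_node() -> str:
        nonlocal counter
        name = f"n{counter:04d}"
        counter += 1
        return name

    members: dict[int, list[str]] = {i: [] for i in range(c)}
    membership: dict[Hashable, set[str]] = {}
    for a, b in pairs:
        for _ in range(spec.overlap_per_pair):
            v = new_node()
            members[a].append(v)
            members[b].append(v)
            membership[v] = {f"c{a}", f"c{b}"}
    for i in range(c):
        while len(members[i]) < spec.community_size:
            v = new_node()
            members[i].append(v)
            membership[v] = {f"c{i}"}

    g = nx.Graph()
    g.add_nodes_from(membership)
    for i in range(c):
        comm = sorted(members[i], key=node_sort_key)
        for idx, u in enumerate(comm):
            for v in comm[idx + 1 :]:
                if g.has_edge(u, v):
                    continue
                if rng.random() < spec.p_in:
                    g.add_edge(
                        u, v, weight=_draw_weight(rng, spec.weight_in_mean, spec.weight_sigma)
                    )
    all_nodes = sorted(membership, key=node_sort_key)
    for idx, u in enumerate(all_nodes):
        for v in all_nodes[idx + 1 :]:
            if membership[u] & membership[v] or g.has_edge(u, v):
                continue
            if rng.random() < spec.p_out:
                g.add_edge(
                    u, v, weight=_draw_weight(rng, spec.weight_out_mean, spec.weight_sigma)
                )

    # deterministic repair: bridge any stray components into the one holding
    # the lexicographically smallest node
    comps = sorted(nx.connected_components(g), key=lambda s: min(map(node_sort_key, s)))
    anchor = min(comps[0], key=node_sort_key)
    for comp in comps[1:]:
        v = min(comp, key=node_sort_key)
        g.add_edge(anchor, v, weight=_draw_weight(rng, spec.weight_out_mean, spec.weight_sigma))

    cover = CommunityCover({v: frozenset(labs) for v, labs in membership.items()}, seed=spec.seed)
    return g, cover


def planted_overlap(cover: CommunityCover) -> FrozenSet:
    """Ground-truth overlapping nodes of a generated cover."""
    return frozenset(v for v, labs in cover.membership.items() if len(labs) >= 2)


def load_fixture(name: str) -> nx.Graph:
    """Load a bundled weighted network (``karate``: N=34, ``lesmis``: N=77)."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    ref = resources.files("netbackbone").joinpath("data", FIXTURES[name])
    with resources.as_file(ref) as path:
        return read_graph(path, format="edgelist")
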