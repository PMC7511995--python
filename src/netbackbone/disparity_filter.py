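"""Disparity-filter baseline: per-incidence significance of edge weights.

For a node i of degree k >= 2, each incident weight is normalized by the
node strength (p_ij = w_ij / s_i) and tested against a null in which the
k normalized weights are uniformly spread, giving the closed-form score
alpha_ij = (1 - p_ij)^(k - 1).  Degree-one incidences score 1 (never
significant on that side).  An edge survives at level ``alpha`` iff it is
significant for at least one endpoint, and the resulting backbone may be
disconnected — no connectivity repair is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Hashable, Tuple

import networkx as nx
import numpy as np

from .backbone_extraction import Backbone
from .graph_io import weighted_degree

__all__ = [
    "DisparityScores",
    "disparity_scores",
    "edge_score",
    "disparity_backbone",
    "calibrate_alpha",
]


@dataclass(frozen=True)
class DisparityScores:
    """Directed incidence (i, j) -> alpha_ij in [0, 1]."""

    scores: Dict[Tuple[Hashable, Hashable], float]

    def __getitem__(self, incidence: Tuple[Hashable, Hashable]) -> float:
        return self.scores[incidence]


def disparity_scores(g: nx.Graph) -> DisparityScores:
    """Score every directed incidence of ``g``."""
    scores: Dict[Tuple[Hashable, Hashable], float] = {}
    for i in g.nodes:
        k = g.degree(i)
        if k == 0:
            continue
        if k == 1:
            (j,) = g.neighbors(i)
            scores[(i, j)] = 1.0
            continue
        strength = weighted_degree(g, i)
        for j in g.neighbors(i):
            p = g[i][j]["weight"] / strength
            scores[(i, j)] = (1.0 - p) ** (k - 1)
    return DisparityScores(scores)


def edge_score(scores: DisparityScores, u: Hashable, v: Hashable) -> float:
    """Smaller (more significant) of the two per-endpoint scores of an edge."""
    return min(scores.scores[(u, v)], scores.scores[(v, u)])


def disparity_backbone(g: nx.Graph, alpha: float) -> Backbone:
    """Keep each edge iff alpha_ij < alpha for at least one endpoint.

    Backbone nodes are the endpoints of kept edges; the subgraph may be
    disconnected.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    scores = disparity_scores(g)
    sub = nx.Graph()
    for u, v, data in g.edges(data=True):
        if edge_score(scores, u, v) < alpha:
            sub.add_edge(u, v, **data)
    return Backbone(subgraph=sub, method="disparity", alpha=alpha)


def _node_count_at(g: nx.Graph, scores: DisparityScores, alpha: float) -> int:
    nodes = set()
    for u, v in g.edges:
        if edge_score(scores, u, v) < alpha:
            nodes.add(u)
            nodes.add(v)
    return len(nodes)


def calibrate_alpha(g: nx.Graph, target_fraction: float) -> float:
    """Smallest significance level whose backbone node count is closest to
    ``floor(target_fraction * N)``.

    The node count is a step function of alpha that only changes at the
    distinct per-edge scores, so all candidate thresholds are enumerated
    exactly instead of bisected numerically.
    """
    if not (0 < target_fraction <= 1):
        raise ValueError(f"target_fraction must be in (0, 1], got {target_fraction}")
    target = math.floor(target_fraction * g.number_of_nodes())
    scores = disparity_scores(g)
    edge_scores = sorted({edge_score(scores, u, v) for u, v in g.edges})
    # thresholds just above each distinct score flip that score's edges on;
    # alpha must stay strictly inside (0, 1)
    candidates = [s for s in edge_scores if 0 < s < 1]
    candidates += [float(np.nextafter(s, 1.0)) for s in edge_scores if np.nextafter(s, 1.0) < 1]
    candidates = sorted(set(candidates))
    if not candidates:
        warnings.warn("no tunable edge scores; returning alpha=0.5 (empty backbone)")
        return 0.5

    best_alpha, best_count = None, None
    for alpha in candidates:
        count = _node_count_at(g, scores, alpha)
        if best_alpha is None or abs(count - target) < abs(best_count - target):
            best_alpha, best_count = alpha, count
    if best_count != target:
        warnings.warn(
            f"target node count {target} unreachable; best achievable is "
            f"{best_count} at alpha={best_alpha}"
        )
    return best_alpha
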