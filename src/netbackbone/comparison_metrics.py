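"""Similarity and effectiveness measures for comparing backbones.

Backbone node sets are compared as ranked lists ordered by weighted degree
in the original network: common-node proportion, top-ranked-node overlap,
rank-biased overlap at several patience values, Pearson correlation of the
positional degree profiles, and Kendall tau-a on their dense ranks.
Effectiveness of a single backbone is summarized by the mean normalized
betweenness, mean weighted degree and mean surviving-edge weight of its
subgraph.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .backbone_extraction import Backbone
from .graph_io import RankedNode, rank_nodes

__all__ = [
    "ComparisonReport",
    "common_node_proportion",
    "top_t_overlap",
    "rank_biased_overlap",
    "pearson_correlation",
    "kendall_tau",
    "effectiveness",
    "compare_pair",
    "compare_backbones",
]

DEFAULT_P_VALUES = (0.5, 0.7, 0.8, 0.9, 0.98)


def common_node_proportion(x: Iterable, y: Iterable) -> float:
    """|X ∩ Y| / n for two node sets of common size n.

    Unequal sizes are tolerated with a warning, using the smaller size as n
    (truncation of ranked lists is handled by the caller).
    """
    xs, ys = set(x), set(y)
    if not xs and not ys:
        raise ValueError("both node sets are empty")
    if len(xs) != len(ys):
        warnings.warn(f"node sets differ in size ({len(xs)} vs {len(ys)}); using min")
    n = min(len(xs), len(ys))
    return len(xs & ys) / n


def top_t_overlap(g: nx.Graph, backbone_nodes: Iterable, t_fraction: float = 0.1) -> float:
    """Overlap between the graph's top-t strength nodes and the backbone's.

    t = max(1, floor(t_fraction * N)).  If the backbone holds fewer than t
    nodes, all of them are used (with a warning).
    """
    t = max(1, math.floor(t_fraction * g.number_of_nodes()))
    backbone_nodes = set(backbone_nodes)
    top_global = {e.node for e in rank_nodes(g)[:t]}
    ranked_backbone = rank_nodes(g, backbone_nodes)
    if len(ranked_backbone) < t:
        warnings.warn(f"backbone smaller than t={t}; comparing all {len(ranked_backbone)} nodes")
    top_backbone = {e.node for e in ranked_backbone[:t]}
    return len(top_global & top_backbone) / t


def _ids(ranked: Sequence) -> list:
    return [e.node if isinstance(e, RankedNode) else e[0] for e in ranked]


def rank_biased_overlap(
    x: Sequence, y: Sequence, p: float, normalized: bool = True
) -> float:
    """Rank-biased overlap of two ranked lists at patience ``p``.

    r = sum_{d=1..D} (1-p) p^(d-1) |X_:d ∩ Y_:d| / d with D the shorter
    length.  With ``normalized`` the geometric weights are renormalized by
    their finite-depth mass (1 - p^D) so identical lists score exactly 1.
    """
    if not (0 < p < 1):
        raise ValueError(f"p must be in (0, 1), got {p}")
    xs, ys = _ids(x), _ids(y)
    if not xs or not ys:
        raise ValueError("ranked lists must be non-empty")
    depth = min(len(xs), len(ys))
    seen_x: set = set()
    seen_y: set = set()
    overlap = 0
    r = 0.0
    for d in range(1, depth + 1):
        a, b = xs[d - 1], ys[d - 1]
        if a == b:
            overlap += 1
        else:
            if a in seen_y:
                overlap += 1
            if b in seen_x:
                overlap += 1
            seen_x.add(a)
            seen_y.add(b)
        r += (1 - p) * p ** (d - 1) * overlap / d
    if normalized:
        r /= 1 - p**depth
    return r


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length sequences."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("sequences must be one-dimensional and of equal length")
    if xa.size < 2:
        raise ValueError("need at least two observations")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    denom = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(dx @ dy) / denom


def _dense_ranks(values: Sequence[float]) -> np.ndarray:
    # descending values -> rank 1 for the largest; equal values share a rank
    arr = np.asarray(values, dtype=float)
    distinct = np.unique(arr)[::-1]
    lookup = {v: i + 1 for i, v in enumerate(distinct)}
    return np.array([lookup[v] for v in arr])


def kendall_tau(x: Sequence, y: Sequence) -> float:
    """Kendall tau-a between two ranked lists, paired by position.

    Degrees are converted to dense ranks (tied degrees share a rank); pairs
    tied in either ranking count neither as concordant nor discordant, but
    the denominator stays n(n-1)/2.
    """

    def degrees(seq):
        return [e.weighted_degree if isinstance(e, RankedNode) else float(e[1]) for e in seq]

    n = min(len(x), len(y))
    if n < 2:
        raise ValueError("need at least two ranked entries")
    rx = _dense_ranks(degrees(x)[:n])
    ry = _dense_ranks(degrees(y)[:n])
    sign_x = np.sign(np.subtract.outer(rx, rx))
    sign_y = np.sign(np.subtract.outer(ry, ry))
    upper = np.triu_indices(n, k=1)
    prod = sign_x[upper] * sign_y[upper]
    n_c = int(np.sum(prod > 0))
    n_d = int(np.sum(prod < 0))
    return (n_c - n_d) / (n * (n - 1) / 2)


def effectiveness(
    backbone: Backbone, weighted_paths: bool = False
) -> Tuple[float, float, float]:
    """(mean normalized betweenness, mean weighted degree, mean edge weight)
    of the backbone subgraph.

    Betweenness uses unweighted shortest paths by default (switch with
    ``weighted_paths``) and networkx's (n-1)(n-2)/2 normalization; graphs
    with fewer than three nodes get mean betweenness 0 by convention.
    """
    sub = backbone.subgraph
    n = sub.number_of_nodes()
    if n == 0:
        raise ValueError("empty backbone")
    if n < 3:
        beta = 0.0
    else:
        bc = nx.betweenness_centrality(
            sub, normalized=True, weight="weight" if weighted_paths else None
        )
        beta = float(np.mean(list(bc.values())))
    k = float(np.mean([sub.degree(v, weight="weight") for v in sub.nodes]))
    if sub.number_of_edges() == 0:
        w = 0.0
    else:
        w = float(np.mean([d["weight"] for *_, d in sub.edges(data=True)]))
    return beta, k, w


def compare_pair(
    g: nx.Graph,
    b1: Backbone,
    b2: Backbone,
    p_values: Sequence[float] = DEFAULT_P_VALUES,
    size: Optional[int] = None,
) -> Dict[str, float]:
    """All pairwise similarity measures between two backbones of ``g``.

    Node sets are ranked by weighted degree in the original graph and
    truncated to a common size (``size`` if given, else the smaller set).
    """
    r1 = rank_nodes(g, b1.nodes)
    r2 = rank_nodes(g, b2.nodes)
    n = min(len(r1), len(r2))
    if size is not None:
        n = min(n, size)
    if n == 0:
        raise ValueError("cannot compare empty backbones")
    r1, r2 = r1[:n], r2[:n]
    out: Dict[str, float] = {
        "A_n": common_node_proportion(_ids(r1), _ids(r2)),
    }
    for p in p_values:
        out[f"rbo_p{p}"] = rank_biased_overlap(r1, r2, p)
    deg1 = [e.weighted_degree for e in r1]
    deg2 = [e.weighted_degree for e in r2]
    try:
        out["pearson"] = pearson_correlation(deg1, deg2)
    except ValueError:
        out["pearson"] = float("nan")
    out["kendall"] = kendall_tau(r1, r2) if n >= 2 else float("nan")
    return out


@dataclass
class ComparisonReport:
    """Means and standard deviations of every measure across runs.

    Keys are ``(measure, subject)`` where the subject is a method pair like
    ``"ego-hubs"`` for similarity measures or a single method name for
    effectiveness and top-t overlap.
    """

    means: Dict[Tuple[str, str], float] = field(default_factory=dict)
    stds: Dict[Tuple[str, str], float] = field(default_factory=dict)
    n_runs: int = 0

    def to_frame(self):
        import pandas as pd

        rows = [
            {"measure": m, "subject": s, "mean": v, "std": self.stds[(m, s)]}
            for (m, s), v in sorted(self.means.items())
        ]
        return pd.DataFrame(rows, columns=["measure", "subject", "mean", "std"])


def compare_backbones(
    g: nx.Graph,
    runs: Sequence[Sequence[Backbone]],
    p_values: Sequence[float] = DEFAULT_P_VALUES,
    t_fraction: float = 0.1,
    size: Optional[int] = None,
) -> ComparisonReport:
    """Aggregate all pairwise and per-backbone measures over multiple runs.

    ``runs`` holds one list of (>= 2) backbones per run, e.g. one per
    detector seed; means and stds are taken across runs.
    """
    if not runs:
        raise ValueError("no runs supplied")
    samples: Dict[Tuple[str, str], list] = {}

    def record(measure: str, subject: str, value: float) -> None:
        samples.setdefault((measure, subject), []).append(value)

    for backbones in runs:
        if len(backbones) < 2:
            raise ValueError("each run needs at least two backbones")
        for b1, b2 in itertools.combinations(backbones, 2):
            pair = f"{b1.method}-{b2.method}"
            for measure, value in compare_pair(g, b1, b2, p_values, size).items():
                record(measure, pair, value)
        for b in backbones:
            beta, k, w = effectiveness(b)
            record("beta", b.method, beta)
            record("k", b.method, k)
            record("w", b.method, w)
            record("A_t", b.method, top_t_overlap(g, b.nodes, t_fraction))

    report = ComparisonReport(n_runs=len(runs))
    for key, values in samples.items():
        arr = np.asarray(values, dtype=float)
        report.means[key] = float(arr.mean())
        report.stds[key] = float(arr.std())
    return report
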