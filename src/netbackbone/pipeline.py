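"""Multi-seed extraction/comparison pipeline shared by the CLI and scripts."""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import networkx as nx

from .backbone_extraction import Backbone, extract_backbone
from .community_slpa import CommunityCover, overlapping_nodes, slpa
from .comparison_metrics import DEFAULT_P_VALUES, ComparisonReport, compare_backbones

__all__ = ["covers_for_seeds", "run_comparison"]


def covers_for_seeds(
    g: nx.Graph,
    n_runs: int,
    seed: int,
    t_iter: int = 100,
    r: float = 0.1,
    max_attempts_factor: int = 10,
) -> list[CommunityCover]:
    """Detect ``n_runs`` covers with overlapping nodes, one per seed.

    Seeds count up from ``seed``; seeds whose cover has no overlapping node
    are skipped (the extractors are undefined there) up to a bounded number
    of attempts.
    """
    covers: list[CommunityCover] = []
    attempts = 0
    current = seed
    while len(covers) < n_runs and attempts < n_runs * max_attempts_factor:
        cover = slpa(g, t_iter=t_iter, r=r, seed=current)
        if overlapping_nodes(cover):
            covers.append(cover)
        else:
            warnings.warn(f"seed {current}: cover has no overlapping nodes; skipped")
        current += 1
        attempts += 1
    if len(covers) < n_runs:
        raise RuntimeError(
            f"could only find {len(covers)}/{n_runs} covers with overlap "
            f"after {attempts} attempts"
        )
    return covers


def run_comparison(
    g: nx.Graph,
    methods: Sequence[str] = ("ego", "hubs", "disparity"),
    s: float = 0.3,
    n_runs: int = 10,
    seed: int = 0,
    t_iter: int = 100,
    r: float = 0.1,
    p_values: Sequence[float] = DEFAULT_P_VALUES,
    covers: Optional[Sequence[CommunityCover]] = None,
) -> ComparisonReport:
    """Extract every method per detector run and aggregate all measures."""
    if covers is None:
        covers = covers_for_seeds(g, n_runs, seed, t_iter=t_iter, r=r)
    runs: list[list[Backbone]] = []
    for cover in covers:
        backbones = [
            extract_backbone(g, cover=cover, method=m, s=s, seed=cover.seed)
            for m in methods
        ]
        runs.append(backbones)
    return compare_backbones(g, runs, p_values=p_values)
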