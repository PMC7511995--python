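"""Overlapping community detection with speaker-listener label propagation.

Each node starts with its own label in memory.  For ``t_iter`` rounds every
node, visited in a seed-shuffled order, listens to one label from each
neighbor (the speaker samples from its memory proportionally to label
frequencies) and appends the most frequent received label to its own memory.
Afterwards a node keeps every label whose memory frequency reaches the
retention threshold ``r``; nodes retaining two or more labels are the
overlapping nodes.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, Hashable, Mapping, Optional

import networkx as nx

from .graph_io import node_sort_key

__all__ = [
    "CommunityCover",
    "slpa",
    "overlapping_nodes",
    "read_cover",
    "write_cover",
]


@dataclass(frozen=True)
class CommunityCover:
    """Node -> non-empty set of community labels (a cover, not a partition)."""

    membership: Mapping[Hashable, FrozenSet[str]]
    t_iter: Optional[int] = None
    r: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self):
        for v, labels in self.membership.items():
            if not labels:
                raise ValueError(f"node {v!r} has no community label")

    def communities(self) -> dict[str, set]:
        """Invert the membership map: label -> set of member nodes."""
        out: dict[str, set] = {}
        for v, labels in self.membership.items():
            for lab in labels:
                out.setdefault(lab, set()).add(v)
        return out

    def validate_cover(self, g: nx.Graph) -> None:
        missing = set(g.nodes) - set(self.membership)
        if missing:
            raise ValueError(
                f"cover is missing {len(missing)} graph node(s), e.g. "
                f"{sorted(map(str, missing))[:5]}"
            )


def _most_frequent(counts: Counter) -> str:
    # highest count, ties -> lexicographically smallest label
    return min(counts, key=lambda lab: (-counts[lab], lab))


def slpa(
    g: nx.Graph,
    t_iter: int = 100,
    r: float = 0.1,
    seed: int = 0,
    weighted: bool = False,
    tie_break: str = "random",
) -> CommunityCover:
    """Run SLPA on ``g`` and return the retained overlapping cover.

    Parameters
    ----------
    g : networkx.Graph
        Weighted undirected graph.
    t_iter : int
        Number of propagation rounds (>= 1).
    r : float
        Retention threshold in (0, 1]; a label survives post-processing iff
        its memory frequency is at least ``r``.  If no label of a node
        qualifies, the single most frequent one is kept.
    seed : int
        Seed driving both the per-round node shuffle and speaker sampling;
        fixed seed gives an identical cover.
    weighted : bool
        If True, a listener tallies each received label with the weight of
        the edge it arrived on instead of a unit count (classic SLPA is
        unweighted; off by default).
    tie_break : {"random", "lexicographic"}
        How a listener resolves ties among equally frequent received labels.
        ``random`` (seed-driven, the classic rule) is the default;
        ``lexicographic`` always picks the smallest label, which biases the
        dynamics toward takeover by small labels and yields far fewer
        overlapping nodes.
    """
    if t_iter < 1:
        raise ValueError(f"t_iter must be >= 1, got {t_iter}")
    if not (0 < r <= 1):
        raise ValueError(f"r must be in (0, 1], got {r}")
    if tie_break not in ("random", "lexicographic"):
        raise ValueError(f"unknown tie_break {tie_break!r}")

    rng = random.Random(seed)
    memory: dict[Hashable, Counter] = {v: Counter({str(v): 1}) for v in g.nodes}
    nodes = sorted(g.nodes, key=node_sort_key)

    for _ in range(t_iter):
        order = nodes[:]
        rng.shuffle(order)
        for listener in order:
            received: Counter = Counter()
            for speaker in sorted(g.neighbors(listener), key=node_sort_key):
                mem = memory[speaker]
                labels = sorted(mem)
                spoken = rng.choices(labels, weights=[mem[lab] for lab in labels])[0]
                tally = g[listener][speaker].get("weight", 1.0) if weighted else 1
                received[spoken] += tally
            if not received:
                continue  # isolated node keeps its own label
            if tie_break == "random":
                top = max(received.values())
                winner = rng.choice(sorted(lab for lab, c in received.items() if c == top))
            else:
                winner = _most_frequent(received)
            memory[listener][winner] += 1

    membership: dict[Hashable, FrozenSet[str]] = {}
    for v, mem in memory.items():
        total = sum(mem.values())
        kept = frozenset(lab for lab, c in mem.items() if c / total >= r)
        if not kept:
            kept = frozenset({_most_frequent(mem)})
        membership[v] = kept
    return CommunityCover(membership, t_iter=t_iter, r=r, seed=seed)


def overlapping_nodes(cover: CommunityCover) -> set:
    """Nodes assigned to two or more communities; may be empty."""
    return {v for v, labels in cover.membership.items() if len(labels) >= 2}


def read_cover(path) -> CommunityCover:
    """Read a cover file: one line per node, ``node_id label1,label2,...``."""
    membership: dict[Hashable, FrozenSet[str]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'node label1,label2,...'")
            node, labels = parts
            labs = frozenset(lab for lab in labels.split(",") if lab)
            if not labs:
                raise ValueError(f"{path}:{lineno}: node {node!r} has no labels")
            membership[node] = labs
    if not membership:
        raise ValueError(f"{path}: empty cover file")
    return CommunityCover(membership)


def write_cover(cover: CommunityCover, path) -> None:
    with open(path, "w") as fh:
        for v in sorted(cover.membership, key=node_sort_key):
            fh.write(f"{v} {','.join(sorted(cover.membership[v]))}\n")
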