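"""Read/write weighted networks and elementary weighted measures.

Graphs are plain :class:`networkx.Graph` objects whose edges all carry a
strictly positive ``weight`` attribute.  Node identifiers are opaque; every
deterministic tie-break in the package is lexicographic on ``str(node)``.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Hashable, Iterable, NamedTuple, Optional, Sequence

import networkx as nx

__all__ = [
    "GraphFormatError",
    "RankedNode",
    "read_graph",
    "write_graph",
    "validate_graph",
    "weighted_degree",
    "rank_nodes",
    "node_sort_key",
]

_FORMATS = ("edgelist", "gml", "graphml")


class GraphFormatError(ValueError):
    """Raised when an input file cannot be parsed as a weighted graph."""


class RankedNode(NamedTuple):
    node: Hashable
    weighted_degree: float


def node_sort_key(v: Hashable) -> str:
    """Total order on node identifiers used for every tie-break."""
    return str(v)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("gml",):
        return "gml"
    if suffix in ("graphml", "xml"):
        return "graphml"
    return "edgelist"


def _check_weight(raw, where: str) -> float:
    try:
        w = float(raw)
    except (TypeError, ValueError):
        raise GraphFormatError(f"non-numeric edge weight {raw!r} at {where}")
    if not math.isfinite(w) or w <= 0:
        raise GraphFormatError(f"edge weight must be positive, got {raw!r} at {where}")
    return w


def _read_edgelist(path: Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'u v w', weights required"
                )
            u, v, raw_w = parts[0], parts[1], parts[2]
            w = _check_weight(raw_w, f"{path}:{lineno}")
            _add_edge(g, u, v, w, f"{path}:{lineno}")
    return g


def _add_edge(g: nx.Graph, u, v, w: float, where: str) -> None:
    if u == v:
        warnings.warn(f"self-loop on {u!r} dropped ({where})")
        return
    if g.has_edge(u, v):
        old = g[u][v]["weight"]
        if old != w:
            warnings.warn(
                f"duplicate edge {u!r}-{v!r} collapsed to max weight ({where})"
            )
        g[u][v]["weight"] = max(old, w)
    else:
        g.add_edge(u, v, weight=w)


def _normalize(raw: nx.Graph, source: str) -> nx.Graph:
    if raw.is_directed():
        warnings.warn(f"directed input symmetrized by summing reciprocal weights ({source})")
        und = nx.Graph()
        und.add_nodes_from(raw.nodes)
        for u, v, data in raw.edges(data=True):
            if "weight" not in data:
                raise GraphFormatError(f"weights required: edge {u!r}-{v!r} in {source}")
            w = _check_weight(data["weight"], f"edge {u!r}-{v!r} in {source}")
            if u == v:
                warnings.warn(f"self-loop on {u!r} dropped ({source})")
                continue
            if und.has_edge(u, v):
                und[u][v]["weight"] += w
            else:
                und.add_edge(u, v, weight=w)
        return und

    g = nx.Graph()
    g.add_nodes_from(raw.nodes)
    if raw.is_multigraph():
        edge_iter = ((u, v, d) for u, v, _, d in raw.edges(keys=True, data=True))
    else:
        edge_iter = raw.edges(data=True)
    for u, v, data in edge_iter:
        if "weight" not in data:
            raise GraphFormatError(f"weights required: edge {u!r}-{v!r} in {source}")
        w = _check_weight(data["weight"], f"edge {u!r}-{v!r} in {source}")
        _add_edge(g, u, v, w, source)
    return g


def read_graph(path, format: Optional[str] = None) -> nx.Graph:
    """Read a weighted undirected graph from ``path``.

    Supported formats: whitespace-separated weighted edge list (``u v w``,
    ``#`` comments), GML and GraphML with a ``weight`` edge attribute.
    Duplicate undirected edges collapse to the maximum weight, self-loops are
    dropped, and directed input is symmetrized — each with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "edgelist":
        return _read_edgelist(path)
    try:
        if fmt == "gml":
            raw = nx.read_gml(path)
        else:
            raw = nx.read_graphml(path)
    except Exception as exc:  # parse failure from networkx
        raise GraphFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    return _normalize(raw, str(path))


def write_graph(g: nx.Graph, path, format: Optional[str] = None) -> None:
    """Write ``g`` to ``path`` in the requested (or suffix-inferred) format."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            for u, v, data in sorted(
                g.edges(data=True), key=lambda e: (node_sort_key(e[0]), node_sort_key(e[1]))
            ):
                fh.write(f"{u} {v} {data['weight']}\n")
    elif fmt == "gml":
        nx.write_gml(g, path)
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def validate_graph(g: nx.Graph) -> nx.Graph:
    """Check the weighted-graph invariants, returning ``g`` unchanged."""
    if g.number_of_nodes() < 1:
        raise ValueError("graph must have at least one node")
    for u, v, data in g.edges(data=True):
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        if "weight" not in data:
            raise GraphFormatError(f"weights required: edge {u!r}-{v!r}")
        _check_weight(data["weight"], f"edge {u!r}-{v!r}")
    return g


def weighted_degree(g: nx.Graph, v: Hashable) -> float:
    """Strength of ``v``: sum of the weights of its incident edges."""
    if v not in g:
        raise KeyError(f"unknown node {v!r}")
    return float(g.degree(v, weight="weight"))


def rank_nodes(g: nx.Graph, nodes: Optional[Iterable[Hashable]] = None) -> list[RankedNode]:
    """Rank ``nodes`` (default: all) by descending weighted degree.

    Ties are broken lexicographically on the string form of the node
    identifier, so the output is stable across runs and input orderings.
    """
    if nodes is None:
        nodes = g.nodes
    pool = set(nodes)
    missing = pool - set(g.nodes)
    if missing:
        raise KeyError(f"unknown nodes {sorted(map(str, missing))}")
    ranked = sorted(
        (RankedNode(v, weighted_degree(g, v)) for v in pool),
        key=lambda e: (-e.weighted_degree, node_sort_key(e.node)),
    )
    return ranked


def ranked_node_ids(ranked: Sequence[RankedNode]) -> list[Hashable]:
    """Node identifiers of a ranked list, in rank order."""
    return [e.node for e in ranked]
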