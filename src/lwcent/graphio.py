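"""Graph input/output and basic network summaries.

Every function in this package operates on a plain :class:`networkx.Graph`
that is *simple* (no self-loops, no parallel edges) and undirected.  The
readers below enforce that contract regardless of what the source file
declares: directed edges are symmetrized, duplicate and reversed-duplicate
edges are collapsed, and self-loops are dropped (with a logged count).
Node labels are preserved verbatim from the file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "read_graph",
    "write_graph",
    "largest_component",
    "summary_stats",
]


@dataclass(frozen=True)
class SummaryStats:
    """Global statistics of a network.

    Attributes
    ----------
    n_nodes, n_edges : int
        |V| and |E| of the simple undirected graph.
    avg_degree : float
        Mean degree ``2|E|/|V|``.
    max_degree : int
        Largest node degree.
    avg_clustering : float
        Mean of the per-node clustering coefficients (nodes with degree
        <= 1 contribute 0).
    """

    n_nodes: int
    n_edges: int
    avg_degree: float
    max_degree: int
    avg_clustering: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        """Aligned one-row table (|V|, |E|, <k>, k_max, clc_ave)."""
        header = f"{'|V|':>8} {'|E|':>8} {'<k>':>8} {'k_max':>6} {'clc_ave':>8}"
        row = (
            f"{self.n_nodes:>8d} {self.n_edges:>8d} {self.avg_degree:>8.3f} "
            f"{self.max_degree:>6d} {self.avg_clustering:>8.3f}"
        )
        return header + "\n" + row


def _as_simple_undirected(g: nx.Graph | nx.DiGraph | nx.MultiGraph) -> nx.Graph:
    """Collapse any networkx graph to a simple undirected one."""
    simple = nx.Graph()
    simple.add_nodes_from(g.nodes())
    n_loops = 0
    for u, v in g.edges():
        if u == v:
            n_loops += 1
            continue
        simple.add_edge(u, v)
    if n_loops:
        logger.info("dropped %d self-loop(s)", n_loops)
    return simple


def _read_gml(path: Path) -> nx.Graph:
    # Read on raw integer ids; promote to the human-readable "label"
    # attribute when the file provides one for every node and they are
    # unique (the Newman-archive files do).
    g = nx.read_gml(path, label="id")
    labels = nx.get_node_attributes(g, "label")
    if len(labels) == g.number_of_nodes() and len(set(labels.values())) == len(labels):
        g = nx.relabel_nodes(g, labels, copy=True)
    return _as_simple_undirected(g)


def _token(tok: str):
    try:
        return int(tok)
    except ValueError:
        return tok


def _read_edgelist(path: Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "%")):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: malformed edge record {line!r} "
                    "(expected at least two tokens)"
                )
            u, v = _token(parts[0]), _token(parts[1])
            if u == v:
                logger.info("dropped self-loop at %s:%d", path, lineno)
                g.add_node(u)
                continue
            g.add_edge(u, v)
    return g


def read_graph(path: str | Path, format: str = "auto") -> nx.Graph:
    """Read a simple undirected graph from a GML file or an edge list.

    Parameters
    ----------
    path : str or Path
        File to read.
    format : {"auto", "gml", "edgelist"}
        ``"auto"`` dispatches on the ``.gml`` extension (anything else is
        treated as an edge list with ``#``/``%`` comment lines and
        whitespace or comma separators).

    Returns
    -------
    networkx.Graph
        Simple undirected graph; direction and edge weights in the source
        are discarded, duplicate edges collapsed, self-loops dropped.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    if format == "auto":
        format = "gml" if path.suffix.lower() == ".gml" else "edgelist"
    if format == "gml":
        try:
            return _read_gml(path)
        except nx.NetworkXError as exc:
            raise ValueError(f"failed to parse GML file {path}: {exc}") from exc
    if format == "edgelist":
        return _read_edgelist(path)
    raise ValueError(f"unknown graph format {format!r}")


def write_graph(net: nx.Graph, path: str | Path, format: str = "auto") -> None:
    """Write a graph as GML or as a whitespace edge list (isolates kept)."""
    path = Path(path)
    if format == "auto":
        format = "gml" if path.suffix.lower() == ".gml" else "edgelist"
    if format == "gml":
        nx.write_gml(net, path)
        return
    if format == "edgelist":
        with open(path, "w") as fh:
            fh.write("# edge list (u v per line); isolated nodes listed alone\n")
            for u, v in net.edges():
                fh.write(f"{u} {v}\n")
            for u in net.nodes():
                if net.degree(u) == 0:
                    fh.write(f"{u} {u}\n")  # readers drop the loop, keep the node
        return
    raise ValueError(f"unknown graph format {format!r}")


def largest_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties on component size are broken by the smallest contained node label.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("largest_component: empty graph")
    comps = list(nx.connected_components(net))
    biggest = max(len(c) for c in comps)
    candidates = [c for c in comps if len(c) == biggest]
    best = min(candidates, key=lambda c: _sort_key(min(c, key=_sort_key)))
    return net.subgraph(best).copy()


def _sort_key(label):
    """Deterministic ordering for possibly mixed-type node labels."""
    return (str(type(label).__name__), label) if not isinstance(label, str) else ("str", label)


def summary_stats(net: nx.Graph) -> SummaryStats:
    """|V|, |E|, average degree, max degree and mean clustering coefficient."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("summary_stats: empty graph")
    m = net.number_of_edges()
    degrees = [d for _, d in net.degree()]
    clc = nx.clustering(net)
    return SummaryStats(
        n_nodes=n,
        n_edges=m,
        avg_degree=2.0 * m / n,
        max_degree=max(degrees),
        avg_clustering=sum(clc.values()) / n,
    )


def node_order(net: nx.Graph) -> list:
    """Canonical node order used throughout the package (sorted labels)."""
    return sorted(net.nodes(), key=_sort_key)
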