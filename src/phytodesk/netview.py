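"""Two-step interaction networks: extraction, metrics, 3D layout, export.

A query protein's local interaction neighborhood is modelled as the "two-step"
network: every node within graph distance 2 of the query, with all edges of
the parent interactome induced on that node set.  Per-node annotations —
Watts–Strogatz clustering coefficient ``C = 2e / (k(k-1))``, Pearson
expression correlation against the query, and a sub-cellular localization
label — drive node size and color in the rendered view.

Node coordinates come from a seeded 3D Fruchterman–Reingold force-directed
layout (networkx implementation, 200 iterations, uniform initial placement),
exported in the plain-text XYZ chemical format so any molecular viewer can
render the network: the query is written as element ``N``, first-shell
neighbors as ``C``, second-shell as ``O``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYOUT_ITERATIONS = 200
LAYOUT_METHOD = "fruchterman-reingold-3d"

SHELL_SYMBOLS = {0: "N", 1: "C", 2: "O"}
DEFAULT_SYMBOL = "C"

# fixed categorical palette for localization labels (assigned to sorted labels)
LOCALIZATION_PALETTE = [
    "blue",
    "green",
    "orange",
    "purple",
    "red",
    "cyan",
    "magenta",
    "olive",
]
DEFAULT_COLOR = "grey"


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected interaction; endpoints stored in canonical order."""

    node_a: str
    node_b: str
    confidence: float
    provenance: str  # documented | predicted

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError(f"self-loop on {self.node_a!r}")
        if self.provenance not in ("documented", "predicted"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        a, b = sorted((self.node_a, self.node_b))
        object.__setattr__(self, "node_a", a)
        object.__setattr__(self, "node_b", b)


@dataclass
class Layout3D:
    """Seeded 3D coordinates for every node of a network."""

    coordinates: dict[Hashable, tuple[float, float, float]]
    seed: int
    method: str = LAYOUT_METHOD

    def validate(self) -> None:
        pts = np.array(list(self.coordinates.values()), dtype=float)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("non-finite layout coordinates")
        nodes = list(self.coordinates)
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                d = np.linalg.norm(pts[i] - pts[j])
                if d < 1e-6:
                    raise ValueError(
                        f"nodes {nodes[i]!r} and {nodes[j]!r} coincide"
                    )


def load_edges(path_or_buffer) -> nx.Graph:
    """Read an interaction edge TSV into an undirected graph.

    Columns: node_a, node_b, confidence, provenance.  Duplicate undirected
    pairs are merged keeping the maximum confidence (with a warning);
    self-loops are dropped with a warning.
    """
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str)
    missing = {"node_a", "node_b", "confidence", "provenance"} - set(df.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        a, b = str(row.node_a), str(row.node_b)
        conf = float(row.confidence)
        if a == b:
            logger.warning("dropping self-loop on %r", a)
            continue
        if g.has_edge(a, b):
            old = g.edges[a, b]["confidence"]
            if old != conf:
                logger.warning(
                    "duplicate edge %r-%r: keeping max confidence %g",
                    a, b, max(old, conf),
                )
            g.edges[a, b]["confidence"] = max(old, conf)
        else:
            g.add_edge(a, b, confidence=conf, provenance=row.provenance)
    return g


def write_edges(graph: nx.Graph, path_or_buffer) -> None:
    rows = [
        {
            "node_a": min(a, b),
            "node_b": max(a, b),
            "confidence": data.get("confidence", 1.0),
            "provenance": data.get("provenance", "predicted"),
        }
        for a, b, data in graph.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["node_a", "node_b", "confidence", "provenance"]
    ).to_csv(path_or_buffer, sep="\t", index=False)


def two_step_subnetwork(
    graph: nx.Graph, query: str, depth: int = 2
) -> nx.Graph:
    """Induced subgraph on all nodes within graph distance ``depth`` of query.

    A query absent from the parent network yields a single-node network (the
    query with no edges), so downstream layout/export still work.
    """
    if query not in graph:
        g = nx.Graph()
        g.add_node(query)
        return g
    return nx.ego_graph(graph, query, radius=depth)


def clustering_coefficient(graph: nx.Graph, node: str) -> float:
    """Watts–Strogatz local clustering: ``2e / (k(k-1))``, 0 when degree < 2."""
    if node not in graph:
        raise KeyError(f"node {node!r} not in network")
    neighbors = list(graph.neighbors(node))
    k = len(neighbors)
    if k < 2:
        return 0.0
    e = 0
    for i in range(k):
        for j in range(i + 1, k):
            if graph.has_edge(neighbors[i], neighbors[j]):
                e += 1
    return 2.0 * e / (k * (k - 1))


def expression_correlation(
    profile_a: Sequence[float], profile_b: Sequence[float]
) -> float | None:
    """Pearson correlation of two expression profiles; None if degenerate."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles differ in length")
    if a.size < 3:
        raise ValueError("profiles need at least 3 conditions")
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def annotate_network(
    graph: nx.Graph,
    query: str,
    expression: pd.DataFrame | None = None,
    localization: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Attach per-node clustering, expression-correlation and localization attributes."""
    for node in graph.nodes:
        graph.nodes[node]["clustering"] = clustering_coefficient(graph, node)
        if localization and node in localization:
            graph.nodes[node]["localization"] = localization[node]
    if expression is not None and query in expression.index:
        qprof = expression.loc[query].to_numpy(dtype=float)
        for node in graph.nodes:
            if node in expression.index:
                r = expression_correlation(
                    qprof, expression.loc[node].to_numpy(dtype=float)
                )
                if r is not None:
                    graph.nodes[node]["correlation"] = r
    return graph


def read_expression_tsv(path_or_buffer) -> pd.DataFrame:
    """Gene x condition numeric table with gene identifiers as the index."""
    return pd.read_csv(path_or_buffer, sep="\t", index_col=0)


def layout_3d(graph: nx.Graph, seed: int) -> Layout3D:
    """Seeded deterministic 3D force-directed embedding.

    Fruchterman–Reingold with 200 iterations and seeded uniform initial
    placement; a single-node network sits at the origin.  Identical
    (graph, seed) inputs give identical coordinates.
    """
    if graph.number_of_nodes() == 0:
        return Layout3D({}, seed)
    pos = nx.spring_layout(
        graph, dim=3, seed=seed, iterations=LAYOUT_ITERATIONS
    )
    coords = {
        node: (float(p[0]), float(p[1]), float(p[2]))
        for node, p in pos.items()
    }
    layout = Layout3D(coords, seed)
    layout.validate()
    return layout


def shell_symbols(graph: nx.Graph, query: str) -> dict[str, str]:
    """XYZ element symbol per node by BFS shell: query N, shell-1 C, shell-2 O."""
    if query not in graph:
        return {}
    dist = nx.single_source_shortest_path_length(graph, query)
    return {
        node: SHELL_SYMBOLS.get(d, DEFAULT_SYMBOL) for node, d in dist.items()
    }


def export_xyz(
    layout: Layout3D,
    labels: Mapping[str, str] | None = None,
    comment: str = "",
) -> str:
    """Serialize a layout in XYZ chemical format.

    Line 1: node count; line 2: comment (by convention the query id, seed and
    symbol legend); then one ``SYMBOL x y z`` line per node with 3-decimal
    coordinates.  Nodes are written in sorted-identifier order so output is
    byte-stable.
    """
    labels = labels or {}
    if not comment:
        comment = (
            f"seed={layout.seed} method={layout.method} "
            "symbols: N=query C=shell1 O=shell2"
        )
    lines = [str(len(layout.coordinates)), comment]
    for node in sorted(layout.coordinates, key=str):
        x, y, z = layout.coordinates[node]
        sym = labels.get(node, DEFAULT_SYMBOL)
        lines.append(f"{sym} {x:.3f} {y:.3f} {z:.3f}")
    return "\n".join(lines) + "\n"


def parse_xyz(text: str) -> list[tuple[str, float, float, float]]:
    """Inverse of :func:`export_xyz` (symbols and 3-decimal coordinates)."""
    lines = text.splitlines()
    count = int(lines[0])
    out = []
    for line in lines[2 : 2 + count]:
        sym, x, y, z = line.split()
        out.append((sym, float(x), float(y), float(z)))
    if len(out) != count:
        raise ValueError("XYZ body shorter than the declared count")
    return out


def render_spec(
    graph: nx.Graph,
    query: str,
    size_metric: str = "clustering",
    r_min: float = 0.5,
    r_max: float = 2.0,
) -> pd.DataFrame:
    """Per-node (size, color, shell) render table.

    Node size is an affine map of the chosen metric (``clustering``,
    ``correlation`` or ``confidence`` — the latter the max confidence of the
    node's incident edges) into ``[r_min, r_max]``; when every value is equal
    (or missing) nodes sit at the midpoint.  Color is a fixed categorical
    palette keyed by the sorted distinct localization labels; nodes without a
    label are grey.
    """
    if r_min > r_max:
        raise ValueError("r_min must not exceed r_max")
    nodes = sorted(graph.nodes, key=str)

    values: dict[str, float | None] = {}
    for node in nodes:
        if size_metric == "confidence":
            confs = [
                graph.edges[node, other].get("confidence")
                for other in graph.neighbors(node)
            ]
            confs = [c for c in confs if c is not None]
            values[node] = max(confs) if confs else None
        else:
            values[node] = graph.nodes[node].get(size_metric)
    present = [v for v in values.values() if v is not None]
    if any(v is None for v in values.values()):
        logger.warning(
            "metric %r missing for %d node(s); using default size",
            size_metric,
            sum(1 for v in values.values() if v is None),
        )
    mid = (r_min + r_max) / 2.0

    def size_of(v: float | None) -> float:
        if v is None or not present:
            return mid
        lo, hi = min(present), max(present)
        if hi == lo:
            return mid
        return r_min + (v - lo) / (hi - lo) * (r_max - r_min)

    labels = sorted(
        {
            graph.nodes[n]["localization"]
            for n in nodes
            if "localization" in graph.nodes[n]
        }
    )
    palette = {
        lab: LOCALIZATION_PALETTE[i % len(LOCALIZATION_PALETTE)]
        for i, lab in enumerate(labels)
    }
    dist = (
        nx.single_source_shortest_path_length(graph, query)
        if query in graph
        else {}
    )
    rows = [
        {
            "node": node,
            "size": round(size_of(values[node]), 6),
            "color": palette.get(
                graph.nodes[node].get("localization"), DEFAULT_COLOR
            ),
            "shell": dist.get(node, -1),
        }
        for node in nodes
    ]
    return pd.DataFrame(rows, columns=["node", "size", "color", "shell"])
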