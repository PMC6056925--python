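"""Interaction-network data model, readers/writers and topology statistics.

The network container wraps a simple undirected :class:`networkx.Graph` over
uppercased gene symbols: no self-loops, no parallel edges, edge {A,B} == {B,A}.
Readers accept two-column TSV edge lists, SIF, GraphML and the HPRD flat
binary-interaction export; writers round-trip all of them.

Topology statistics cover what a network-analyzer style report needs:
density, mean degree, mean local clustering (degree<2 nodes count as 0),
a log-log OLS fit to the degree histogram as a descriptive scale-free check,
and category-stratified mean degree / hub ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .gene_catalog import NodeCategory, normalize_symbol

logger = logging.getLogger("mgnet.interaction_graph")

__all__ = [
    "InteractionNetwork",
    "TopologySummary",
    "DegreeDistribution",
    "CategoryDegreeReport",
    "load_network",
    "topology_summary",
    "degree_distribution",
    "hub_analysis",
    "write_network",
]


class InteractionNetwork:
    """Simple undirected graph over gene symbols.

    Construction canonicalises: symbols are uppercased, self-loops dropped,
    duplicate and reversed-duplicate edges collapsed.
    """

    def __init__(self, graph: nx.Graph | None = None, name: str = "network"):
        self.graph = graph if graph is not None else nx.Graph()
        self.name = name
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)
            logger.info("%s: removed %d self-loops", name, len(loops))

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], name: str = "network",
                   nodes: Iterable[str] = ()) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(normalize_symbol(n) for n in nodes)
        dropped_loops = 0
        for a, b in edges:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                dropped_loops += 1
                continue
            g.add_edge(a, b)
        if dropped_loops:
            logger.info("%s: dropped %d self-loop records", name, dropped_loops)
        return cls(g, name=name)

    # -- set views ---------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def subgraph(self, nodes: Iterable[str], name: str | None = None) -> "InteractionNetwork":
        """Induced subgraph (copy) on the given nodes."""
        sub = self.graph.subgraph(nodes).copy()
        return InteractionNetwork(sub, name=name or f"{self.name}-sub")

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return (f"InteractionNetwork({self.name!r}, nodes={self.node_count}, "
                f"edges={self.edge_count})")


@dataclass(frozen=True)
class TopologySummary:
    node_count: int
    edge_count: int
    density: float
    mean_degree: float
    mean_clustering: float
    per_node: pd.DataFrame = field(compare=False, repr=False)

    def as_dict(self) -> dict:
        return {
            "node_count": self.node_count,
            "edge_count": self.edge_count,
            "density": self.density,
            "mean_degree": self.mean_degree,
            "mean_clustering": self.mean_clustering,
        }


@dataclass(frozen=True)
class DegreeDistribution:
    histogram: dict[int, int]
    loglog_slope: float  # NaN when fewer than 2 occupied positive-degree bins
    loglog_r2: float

    def as_dict(self) -> dict:
        return {
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
            "loglog_slope": None if math.isnan(self.loglog_slope) else self.loglog_slope,
            "loglog_r2": None if math.isnan(self.loglog_r2) else self.loglog_r2,
        }


@dataclass(frozen=True)
class CategoryDegreeReport:
    mean_degree: dict[NodeCategory, float]
    top_hubs: list[tuple[str, int, NodeCategory]]

    def as_dict(self) -> dict:
        return {
            "mean_degree": {cat.value: v for cat, v in self.mean_degree.items()},
            "top_hubs": [
                {"symbol": s, "degree": d, "category": c.value}
                for s, d, c in self.top_hubs
            ],
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_HPRD_DEFAULT_COLUMNS = (0, 3)  # gene symbols in cols 1 and 4 of the flat export


def load_network(path: str | Path, dialect: str = "tsv-edge-list",
                 name: str | None = None,
                 hprd_columns: tuple[int, int] = _HPRD_DEFAULT_COLUMNS,
                 ) -> InteractionNetwork:
    """Read an undirected PPI network.

    Dialects: ``tsv-edge-list`` (two tab-separated symbols per line, ``#``
    comments), ``sif`` (``node relation node+``; whitespace separated),
    ``hprd-binary-flat`` (tab-separated, symbols at `hprd_columns`), and
    ``graphml``.

    Self-loops are dropped and duplicate / reversed edges collapsed; the
    number of dropped records is logged. Raises ``ValueError`` on malformed
    lines (with line number) and when the parsed edge set is empty.
    """
    path = Path(path)
    name = name or path.stem
    if dialect == "graphml":
        g = nx.read_graphml(path)
        net = InteractionNetwork.from_edges(((a, b) for a, b in g.edges), name=name,
                                            nodes=g.nodes)
        if net.edge_count == 0:
            raise ValueError(f"{path}: network has no edges")
        return net

    edges: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if dialect == "tsv-edge-list":
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected ≥2 tab-separated fields")
            edges.append((fields[0], fields[1]))
        elif dialect == "sif":
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(fields) == 1:
                continue  # isolated node line
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: SIF line needs source, relation, target(s)")
            src = fields[0]
            for tgt in fields[2:]:
                edges.append((src, tgt))
        elif dialect == "hprd-binary-flat":
            fields = line.rstrip("\n").split("\t")
            i, j = hprd_columns
            if len(fields) <= max(i, j):
                raise ValueError(f"{path}:{lineno}: expected ≥{max(i, j) + 1} columns")
            edges.append((fields[i], fields[j]))
        else:
            raise ValueError(f"unknown network dialect: {dialect!r}")
    net = InteractionNetwork.from_edges(edges, name=name)
    dup = len(edges) - net.edge_count
    if dup:
        logger.info("%s: collapsed %d duplicate/self-loop records", name, dup)
    if net.edge_count == 0:
        raise ValueError(f"{path}: network has no edges")
    return net


def write_network(net: InteractionNetwork, path: str | Path, format: str = "tsv-edge-list",
                  attributes: Mapping[str, NodeCategory] | None = None) -> None:
    """Write a network; ``load_network`` on the output reproduces (nodes, edges).

    GraphML carries the category map (when given) as a string node attribute
    ``category``; TSV/SIF list isolated nodes as single-field lines (SIF) or
    are limited to edges (TSV).
    """
    path = Path(path)
    if format == "graphml":
        g = net.graph.copy()
        if attributes:
            nx.set_node_attributes(
                g, {n: attributes[n].value for n in g.nodes if n in attributes},
                "category")
        nx.write_graphml(g, path)
        return
    edges = sorted(tuple(sorted(e)) for e in net.edges)
    with path.open("w") as fh:
        if format == "tsv-edge-list":
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")
        elif format == "sif":
            for a, b in edges:
                fh.write(f"{a}\tpp\t{b}\n")
            for node in sorted(net.nodes - {n for e in edges for n in e}):
                fh.write(f"{node}\n")
        else:
            raise ValueError(f"unknown network format: {format!r}")


# ---------------------------------------------------------------------------
# topology statistics
# ---------------------------------------------------------------------------

def topology_summary(net: InteractionNetwork) -> TopologySummary:
    """Node/edge counts, density, mean degree and mean local clustering.

    density = 2E / (N(N-1)); local clustering of a node with degree < 2 is 0
    and is included in the mean. A single-node (or empty) network reports
    density 0 with a warning.
    """
    n, e = net.node_count, net.edge_count
    if n < 2:
        logger.warning("%s: density undefined for %d node(s); reporting 0", net.name, n)
        density = 0.0
    else:
        density = 2.0 * e / (n * (n - 1))
    degrees = dict(net.graph.degree)
    clustering = nx.clustering(net.graph)  # degree<2 -> 0.0, matching our convention
    per_node = pd.DataFrame(
        {"degree": pd.Series(degrees, dtype=int),
         "clustering": pd.Series(clustering, dtype=float)}
    ).sort_index()
    mean_degree = 2.0 * e / n if n else 0.0
    mean_clustering = float(per_node["clustering"].mean()) if n else 0.0
    return TopologySummary(node_count=n, edge_count=e, density=density,
                           mean_degree=mean_degree, mean_clustering=mean_clustering,
                           per_node=per_node)


def degree_distribution(net: InteractionNetwork) -> DegreeDistribution:
    """Degree histogram plus a descriptive log10-log10 OLS power-law fit.

    The fit regresses log10 N(k) on log10 k over occupied bins with k >= 1.
    Fewer than two such bins -> slope and r² are NaN.
    """
    degrees = [d for _, d in net.graph.degree]
    histogram: dict[int, int] = {}
    for d in degrees:
        histogram[d] = histogram.get(d, 0) + 1
    ks = np.array(sorted(k for k in histogram if k >= 1), dtype=float)
    if len(ks) < 2:
        return DegreeDistribution(histogram, float("nan"), float("nan"))
    ys = np.log10([histogram[int(k)] for k in ks])
    xs = np.log10(ks)
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * xs + intercept
    ss_res = float(np.sum((ys - fitted) ** 2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return DegreeDistribution(histogram, float(slope), float(r2))


def hub_analysis(net: InteractionNetwork, cmap: Mapping[str, NodeCategory],
                 k: int = 5) -> CategoryDegreeReport:
    """Per-category mean degree and the top-k hubs.

    Hubs are ranked by degree descending with ties broken by lexicographic
    symbol order, so the report is deterministic. Requires `cmap` to cover
    every node; `k` must be positive.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    missing = net.nodes - set(cmap)
    if missing:
        raise ValueError(f"category map misses {len(missing)} nodes, e.g. "
                         f"{sorted(missing)[:3]}")
    by_cat: dict[NodeCategory, list[int]] = {}
    for node in net.nodes:
        by_cat.setdefault(cmap[node], []).append(net.degree(node))
    mean_degree = {cat: float(np.mean(degs)) for cat, degs in sorted(
        by_cat.items(), key=lambda kv: kv[0].value)}
    ranked = sorted(net.nodes, key=lambda v: (-net.degree(v), v))[:k]
    top_hubs = [(v, net.degree(v), cmap[v]) for v in ranked]
    return CategoryDegreeReport(mean_degree=mean_degree, top_hubs=top_hubs)
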