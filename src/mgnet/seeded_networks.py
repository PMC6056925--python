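"""Seed-anchored neighbor subnetworks.

The analysis extracts two nested subnetworks from the full PPI graph:

* the immune-or-disease neighbor network — seeds are the union of the
  immune and disease gene lists; nodes are seeds present in the base
  network plus every direct interactor; edges are the induced subgraph;
* the disease-directed network — the same construction applied to the
  first subnetwork with the disease genes alone as seeds.

Keeping induced edges (including neighbor–neighbor edges) is what lets
dense modules among non-seed genes survive into the module-detection stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .gene_catalog import GeneSet, unmatched_seeds
from .interaction_graph import InteractionNetwork

logger = logging.getLogger("mgnet.seeded_networks")

__all__ = ["SeededNetwork", "RetentionReport", "build_neighbor_network", "edge_retention"]


@dataclass(frozen=True)
class SeededNetwork:
    """Induced neighbor subnetwork together with the seeds that anchored it."""

    network: InteractionNetwork
    seeds_used: GeneSet
    base_name: str


@dataclass(frozen=True)
class RetentionReport:
    """How many base-network interactions the subnetwork retains."""

    sub_edges: int
    base_edges: int

    @property
    def fraction(self) -> float:
        return self.sub_edges / self.base_edges

    @property
    def percent(self) -> float:
        """Percentage rendering rounded to 2 decimals (e.g. 22.22)."""
        return round(100.0 * self.fraction, 2)

    def as_dict(self) -> dict:
        return {"sub_edges": self.sub_edges, "base_edges": self.base_edges,
                "fraction": self.fraction, "percent": self.percent}


def build_neighbor_network(base: InteractionNetwork, seeds: GeneSet,
                           name: str) -> SeededNetwork:
    """Extract the induced subgraph on seeds plus their direct interactors.

    Node set = (seeds ∩ base nodes) ∪ all base-network neighbors of those
    seeds; edge set = every base edge with both endpoints in the node set.
    Seeds absent from the base network are logged and ignored; raises
    ``ValueError`` when no seed is present at all.
    """
    if base.node_count == 0:
        raise ValueError("base network is empty")
    present = seeds.symbols & base.nodes
    unmatched_seeds(seeds, base.nodes)
    if not present:
        raise ValueError(
            f"none of the {len(seeds)} seeds of {seeds.name!r} are in {base.name!r}")
    members = set(present)
    for seed in present:
        members |= base.neighbors(seed)
    sub = base.subgraph(members, name=name)
    logger.info("%s: %d seeds present -> %d nodes, %d edges (base %s)",
                name, len(present), sub.node_count, sub.edge_count, base.name)
    return SeededNetwork(
        network=sub,
        seeds_used=GeneSet(name=seeds.name, symbols=frozenset(present),
                           provenance=f"{seeds.provenance} ∩ {base.name}"),
        base_name=base.name,
    )


def edge_retention(sub: SeededNetwork, base: InteractionNetwork) -> RetentionReport:
    """Fraction of base-network edges retained by the subnetwork.

    Raises ``ValueError`` if the subnetwork has edges outside the base
    network (inconsistent inputs) or the base network has no edges.
    """
    stray = sub.network.edges - base.edges
    if stray:
        raise ValueError(f"subnetwork has {len(stray)} edges absent from {base.name!r}")
    if base.edge_count == 0:
        raise ValueError(f"base network {base.name!r} has no edges; fraction undefined")
    return RetentionReport(sub_edges=sub.network.edge_count, base_edges=base.edge_count)
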