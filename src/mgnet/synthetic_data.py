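"""Synthetic benchmark scenarios with full ground truth.

The generator emulates the statistical structure the analysis assumes,
at a desk-scale size:

* a scale-free interaction graph (preferential attachment) with planted
  dense modules whose members overlap the disease seed list, so the seeded
  subnetworks contain recoverable dense regions;
* a gene-by-sample expression matrix in which each planted module shares a
  latent factor — giving closed-form implied pairwise correlations on
  module edges, with both signs — and selected genes carry a standardized
  mean shift in disease samples.

Ground truth (planted modules, implied edge correlations, DE genes, seed
assignment, all generator parameters) is recorded so recovery tests and
pipeline reports can be checked against exact expectations. Everything is
a pure function of the configuration and the RNG seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .gene_catalog import GeneSet
from .interaction_graph import InteractionNetwork, write_network
from .expression_overlay import ExpressionMatrix, DISEASE, CONTROL
from .enrichment import GeneSetCollection, write_gene_set_collection

logger = logging.getLogger("mgnet.synthetic_data")

__all__ = ["ScenarioConfig", "SyntheticTruth", "simulate_network",
           "simulate_expression", "make_scenario"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator parameters; defaults define the package's benchmark scenario.

    Sample sizes default to 21 disease / 18 control. Effect sizes (planted
    edge correlation 0.7, standardized DE shift 1.5) are chosen so that at
    those sample sizes the power of the overlay statistics exceeds
    0.9 / 0.95, keeping recovery assertions stable.
    """

    n_nodes: int = 500
    m_attach: int = 2
    modules: tuple[tuple[int, float], ...] = ((12, 0.9),)  # (size, density)
    n_immune_seeds: int = 60
    n_disease_seeds: int = 25
    module_disease_fraction: float = 0.5  # module members put on the disease list
    n_disease_samples: int = 21
    n_control_samples: int = 18
    rho: float = 0.7                 # target planted edge correlation
    negative_fraction: float = 0.3   # loadings with negative sign
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    de_effect: float = 1.5           # standardized mean shift d
    module_de_fraction: float = 0.75
    n_background_de: int = 20

    def __post_init__(self) -> None:
        if self.n_disease_samples < 4 or self.n_control_samples < 4:
            raise ValueError("need >= 4 samples per group")
        for size, dens in self.modules:
            if size > self.n_nodes:
                raise ValueError(f"module size {size} exceeds n_nodes {self.n_nodes}")
            if not 0 < dens <= 1:
                raise ValueError(f"module density must be in (0,1], got {dens}")
        if not -1 < self.rho < 1:
            raise ValueError("rho must be in (-1, 1)")
        if self.de_effect < 0:
            raise ValueError("de_effect must be >= 0")


@dataclass
class SyntheticTruth:
    """Everything planted by the generator, for recovery checks."""

    config: ScenarioConfig
    seed: int
    planted_modules: list[frozenset[str]] = field(default_factory=list)
    module_densities: list[float] = field(default_factory=list)
    immune_seeds: frozenset[str] = frozenset()
    disease_seeds: frozenset[str] = frozenset()
    # (gene_a, gene_b, implied signed correlation)
    correlated_edges: list[tuple[str, str, float]] = field(default_factory=list)
    # gene -> (standardized effect d, direction "up"/"down")
    de_genes: dict[str, tuple[float, str]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["modules"] = [list(m) for m in self.config.modules]
        return {
            "config": cfg,
            "seed": self.seed,
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "module_densities": self.module_densities,
            "immune_seeds": sorted(self.immune_seeds),
            "disease_seeds": sorted(self.disease_seeds),
            "correlated_edges": [[a, b, rho] for a, b, rho in self.correlated_edges],
            "de_genes": {g: [d, direction]
                         for g, (d, direction) in sorted(self.de_genes.items())},
        }


def _gene_name(i: int, width: int) -> str:
    return f"G{i + 1:0{width}d}"


def simulate_network(cfg: ScenarioConfig, seed: int,
                     ) -> tuple[InteractionNetwork, SyntheticTruth]:
    """Preferential-attachment background with planted dense modules.

    Each planted module is realized by adding random edges among its
    members until the internal density reaches the target. Disease seeds
    cover `module_disease_fraction` of each module (so seeded extraction
    keeps the modules); remaining disease and all immune seeds are drawn
    uniformly. Deterministic given (cfg, seed).
    """
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(cfg.n_nodes, cfg.m_attach,
                                 seed=int(rng.integers(2 ** 31)))
    width = max(4, len(str(cfg.n_nodes)))
    mapping = {i: _gene_name(i, width) for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    all_genes = sorted(g.nodes)

    truth = SyntheticTruth(config=cfg, seed=seed)
    available = list(all_genes)
    for size, density in cfg.modules:
        members = sorted(rng.choice(available, size=size, replace=False))
        available = [v for v in available if v not in set(members)]
        target_edges = math.ceil(density * size * (size - 1) / 2)
        missing = [(a, b) for i, a in enumerate(members) for b in members[i + 1:]
                   if not g.has_edge(a, b)]
        have = size * (size - 1) // 2 - len(missing)
        if have < target_edges:
            picks = rng.choice(len(missing), size=target_edges - have, replace=False)
            for idx in sorted(picks):
                g.add_edge(*missing[idx])
        truth.planted_modules.append(frozenset(members))
        realized = g.subgraph(members)
        truth.module_densities.append(
            2 * realized.number_of_edges() / (size * (size - 1)))

    disease: set[str] = set()
    for members in truth.planted_modules:
        take = round(cfg.module_disease_fraction * len(members))
        disease |= set(rng.choice(sorted(members), size=take, replace=False))
    in_modules = set().union(*truth.planted_modules) if truth.planted_modules \
        else set()
    outside = [v for v in all_genes if v not in disease and v not in in_modules]
    extra = max(0, cfg.n_disease_seeds - len(disease))
    if extra:
        disease |= set(rng.choice(outside, size=extra, replace=False))
    immune = set(rng.choice(all_genes, size=cfg.n_immune_seeds, replace=False))
    truth.disease_seeds = frozenset(disease)
    truth.immune_seeds = frozenset(immune)

    net = InteractionNetwork(g, name="synthetic-ppi")
    logger.info("simulated network: %d nodes, %d edges, %d planted modules",
                net.node_count, net.edge_count, len(truth.planted_modules))
    return net, truth


def implied_correlation(beta_a: float, beta_b: float, noise_sd: float) -> float:
    """Pairwise correlation implied by shared-factor loadings and noise."""
    denom = math.sqrt((beta_a ** 2 + noise_sd ** 2) * (beta_b ** 2 + noise_sd ** 2))
    return beta_a * beta_b / denom


def simulate_expression(net: InteractionNetwork, truth: SyntheticTruth,
                        cfg: ScenarioConfig, seed: int,
                        ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Latent-factor expression with planted co-expression and DE.

    Module member g gets ``mu_g + beta_g * f_module + eps``; the loading
    magnitude ``|beta| = noise_sd * sqrt(rho / (1 - rho))`` makes the
    implied correlation of two same-sign members equal ``rho``. A fraction
    of module members plus background genes receive a mean shift of
    ``de_effect`` total standard deviations in disease samples. The
    returned truth records implied correlations on the network edges inside
    each module and the planted DE table.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(net.nodes)
    samples = ([f"D{i + 1:02d}" for i in range(cfg.n_disease_samples)]
               + [f"C{i + 1:02d}" for i in range(cfg.n_control_samples)])
    group = {s: (DISEASE if s.startswith("D") else CONTROL) for s in samples}
    n_s = len(samples)

    mu = cfg.baseline_mean + cfg.baseline_sd * rng.standard_normal(len(genes))
    values = mu[:, None] + cfg.noise_sd * rng.standard_normal((len(genes), n_s))
    frame = pd.DataFrame(values, index=genes, columns=samples)

    beta_mag = cfg.noise_sd * math.sqrt(cfg.rho / (1.0 - cfg.rho))
    beta: dict[str, float] = {}
    truth.correlated_edges = []
    for members in truth.planted_modules:
        factor = rng.standard_normal(n_s)
        for gname in sorted(members):
            sign = -1.0 if rng.random() < cfg.negative_fraction else 1.0
            beta[gname] = sign * beta_mag
            frame.loc[gname] += beta[gname] * factor
        for a, b in sorted(tuple(sorted(e)) for e in net.edges
                           if e <= members):
            truth.correlated_edges.append(
                (a, b, implied_correlation(beta[a], beta[b], cfg.noise_sd)))

    truth.de_genes = {}
    de_pool: list[str] = []
    for members in truth.planted_modules:
        take = round(cfg.module_de_fraction * len(members))
        de_pool.extend(rng.choice(sorted(members), size=take, replace=False))
    background = [gname for gname in genes
                  if all(gname not in m for m in truth.planted_modules)]
    if cfg.n_background_de:
        de_pool.extend(rng.choice(background, size=cfg.n_background_de,
                                  replace=False))
    disease_cols = [s for s in samples if group[s] == DISEASE]
    for gname in de_pool:
        total_sd = math.sqrt(beta.get(gname, 0.0) ** 2 + cfg.noise_sd ** 2)
        direction = "up" if rng.random() < 0.5 else "down"
        shift = cfg.de_effect * total_sd * (1.0 if direction == "up" else -1.0)
        frame.loc[gname, disease_cols] += shift
        truth.de_genes[gname] = (cfg.de_effect, direction)

    mat = ExpressionMatrix(values=frame, group=group)
    logger.info("simulated expression: %d genes × %d samples, %d DE genes, "
                "%d planted correlated edges", len(genes), n_s,
                len(truth.de_genes), len(truth.correlated_edges))
    return mat, truth


def make_scenario(cfg: ScenarioConfig, seed: int, out_dir: str | Path) -> dict:
    """Generate a full fixture bundle on disk, in the pipeline's own formats.

    Writes the PPI edge list, immune/disease seed lists, expression TSV +
    sample labels, a GMT collection (planted modules as terms plus a
    planted drug-target set), and the truth JSON. Returns a dict of paths
    plus the in-memory objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, truth = simulate_network(cfg, seed)
    mat, truth = simulate_expression(net, truth, cfg, seed + 1)

    paths = {
        "ppi": out / "ppi_edges.tsv",
        "immune": out / "immune_genes.txt",
        "disease": out / "disease_genes.txt",
        "expression": out / "expression.tsv",
        "labels": out / "sample_labels.tsv",
        "gmt": out / "collections.gmt",
        "truth": out / "truth.json",
    }
    write_network(net, paths["ppi"], format="tsv-edge-list")
    paths["immune"].write_text(
        "".join(f"{s}\n" for s in sorted(truth.immune_seeds)))
    paths["disease"].write_text(
        "".join(f"{s}\n" for s in sorted(truth.disease_seeds)))
    mat.values.to_csv(paths["expression"], sep="\t", index_label="gene",
                      float_format="%.6f")
    with paths["labels"].open("w") as fh:
        fh.write("sample\tgroup\n")
        for s in mat.samples:
            fh.write(f"{s}\t{mat.group[s]}\n")
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for i, members in enumerate(truth.planted_modules, 1):
        sets[f"MODULE_{i:02d}"] = frozenset(members)
        descriptions[f"MODULE_{i:02d}"] = "planted dense module"
    if truth.planted_modules:
        sets["DRUG_PLANTED"] = frozenset(truth.planted_modules[0])
        descriptions["DRUG_PLANTED"] = "synthetic drug-target signature"
    write_gene_set_collection(
        GeneSetCollection(name="synthetic", sets=sets, descriptions=descriptions),
        paths["gmt"])
    paths["truth"].write_text(json.dumps(truth.as_dict(), indent=2, sort_keys=True))
    return {"paths": {k: str(v) for k, v in paths.items()},
            "network": net, "truth": truth, "expression": mat}
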