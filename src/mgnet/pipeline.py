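"""End-to-end pipeline: seeds → networks → topology → modules → expression → enrichment.

One structured configuration (YAML or JSON) drives the whole analysis:

.. code-block:: yaml

    inputs:                  # either real files ...
      ppi: ppi_edges.tsv
      ppi_dialect: tsv-edge-list
      immune: immune_genes.txt
      disease: disease_genes.txt
      expression: expression.tsv        # optional block
      expression_dialect: plain-tsv
      labels: sample_labels.tsv
      gmt: collections.gmt              # optional
    synthetic: {}            # ... or a synthetic scenario (overrides inputs)
    thresholds:
      coexpression_alpha: 0.05
      strong_threshold: 0.5
      de_alpha: 0.05
      de_variant: welch
      enrichment_alpha: 0.01
      top_modules: 5

Every threshold the analysis uses appears in the report with its value, so
runs are self-documenting. The report JSON is a pure function of (inputs,
config, seed): keys are sorted and no wall-clock values are embedded, so
identical runs produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .gene_catalog import (GeneSet, classify_nodes, load_gene_set,
                           tally_categories, write_category_map)
from .interaction_graph import (InteractionNetwork, degree_distribution,
                                hub_analysis, load_network, topology_summary,
                                write_network)
from .seeded_networks import build_neighbor_network, edge_retention
from .module_detection import McodeParams, detect_modules
from .expression_overlay import (classify_correlations, correlate_edges,
                                 correlations_to_frame, differential_expression,
                                 diffexpr_to_frame, load_expression,
                                 module_expression_report)
from .enrichment import (drug_gene_network, load_gene_set_collection,
                         overrepresent)
from .synthetic_data import ScenarioConfig, make_scenario

logger = logging.getLogger("mgnet.pipeline")

__all__ = ["DEFAULT_THRESHOLDS", "load_config", "run_pipeline"]

DEFAULT_THRESHOLDS: dict[str, Any] = {
    "coexpression_alpha": 0.05,
    "strong_threshold": 0.5,
    "de_alpha": 0.05,
    "de_variant": "welch",
    "enrichment_alpha": 0.01,
    "top_modules": 5,
    "top_hubs": 5,
}


def load_config(path: str | Path) -> dict:
    """Read a YAML/JSON pipeline configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def _config_hash(cfg: Mapping, seed: int | None) -> str:
    blob = json.dumps({"config": cfg, "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _scenario_config(block: Mapping) -> ScenarioConfig:
    kwargs = dict(block)
    if "modules" in kwargs:
        kwargs["modules"] = tuple(tuple(m) for m in kwargs["modules"])
    return ScenarioConfig(**kwargs)


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Execute all stages and write artifacts plus a single report JSON.

    Stages whose inputs are absent are skipped (e.g. no expression block →
    topology/module stages only). Returns the report dict; the same dict is
    written to ``<out_dir>/report.json``.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    report: dict[str, Any] = {
        "metadata": {
            "package_version": __version__,
            "config_hash": _config_hash(cfg, seed),
            "seed": seed,
            "thresholds": thresholds,
        }
    }

    # -- stage 0: inputs ---------------------------------------------------
    if "synthetic" in cfg:
        if seed is None:
            raise ValueError("a seed is required for a synthetic scenario")
        scen_cfg = _scenario_config(cfg["synthetic"])
        bundle = make_scenario(scen_cfg, seed, out / "inputs")
        paths = bundle["paths"]
        inputs = {
            "ppi": paths["ppi"], "ppi_dialect": "tsv-edge-list",
            "immune": paths["immune"], "immune_dialect": "plain-list",
            "disease": paths["disease"], "disease_dialect": "plain-list",
            "expression": paths["expression"], "expression_dialect": "plain-tsv",
            "labels": paths["labels"], "gmt": paths["gmt"],
        }
        report["metadata"]["synthetic"] = True
    elif "inputs" in cfg:
        inputs = dict(cfg["inputs"])
        for key in ("ppi", "immune", "disease"):
            if key not in inputs:
                raise ValueError(f"config inputs block is missing {key!r}")
        report["metadata"]["synthetic"] = False
    else:
        raise ValueError("config needs an 'inputs' or 'synthetic' block")

    # -- stage 1: seeds and base network ------------------------------------
    immune = load_gene_set(inputs["immune"], inputs.get("immune_dialect", "plain-list"),
                           name="immune")
    disease = load_gene_set(inputs["disease"], inputs.get("disease_dialect", "plain-list"),
                            name="disease")
    ppi = load_network(inputs["ppi"], inputs.get("ppi_dialect", "tsv-edge-list"),
                       name="ppi")
    union_seeds = GeneSet(name="immune∪disease",
                          symbols=immune.symbols | disease.symbols,
                          provenance="union of immune and disease seed sets")
    report["inputs"] = {
        "ppi_nodes": ppi.node_count, "ppi_edges": ppi.edge_count,
        "immune_seeds": len(immune), "disease_seeds": len(disease),
        "seed_union": len(union_seeds),
    }

    # -- stage 2: seeded subnetworks ----------------------------------------
    iomdn = build_neighbor_network(ppi, union_seeds, name="IOMDN")
    mgnd = build_neighbor_network(iomdn.network, disease, name="MGND")
    retention = edge_retention(mgnd, iomdn.network)
    report["networks"] = {}
    for label, seeded in (("iomdn", iomdn), ("mgnd", mgnd)):
        net = seeded.network
        cmap = classify_nodes(net.nodes, immune, disease)
        tally = tally_categories(cmap)
        topo = topology_summary(net)
        dd = degree_distribution(net)
        hubs = hub_analysis(net, cmap, k=int(thresholds["top_hubs"]))
        report["networks"][label] = {
            "topology": topo.as_dict(),
            "category_tally": tally.as_dict(),
            "degree_distribution": dd.as_dict(),
            "hubs": hubs.as_dict(),
        }
        for fmt, ext in (("tsv-edge-list", "tsv"), ("sif", "sif"),
                         ("graphml", "graphml")):
            write_network(net, out / f"{label}.{ext}", format=fmt, attributes=cmap)
        write_category_map(cmap, out / f"{label}_categories.tsv")
    report["retention"] = retention.as_dict()
    mgnd_cmap = classify_nodes(mgnd.network.nodes, immune, disease)

    # -- stage 3: dense modules ---------------------------------------------
    params = McodeParams(**cfg.get("mcode", {}))
    modules_all = detect_modules(mgnd.network, params)
    top_modules = detect_modules(mgnd.network, params,
                                 top=int(thresholds["top_modules"]))
    report["modules"] = {
        "params": params.as_dict(),
        "detected": len(modules_all),
        "by_score": [m.as_dict() for m in modules_all],
        "top_by_size": [m.as_dict() for m in top_modules],
    }
    for mod in top_modules:
        sub = mgnd.network.subgraph(mod.members, name=f"module{mod.rank}")
        write_network(sub, out / f"module_{mod.rank}.sif", format="sif")
        (out / f"module_{mod.rank}_members.tsv").write_text(
            "".join(f"{g}\t{mgnd_cmap[g].value}\n" for g in sorted(mod.members)))

    # -- stage 4: expression overlay ----------------------------------------
    if inputs.get("expression"):
        mat = load_expression(inputs["expression"],
                              inputs.get("expression_dialect", "plain-tsv"),
                              labels=inputs["labels"])
        cors = correlate_edges(mgnd.network, mat, group="disease",
                               alpha=thresholds["coexpression_alpha"],
                               strong_threshold=thresholds["strong_threshold"])
        summary = classify_correlations(cors, alpha=thresholds["coexpression_alpha"],
                                        strong_threshold=thresholds["strong_threshold"])
        dex = differential_expression(mat, variant=thresholds["de_variant"],
                                      alpha=thresholds["de_alpha"])
        correlations_to_frame(cors).to_csv(out / "edge_correlations.tsv",
                                           sep="\t", index=False)
        diffexpr_to_frame(dex).to_csv(out / "differential_expression.tsv",
                                      sep="\t", index=False)
        report["expression"] = {
            "samples_disease": len(mat.group_samples("disease")),
            "samples_control": len(mat.group_samples("control")),
            "genes": len(mat.genes),
            "correlation_summary": summary.as_dict(),
            "differential_total": sum(1 for r in dex if r.differential),
            "per_module": [
                module_expression_report(mod, dex, cors).as_dict()
                for mod in top_modules
            ],
        }
    else:
        logger.info("no expression block; skipping overlay stage")

    # -- stage 5: enrichment -------------------------------------------------
    if inputs.get("gmt"):
        coll = load_gene_set_collection(inputs["gmt"])
        background = GeneSet(name="mgnd-nodes",
                             symbols=frozenset(mgnd.network.nodes),
                             provenance="all MGND network genes")
        module_genes = frozenset().union(*(m.members for m in top_modules)) \
            if len(top_modules) else frozenset()
        query = GeneSet(name="module-genes", symbols=module_genes,
                        provenance="union of top-module members")
        results = overrepresent(query, coll, background,
                                alpha=thresholds["enrichment_alpha"])
        bipartite = drug_gene_network(results, query)
        with (out / "enrichment.tsv").open("w") as fh:
            fh.write("term\tk\tK\tn\tN\tp\tq\tenriched\toverlap\n")
            for res in results:
                fh.write(f"{res.term}\t{res.overlap_count}\t{res.term_size}\t"
                         f"{res.query_size}\t{res.background_size}\t{res.p:.6g}\t"
                         f"{res.q:.6g}\t{res.enriched}\t"
                         f"{','.join(sorted(res.overlap_genes))}\n")
        with (out / "drug_gene_network.sif").open("w") as fh:
            for term, gene in bipartite:
                fh.write(f"{term}\ttargets\t{gene}\n")
        report["enrichment"] = {
            "collection_terms": len(coll),
            "tested": len(results),
            "enriched": sum(1 for res in results if res.enriched),
            "results": [res.as_dict() for res in results],
            "drug_gene_edges": len(bipartite),
        }
    else:
        logger.info("no gene-set collection; skipping enrichment stage")

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("report written to %s", report_path)
    return report
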