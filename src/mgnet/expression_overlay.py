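"""Expression overlay on the interaction network.

Loads a gene-by-sample expression matrix (plain TSV or GEO series-matrix
text) with disease/control labels, computes edge-wise Pearson correlations
on the disease samples with a two-sided t-transform significance test,
classifies significant / strong co-expression, and calls per-gene
differential expression with an unpaired (Welch by default) t-test.

Raw p-values drive the significant/differential flags, mirroring how such
pipelines typically report them; Benjamini–Hochberg q-values are computed
alongside every p and written to all outputs, clearly labelled, so users
can apply FDR control instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gene_catalog import normalize_symbol
from .interaction_graph import InteractionNetwork
from .module_detection import Module

logger = logging.getLogger("mgnet.expression_overlay")

__all__ = [
    "ExpressionMatrix",
    "EdgeCorrelation",
    "CorrelationSummary",
    "DiffExpressionRecord",
    "ModuleExpressionReport",
    "load_expression",
    "collapse_probes",
    "pearson_pvalue",
    "correlate_edges",
    "classify_correlations",
    "differential_expression",
    "module_expression_report",
]

DISEASE = "disease"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with a disease/control labelling.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample IDs
    as columns; missing observations are NaN. Every sample must carry a
    group label.
    """

    values: pd.DataFrame
    group: dict[str, str]

    def __post_init__(self) -> None:
        unlabeled = [s for s in self.values.columns if s not in self.group]
        if unlabeled:
            raise ValueError(f"samples without a group label: {unlabeled[:5]}")
        bad = {g for g in self.group.values()} - {DISEASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene rows (collapse probes first): "
                             f"{list(dups[:5])}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        if group == "all":
            return self.samples
        return [s for s in self.samples if self.group[s] == group]


@dataclass(frozen=True)
class EdgeCorrelation:
    """Pearson correlation of one network edge over one sample group."""

    edge: tuple[str, str]
    r: float
    n: int
    p: float
    q: float = float("nan")
    significant: bool = False
    strong: bool = False
    valid: bool = True       # False: gene missing, zero variance, or n too small
    degenerate: bool = False  # |r| == 1 exactly; p is the df-limited floor


@dataclass(frozen=True)
class CorrelationSummary:
    total_edges: int
    computed_edges: int
    significant_count: int
    strong_among_significant: int
    positive_significant: int
    negative_significant: int

    @property
    def significant_share(self) -> float:
        return self.significant_count / self.computed_edges if self.computed_edges else 0.0

    @property
    def strong_share(self) -> float:
        return (self.strong_among_significant / self.significant_count
                if self.significant_count else 0.0)

    def as_dict(self) -> dict:
        return {
            "total_edges": self.total_edges,
            "computed_edges": self.computed_edges,
            "significant_count": self.significant_count,
            "significant_share": self.significant_share,
            "significant_percent": round(100 * self.significant_share, 2),
            "strong_among_significant": self.strong_among_significant,
            "strong_share": self.strong_share,
            "strong_percent": round(100 * self.strong_share, 2),
            "positive_significant": self.positive_significant,
            "negative_significant": self.negative_significant,
        }


@dataclass(frozen=True)
class DiffExpressionRecord:
    gene: str
    mean_disease: float
    mean_control: float
    t_statistic: float
    p: float
    q: float
    direction: str  # "up" | "down"
    differential: bool


@dataclass(frozen=True)
class ModuleExpressionReport:
    module_rank: int | None
    gene_count: int
    differential_count: int
    up_count: int
    down_count: int
    correlations: tuple[EdgeCorrelation, ...] = field(repr=False)

    def as_dict(self) -> dict:
        sig = [c for c in self.correlations if c.valid and c.significant]
        return {
            "module_rank": self.module_rank,
            "gene_count": self.gene_count,
            "differential_count": self.differential_count,
            "up_count": self.up_count,
            "down_count": self.down_count,
            "edge_count": len(self.correlations),
            "significant_edges": len(sig),
            "positive_significant": sum(1 for c in sig if c.r > 0),
            "negative_significant": sum(1 for c in sig if c.r < 0),
        }


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

_SM_BEGIN = "!series_matrix_table_begin"
_SM_END = "!series_matrix_table_end"


def _read_labels(labels: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(labels, Mapping):
        return dict(labels)
    table = pd.read_csv(labels, sep="\t", header=None, comment="#", dtype=str)
    if list(table.iloc[0]) in (["sample", "group"], ["sample_id", "group"]):
        table = table.iloc[1:]
    return {str(row[0]).strip(): str(row[1]).strip().lower()
            for row in table.itertuples(index=False)}


def load_expression(path: str | Path, dialect: str = "plain-tsv",
                    labels: str | Path | Mapping[str, str] | None = None,
                    ) -> ExpressionMatrix:
    """Read an expression matrix.

    ``plain-tsv``: first column gene/probe ID, remaining columns samples,
    header row of sample IDs. ``series-matrix``: GEO text export; only the
    block between the table begin/end markers is parsed. Empty cells,
    ``NA`` and ``null`` become missing values; any other non-numeric cell
    raises with its coordinates.
    """
    path = Path(path)
    if dialect == "series-matrix":
        lines = path.read_text().splitlines()
        try:
            start = next(i for i, l in enumerate(lines) if l.strip() == _SM_BEGIN)
            end = next(i for i, l in enumerate(lines) if l.strip() == _SM_END)
        except StopIteration:
            raise ValueError(f"{path}: series-matrix table markers not found")
        from io import StringIO
        block = "\n".join(lines[start + 1:end])
        table = pd.read_csv(StringIO(block), sep="\t", index_col=0,
                            na_values=["NA", "null", ""])
    elif dialect == "plain-tsv":
        table = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                            na_values=["NA", "null", ""])
    else:
        raise ValueError(f"unknown expression dialect: {dialect!r}")
    table.index = [str(i).strip().strip('"').upper() for i in table.index]
    table.columns = [str(c).strip().strip('"') for c in table.columns]
    for col in table.columns:
        if table[col].dtype == object:
            converted = pd.to_numeric(table[col], errors="coerce")
            bad = table[col].notna() & converted.isna()
            if bad.any():
                gene = table.index[bad.argmax()]
                raise ValueError(f"{path}: non-numeric value {table.loc[gene, col]!r} "
                                 f"at gene {gene!r}, sample {col!r}")
            table[col] = converted
    if labels is None:
        raise ValueError("sample group labels are required")
    group = _read_labels(labels)
    logger.info("loaded expression: %d genes × %d samples from %s",
                *table.shape, path)
    return ExpressionMatrix(values=table.astype(float), group=group)


def collapse_probes(mat: ExpressionMatrix, probe2gene: Mapping[str, str],
                    strategy: str = "max-mean-probe") -> ExpressionMatrix:
    """Collapse probe rows to one row per gene.

    ``max-mean-probe`` keeps the probe with the highest mean expression;
    ``mean`` averages all probes of a gene elementwise. Probes missing from
    the mapping are dropped with a log message.
    """
    mapped = {p: normalize_symbol(g) for p, g in probe2gene.items()}
    known = [p for p in mat.values.index if p in mapped]
    dropped = len(mat.values.index) - len(known)
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    sub = mat.values.loc[known]
    gene_of = pd.Series([mapped[p] for p in known], index=sub.index)
    if strategy == "max-mean-probe":
        order = sub.mean(axis=1, skipna=True)
        best = (pd.DataFrame({"gene": gene_of, "mean": order})
                .groupby("gene")["mean"].idxmax())
        out = sub.loc[best]
        out.index = best.index
    elif strategy == "mean":
        out = sub.groupby(gene_of).mean()
    else:
        raise ValueError(f"unknown collapse strategy: {strategy!r}")
    return ExpressionMatrix(values=out.sort_index(), group=dict(mat.group))


# ---------------------------------------------------------------------------
# edge correlations
# ---------------------------------------------------------------------------

_P_FLOOR = float(np.finfo(float).tiny)


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t transform.

    t = r * sqrt((n-2) / (1-r²)) on n-2 degrees of freedom. |r| == 1 returns
    the smallest positive float (degenerate, df-limited).
    """
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if abs(r) >= 1.0:
        return _P_FLOOR
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def correlate_edges(net: InteractionNetwork, mat: ExpressionMatrix,
                    group: str = DISEASE, alpha: float = 0.05,
                    strong_threshold: float = 0.5) -> list[EdgeCorrelation]:
    """Pearson r and two-sided p for every network edge, over one group.

    Uses pairwise-complete observations; edges with a gene missing from the
    matrix, fewer than 4 complete pairs, or a zero-variance gene are
    returned flagged invalid. BH q-values are computed across all valid
    edges. Results are sorted by edge for determinism.
    """
    samples = mat.group_samples(group)
    if len(samples) < 4:
        raise ValueError(f"group {group!r} has {len(samples)} samples; need >= 4")
    sub = mat.values[samples]
    gene_index = set(sub.index)
    records: list[EdgeCorrelation] = []
    edges = sorted(tuple(sorted(e)) for e in net.edges)
    for a, b in edges:
        if a not in gene_index or b not in gene_index:
            records.append(EdgeCorrelation((a, b), float("nan"), 0, float("nan"),
                                           valid=False))
            continue
        x = sub.loc[a].to_numpy(dtype=float)
        y = sub.loc[b].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < 4:
            records.append(EdgeCorrelation((a, b), float("nan"), n, float("nan"),
                                           valid=False))
            continue
        xs, ys = x[ok], y[ok]
        sx, sy = xs.std(), ys.std()
        if sx == 0.0 or sy == 0.0:
            records.append(EdgeCorrelation((a, b), float("nan"), n, float("nan"),
                                           valid=False))
            continue
        r = float(np.clip(((xs - xs.mean()) * (ys - ys.mean())).sum()
                          / (len(xs) * sx * sy), -1.0, 1.0))
        # exact collinearity lands within float rounding of ±1
        degenerate = abs(r) >= 1.0 - 1e-12
        p = _P_FLOOR if degenerate else pearson_pvalue(r, n)
        records.append(EdgeCorrelation((a, b), r, n, p, degenerate=degenerate))
    valid_idx = [i for i, rec in enumerate(records) if rec.valid]
    if valid_idx:
        qs = multipletests([records[i].p for i in valid_idx], method="fdr_bh")[1]
        for i, q in zip(valid_idx, qs):
            rec = records[i]
            records[i] = EdgeCorrelation(
                rec.edge, rec.r, rec.n, rec.p, q=float(q),
                significant=rec.p < alpha,
                strong=abs(rec.r) > strong_threshold,
                degenerate=rec.degenerate)
    return records


def classify_correlations(records: Sequence[EdgeCorrelation], alpha: float = 0.05,
                          strong_threshold: float = 0.5) -> CorrelationSummary:
    """Tally significant and strong co-expression among computed edges.

    ``strong`` (|r| above the threshold) is counted among significant
    records only, matching how "strongly co-expressed interactions" are
    reported downstream.
    """
    valid = [rec for rec in records if rec.valid]
    sig = [rec for rec in valid if rec.p < alpha]
    return CorrelationSummary(
        total_edges=len(records),
        computed_edges=len(valid),
        significant_count=len(sig),
        strong_among_significant=sum(1 for rec in sig
                                     if abs(rec.r) > strong_threshold),
        positive_significant=sum(1 for rec in sig if rec.r > 0),
        negative_significant=sum(1 for rec in sig if rec.r < 0),
    )


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(mat: ExpressionMatrix, variant: str = "welch",
                            alpha: float = 0.05) -> list[DiffExpressionRecord]:
    """Unpaired two-sided t-test per gene, disease vs control.

    ``welch`` (default) does not assume equal variances; ``student`` is the
    classical pooled-variance test. Genes with fewer than 3 non-missing
    observations in either group are skipped with a warning. Direction is
    the sign of (mean_disease − mean_control); the differential flag is raw
    p < alpha, with BH q reported alongside.
    """
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    d_samples = mat.group_samples(DISEASE)
    c_samples = mat.group_samples(CONTROL)
    if len(d_samples) < 3 or len(c_samples) < 3:
        raise ValueError("need >= 3 samples per group")
    rows: list[tuple[str, float, float, float, float]] = []
    skipped = 0
    for gene in mat.genes:
        x = mat.values.loc[gene, d_samples].to_numpy(dtype=float)
        y = mat.values.loc[gene, c_samples].to_numpy(dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 3 or len(y) < 3:
            skipped += 1
            continue
        t, p = stats.ttest_ind(x, y, equal_var=(variant == "student"))
        rows.append((gene, float(x.mean()), float(y.mean()), float(t), float(p)))
    if skipped:
        logger.warning("differential_expression: skipped %d genes with <3 "
                       "observations in a group", skipped)
    if not rows:
        return []
    qs = multipletests([row[4] for row in rows], method="fdr_bh")[1]
    return [
        DiffExpressionRecord(
            gene=gene, mean_disease=md, mean_control=mc, t_statistic=t, p=p,
            q=float(q), direction="up" if md - mc >= 0 else "down",
            differential=p < alpha)
        for (gene, md, mc, t, p), q in zip(rows, qs)
    ]


def module_expression_report(module: Module, dex: Sequence[DiffExpressionRecord],
                             cors: Sequence[EdgeCorrelation],
                             ) -> ModuleExpressionReport:
    """Differential-expression tallies and the edge-correlation table for one module."""
    members = module.members
    mod_dex = [rec for rec in dex if rec.gene in members]
    diff = [rec for rec in mod_dex if rec.differential]
    up = sum(1 for rec in diff if rec.direction == "up")
    mod_cors = tuple(rec for rec in cors
                     if rec.edge[0] in members and rec.edge[1] in members)
    return ModuleExpressionReport(
        module_rank=module.rank,
        gene_count=len(members),
        differential_count=len(diff),
        up_count=up,
        down_count=len(diff) - up,
        correlations=mod_cors,
    )


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def correlations_to_frame(records: Sequence[EdgeCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_a": rec.edge[0], "gene_b": rec.edge[1], "r": rec.r, "n": rec.n,
          "p": rec.p, "q": rec.q, "significant": rec.significant,
          "strong": rec.strong, "valid": rec.valid, "degenerate": rec.degenerate}
         for rec in records]
    )


def diffexpr_to_frame(records: Sequence[DiffExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene": rec.gene, "mean_disease": rec.mean_disease,
          "mean_control": rec.mean_control, "t": rec.t_statistic, "p": rec.p,
          "q": rec.q, "direction": rec.direction, "differential": rec.differential}
         for rec in records]
    )
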