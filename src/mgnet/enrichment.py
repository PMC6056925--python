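"""Local over-representation analysis on GMT gene-set collections.

Runs the classical hypergeometric (one-sided, upper-tail) test of overlap
between a query gene set and each term of a GMT collection over an explicit
background, with Benjamini–Hochberg adjustment across terms. This replaces
web-service enrichment with a local, auditable computation on user-supplied
collections (GO, KEGG, drug-target signatures, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .gene_catalog import GeneSet, normalize_symbol

logger = logging.getLogger("mgnet.enrichment")

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "load_gene_set_collection",
    "write_gene_set_collection",
    "overrepresent",
    "drug_gene_network",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named mapping of term -> member gene set, e.g. one GMT file."""

    name: str
    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] | None = None
    universe: frozenset[str] | None = None

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap_count: int      # k
    query_size: int         # n
    term_size: int          # K (restricted to the background)
    background_size: int    # N
    p: float                # hypergeometric upper tail P(X >= k)
    q: float                # BH-adjusted
    enriched: bool          # p < alpha
    overlap_genes: frozenset[str]

    def as_dict(self) -> dict:
        return {"term": self.term, "k": self.overlap_count, "n": self.query_size,
                "K": self.term_size, "N": self.background_size, "p": self.p,
                "q": self.q, "enriched": self.enriched,
                "overlap_genes": sorted(self.overlap_genes)}


def load_gene_set_collection(path: str | Path, name: str | None = None,
                             ) -> GeneSetCollection:
    """Parse a GMT file (term, description, genes...; tab-separated).

    Symbols are uppercased and deduplicated; terms that end up empty are
    dropped with a warning. Malformed lines raise with their line number.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: GMT line needs term and description")
        term, desc, *genes = fields
        if term in sets:
            raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
        members = frozenset(normalize_symbol(g) for g in genes if g.strip())
        if not members:
            logger.warning("%s:%d: term %r has no genes; dropped", path, lineno, term)
            continue
        sets[term] = members
        descriptions[term] = desc
    return GeneSetCollection(name=name or path.stem, sets=sets,
                             descriptions=descriptions)


def write_gene_set_collection(coll: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for term in sorted(coll.sets):
            desc = (coll.descriptions or {}).get(term, "")
            genes = "\t".join(sorted(coll.sets[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def overrepresent(query: GeneSet, coll: GeneSetCollection, background: GeneSet,
                  alpha: float = 0.01) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of `query` in each term of `coll`.

    Query genes outside the background are dropped with a warning; term
    sizes are likewise restricted to the background (genes the query could
    never have drawn cannot inflate a term). Results are sorted by
    ascending p, then term name. An empty filtered query returns [].
    """
    bg = background.symbols
    q = query.symbols & bg
    dropped = len(query.symbols) - len(q)
    if dropped:
        logger.warning("overrepresent: %d query genes outside the background "
                       "dropped", dropped)
    if not q:
        logger.warning("overrepresent: empty query after background filtering")
        return []
    N, n = len(bg), len(q)
    rows = []
    for term in sorted(coll.sets):
        members = coll.sets[term] & bg
        K = len(members)
        if K == 0:
            continue
        overlap = q & members
        k = len(overlap)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p, overlap))
    if not rows:
        return []
    qs = multipletests([row[3] for row in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(term=term, overlap_count=k, query_size=n, term_size=K,
                         background_size=N, p=p, q=float(adj),
                         enriched=p < alpha, overlap_genes=frozenset(overlap))
        for (term, k, K, p, overlap), adj in zip(rows, qs)
    ]
    results.sort(key=lambda res: (res.p, res.term))
    return results


def drug_gene_network(results: Sequence[EnrichmentResult], query: GeneSet,
                      ) -> list[tuple[str, str]]:
    """Bipartite (term, gene) edge list over enriched terms' query overlaps."""
    edges = []
    for res in results:
        if not res.enriched:
            continue
        for gene in sorted(res.overlap_genes & query.symbols):
            edges.append((res.term, gene))
    return edges
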