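"""Seed gene catalogues.

Reads immune and disease seed gene lists from the common flat formats
(plain symbol lists, GAF 2.x annotation files, two-column TSVs), normalises
symbols to uppercase, and classifies network nodes into the four-way scheme
used throughout the analysis: genes in both seed sets, disease-only,
immune-only, and everything else.

Gene identity is the uppercased symbol string; no alias or identifier
mapping is attempted, so results are deterministic and independent of
annotation snapshots.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger("mgnet.gene_catalog")

__all__ = [
    "GeneSet",
    "NodeCategory",
    "CategoryTally",
    "load_gene_set",
    "classify_nodes",
    "tally_categories",
    "write_category_map",
]


def normalize_symbol(raw: str) -> str:
    """Uppercase and strip a gene symbol.

    Raises ``ValueError`` if the stripped symbol is empty or contains
    internal whitespace (symbols are single tokens).
    """
    sym = raw.strip().upper()
    if not sym:
        raise ValueError("empty gene symbol")
    if any(ch.isspace() for ch in sym):
        raise ValueError(f"gene symbol contains whitespace: {raw!r}")
    return sym


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of uppercased gene symbols."""

    name: str
    symbols: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        for sym in self.symbols:
            if not sym or any(ch.isspace() for ch in sym):
                raise ValueError(f"invalid symbol in gene set {self.name!r}: {sym!r}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, item: str) -> bool:
        return item in self.symbols

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str], provenance: str = "") -> "GeneSet":
        return cls(name=name, symbols=frozenset(normalize_symbol(s) for s in symbols),
                   provenance=provenance)


class NodeCategory(str, Enum):
    """Four-way node classification against the two seed sets."""

    BOTH = "BOTH"
    DISEASE_ONLY = "DISEASE_ONLY"
    IMMUNE_ONLY = "IMMUNE_ONLY"
    OTHER = "OTHER"


#: node symbol -> NodeCategory
CategoryMap = dict


@dataclass(frozen=True)
class CategoryTally:
    """Counts per category; ``total`` always equals their sum."""

    both: int
    disease_only: int
    immune_only: int
    other: int

    @property
    def total(self) -> int:
        return self.both + self.disease_only + self.immune_only + self.other

    def as_dict(self) -> dict[str, int]:
        return {
            "both": self.both,
            "disease_only": self.disease_only,
            "immune_only": self.immune_only,
            "other": self.other,
            "total": self.total,
        }


_GAF_SYMBOL_COLUMN = 2  # DB Object Symbol, third column of GAF 2.x


def _parse_plain_list(lines: Iterable[str]) -> list[str]:
    out = []
    for line in lines:
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def _parse_gaf(lines: Iterable[str], path: Path) -> list[str]:
    out = []
    for lineno, line in enumerate(lines, 1):
        if line.startswith("!") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) <= _GAF_SYMBOL_COLUMN:
            raise ValueError(f"{path}:{lineno}: GAF line has {len(fields)} columns, "
                             f"need at least {_GAF_SYMBOL_COLUMN + 1}")
        out.append(fields[_GAF_SYMBOL_COLUMN])
    return out


def _parse_two_column_tsv(lines: Iterable[str], path: Path, column: int | str) -> list[str]:
    rows = []
    for line in lines:
        if line.startswith("#") or not line.strip():
            continue
        rows.append(line.rstrip("\n").split("\t"))
    if not rows:
        return []
    if isinstance(column, str):
        header, rows = rows[0], rows[1:]
        try:
            idx = [h.strip() for h in header].index(column)
        except ValueError:
            raise ValueError(f"{path}: no column named {column!r} in header {header}")
    else:
        idx = column
    out = []
    for row in rows:
        if len(row) <= idx:
            raise ValueError(f"{path}: row {row} has no column {idx}")
        out.append(row[idx])
    return out


def load_gene_set(path: str | Path, dialect: str = "plain-list", name: str | None = None,
                  column: int | str = 1) -> GeneSet:
    """Read a seed gene list.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``plain-list`` (one symbol per line, ``#`` comments), ``gaf``
        (GAF 2.x, ``!`` comments, symbol in the DB-Object-Symbol column),
        or ``two-column-tsv`` (symbol taken from `column`, a 0-based index
        or a header name; default: second column).
    name
        Label for the set; defaults to the file stem.
    column
        For ``two-column-tsv`` only: which column holds the gene symbol.

    Raises
    ------
    ValueError
        If the file yields zero symbols, or a line is malformed.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect == "plain-list":
        raw = _parse_plain_list(lines)
    elif dialect == "gaf":
        raw = _parse_gaf(lines, path)
    elif dialect == "two-column-tsv":
        raw = _parse_two_column_tsv(lines, path, column)
    else:
        raise ValueError(f"unknown gene-list dialect: {dialect!r}")
    symbols = frozenset(normalize_symbol(s) for s in raw)
    if not symbols:
        raise ValueError(f"no gene symbols parsed from {path} (dialect {dialect})")
    gs = GeneSet(name=name or path.stem, symbols=symbols,
                 provenance=f"{path} ({dialect})")
    logger.info("loaded gene set %s: %d symbols from %s", gs.name, len(gs), path)
    return gs


def classify_nodes(nodes: Iterable[str], immune: GeneSet, disease: GeneSet) -> CategoryMap:
    """Assign each node to exactly one of the four seed categories."""
    cmap: CategoryMap = {}
    for node in nodes:
        in_imm = node in immune.symbols
        in_dis = node in disease.symbols
        if in_imm and in_dis:
            cmap[node] = NodeCategory.BOTH
        elif in_dis:
            cmap[node] = NodeCategory.DISEASE_ONLY
        elif in_imm:
            cmap[node] = NodeCategory.IMMUNE_ONLY
        else:
            cmap[node] = NodeCategory.OTHER
    return cmap


def tally_categories(cmap: CategoryMap) -> CategoryTally:
    """Count nodes per category. Counts always sum to ``len(cmap)``."""
    counts = Counter(cmap.values())
    return CategoryTally(
        both=counts.get(NodeCategory.BOTH, 0),
        disease_only=counts.get(NodeCategory.DISEASE_ONLY, 0),
        immune_only=counts.get(NodeCategory.IMMUNE_ONLY, 0),
        other=counts.get(NodeCategory.OTHER, 0),
    )


def write_category_map(cmap: Mapping[str, NodeCategory], path: str | Path) -> None:
    """Write a category map as a two-column TSV (node, category)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("node\tcategory\n")
        for node in sorted(cmap):
            fh.write(f"{node}\t{cmap[node].value}\n")


def unmatched_seeds(seeds: GeneSet, nodes: Iterable[str]) -> frozenset[str]:
    """Seed symbols absent from a node collection (reported, never dropped)."""
    missing = seeds.symbols - set(nodes)
    if missing:
        logger.info("%d/%d %s seeds not present in the network",
                    len(missing), len(seeds), seeds.name)
    return frozenset(missing)
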