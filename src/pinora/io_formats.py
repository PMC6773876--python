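"""Readers and writers for the plain-text formats the pipeline touches.

Three external formats are supported:

* **SIF** (simple interaction file) for protein--protein interaction
  networks (PINs): one interaction per line, either ``source relation
  target`` or just ``source target``, whitespace- or tab-delimited.  The
  relation column is ignored; interaction types play no role downstream.
* **GMT** (Gene Matrix Transposed) for gene-set collections: one set per
  line as ``set_id<TAB>description<TAB>gene1<TAB>gene2...``.
* **TSV** for differential-expression tables, expression matrices,
  alias maps and enrichment result tables.

Gene symbols are compared case-sensitively after stripping surrounding
whitespace; no automatic upper-casing is applied (HGNC symbols are
case-significant in practice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "FormatError",
    "InteractionNetwork",
    "GeneSetCollection",
    "DegTable",
    "ExpressionMatrix",
    "read_sif",
    "write_sif",
    "read_gmt",
    "write_gmt",
    "read_deg_table",
    "write_deg_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_alias_map",
    "write_result_table",
    "read_result_table",
    "RESULT_COLUMNS",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionNetwork:
    """An undirected, deduplicated, self-loop-free gene-symbol graph (the PIN)."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        g = nx.Graph()
        for a, b in edges:
            a, b = a.strip(), b.strip()
            if a == b:
                continue
            g.add_edge(a, b)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return self.graph.has_node(gene)

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def adjacency(self) -> dict[str, set[str]]:
        """Plain adjacency-set mapping, convenient for tight search loops."""
        return {n: set(nbrs) for n, nbrs in self.graph.adjacency()}


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (pathways) with human-readable descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.sets) != set(self.descriptions):
            raise ValueError("descriptions must cover exactly the set ids present")
        for sid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id]


@dataclass(frozen=True)
class DegTable:
    """Differential expression/methylation input.

    One row per gene: symbol, optional change value (log-fold change) and
    an adjusted p value in [0, 1].  The change column is either present for
    all rows or absent entirely.
    """

    table: pd.DataFrame  # columns: gene, [change,] adj_p

    def __post_init__(self) -> None:
        cols = list(self.table.columns)
        if cols not in (["gene", "adj_p"], ["gene", "change", "adj_p"]):
            raise ValueError(f"unexpected DegTable columns: {cols}")
        if self.table["gene"].duplicated().any():
            dupes = self.table.loc[self.table["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate gene symbols in DegTable: {dupes[:5]}")
        ps = self.table["adj_p"]
        if ps.isna().any() or (ps < 0).any() or (ps > 1).any():
            raise ValueError("adjusted p values must lie in [0, 1]")

    @property
    def has_change(self) -> bool:
        return "change" in self.table.columns

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def p_values(self) -> dict[str, float]:
        return dict(zip(self.table["gene"], self.table["adj_p"]))

    def change_values(self) -> dict[str, float]:
        if not self.has_change:
            return {}
        return dict(zip(self.table["gene"], self.table["change"]))

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], has_change: bool | None = None
    ) -> "DegTable":
        """Build from (gene, [change,] p) tuples, collapsing duplicate genes
        to the row with the lowest p (ties: first occurrence)."""
        rows = [tuple(r) for r in records]
        if not rows:
            return cls(pd.DataFrame({"gene": [], "adj_p": []}).astype({"gene": str}))
        width = len(rows[0])
        if has_change is None:
            has_change = width == 3
        if any(len(r) != width for r in rows):
            raise ValueError("inconsistent row widths in DEG records")
        cols = ["gene", "change", "adj_p"] if has_change else ["gene", "adj_p"]
        df = pd.DataFrame(rows, columns=cols)
        df["gene"] = df["gene"].astype(str).str.strip()
        df["adj_p"] = pd.to_numeric(df["adj_p"], errors="raise")
        if has_change:
            df["change"] = pd.to_numeric(df["change"], errors="raise")
        # stable sort keeps first occurrence on p ties
        df = (
            df.sort_values("adj_p", kind="stable")
            .drop_duplicates("gene", keep="first")
            .sort_index()
            .reset_index(drop=True)
        )
        return cls(df)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes (rows) x samples (columns) of real values, optional group labels."""

    values: pd.DataFrame
    groups: Mapping[str, str] | None = None  # sample -> group label

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene rows in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample labels in expression matrix")
        if self.values.isna().any().any():
            raise ValueError("missing values in expression matrix")
        if self.groups is not None:
            unknown = set(self.groups) - set(self.values.columns)
            if unknown:
                raise ValueError(f"group labels for unknown samples: {sorted(unknown)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# SIF
# ---------------------------------------------------------------------------


def read_sif(path: str | Path) -> InteractionNetwork:
    """Read a PIN from SIF, dropping duplicate interactions and self-loops.

    Accepts both two-field (``source target``) and three-or-more-field
    (``source relation target [target2 ...]``) lines; the relation column is
    discarded.
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) == 1:
                raise FormatError(f"{path}: line {lineno}: expected >=2 fields")
            if len(fields) == 2:
                edges.append((fields[0], fields[1]))
            else:
                src = fields[0]
                edges.extend((src, tgt) for tgt in fields[2:])
    net = InteractionNetwork.from_edges(edges)
    if net.n_edges == 0:
        raise FormatError(f"{path}: empty network")
    return net


def write_sif(net: InteractionNetwork, path: str | Path, relation: str = "pp") -> None:
    lines = sorted(tuple(sorted(e)) for e in net.edges)
    with open(path, "w") as fh:
        for a, b in lines:
            fh.write(f"{a}\t{relation}\t{b}\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a gene-set collection; duplicate genes within a line are dropped."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected id, description and >=1 gene"
                )
            set_id = fields[0].strip()
            if set_id in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}: line {lineno}: no genes in set {set_id!r}")
            sets[set_id] = genes
            descriptions[set_id] = fields[1]
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[set_id]))
            fh.write(f"{set_id}\t{collection.descriptions[set_id]}\t{genes}\n")


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_deg_table(path: str | Path) -> DegTable:
    """Read a two- or three-column DEG table (gene, [log-fold change,] adj p).

    A header row is auto-detected (non-numeric last column in the first row).
    Duplicate gene symbols collapse to the row with the lowest p value, the
    same rule used when one gene is targeted by multiple array probes.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) == 1:  # fall back to any whitespace
                fields = line.split()
            rows.append(fields)
    if not rows:
        raise FormatError(f"{path}: empty DEG table")
    widths = {len(r) for r in rows}
    if len(widths) != 1 or widths.pop() not in (2, 3):
        raise FormatError(f"{path}: DEG table must have 2 or 3 columns throughout")
    if not _is_number(rows[0][-1]):
        rows = rows[1:]
        if not rows:
            raise FormatError(f"{path}: DEG table has a header but no data rows")
    try:
        records = [
            (r[0], *(float(v) for v in r[1:])) for r in rows
        ]
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric value in DEG table: {exc}") from exc
    for rec in records:
        p = rec[-1]
        if not (0.0 <= p <= 1.0) or math.isnan(p):
            raise FormatError(f"{path}: adjusted p value {p} outside [0, 1]")
    return DegTable.from_records(records)


def write_deg_table(deg: DegTable, path: str | Path) -> None:
    deg.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices and alias maps
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene symbols)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value: {exc}") from exc
    try:
        return ExpressionMatrix(values=df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene")


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column alias -> canonical symbol TSV (no header).

    An alias mapping to more than one canonical symbol is an error.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            alias, canonical = fields[0].strip(), fields[1].strip()
            if alias in mapping and mapping[alias] != canonical:
                raise FormatError(
                    f"{path}: line {lineno}: alias {alias!r} maps to both "
                    f"{mapping[alias]!r} and {canonical!r}"
                )
            mapping[alias] = canonical
    return mapping


# ---------------------------------------------------------------------------
# enrichment result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "ID",
    "Description",
    "Fold_Enrichment",
    "occurrence",
    "lowest_p",
    "highest_p",
    "Up_regulated",
    "Down_regulated",
]


def write_result_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an enrichment result table as TSV.

    Gene-list columns are ';'-joined in alphabetical order so that repeated
    runs diff cleanly.
    """
    df = table.copy()
    for col in ("Up_regulated", "Down_regulated"):
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: ";".join(sorted(v)) if not isinstance(v, str) else v
            )
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"result table missing columns: {missing}")
    df[RESULT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_result_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ID": str, "Description": str})
    for col in ("Up_regulated", "Down_regulated"):
        df[col] = df[col].fillna("").map(
            lambda s: sorted(g for g in s.split(";") if g)
        )
    return df
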