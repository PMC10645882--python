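"""Readers and writers for every external artifact of the pipeline.

Formats handled: expression TSV (genes in rows, header = sample ids),
BioMart-style gene annotation TSV, GMT gene-set collections, canonical
ranked edge lists, and GraphML export with node attributes.  All readers
validate strictly and raise :class:`FormatError` with a located message;
all writer/reader pairs round-trip losslessly on valid inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "RankedEdgeList",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_annotation",
    "validate_annotation",
    "normalize_chromosome",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "write_graphml",
]

ANNOTATION_REQUIRED = [
    "gene_id",
    "chromosome",
    "biotype",
    "gc_percent",
    "start_position",
    "end_position",
]

EDGE_COLUMNS = ["gene_a", "gene_b", "score", "abs_score", "rank", "p_value"]


class FormatError(ValueError):
    """Raised when an external file violates its schema."""


def normalize_chromosome(label: str) -> str:
    """Normalize a chromosome label: strip a leading ``chr`` prefix and
    uppercase X/Y/MT.  Anything else is kept verbatim so that unplaced
    scaffolds remain distinct labels (never cis with placed genes)."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.lower() in ("x", "y", "mt", "m"):
        s = "MT" if s.lower() in ("mt", "m") else s.upper()
    return s


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with optional per-sample phenotype.

    ``data`` is a DataFrame indexed by gene id with sample-id columns;
    ``phenotype`` maps each sample id to a label such as ``"AML"`` or
    ``"control"``.
    """

    data: pd.DataFrame
    phenotype: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicated gene ids: {dupes}")
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicated sample ids: {dupes}")
        if self.phenotype is not None:
            self.phenotype = pd.Series(self.phenotype).reindex(cols)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.phenotype)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        pheno = self.phenotype.loc[list(samples)] if self.phenotype is not None else None
        return ExpressionMatrix(self.data[list(samples)], pheno)


@dataclass
class GeneSet:
    set_id: str
    description: str
    members: list[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicated set ids in gene-set collection")
        for s in self.sets:
            if not s.members:
                raise FormatError(f"gene set {s.set_id!r} has no members")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def as_dict(self) -> dict[str, list[str]]:
        return {s.set_id: list(s.members) for s in self.sets}


@dataclass
class RankedEdgeList:
    """Edges sorted by descending absolute co-expression score.

    Canonical form: within each row ``gene_a < gene_b`` lexicographically,
    ranks are contiguous from 1, and rows are ordered by rank.
    """

    edges: pd.DataFrame
    method: str = "unknown"
    n_samples: int | None = None
    estimator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = self.edges
        missing = [c for c in EDGE_COLUMNS if c not in e.columns]
        if missing:
            raise FormatError(f"edge list missing columns: {missing}")
        if len(e):
            bad = e["gene_a"] >= e["gene_b"]
            if bad.any():
                raise FormatError(
                    "edge list not canonical (gene_a < gene_b violated) at rows "
                    f"{e.index[bad][:5].tolist()}"
                )
            ranks = e["rank"].to_numpy()
            if not np.array_equal(ranks, np.arange(1, len(e) + 1)):
                raise FormatError("edge ranks must be contiguous 1..E in order")

    def __len__(self) -> int:
        return len(self.edges)

    def top(self, k: int) -> pd.DataFrame:
        return self.edges.iloc[: int(k)]

    def edge_set(self, k: int | None = None) -> set[tuple[str, str]]:
        e = self.edges if k is None else self.top(k)
        return set(zip(e["gene_a"], e["gene_b"]))


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_matrix(
    path: str | Path, phenotype_map: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Read a genes-in-rows TSV with a header row of sample ids.

    Non-numeric cells and duplicated gene/sample ids are hard errors with a
    located message.  Genes absent from any annotation are permitted here.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated gene ids {dupes}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated sample ids {dupes}")
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        # locate the offending cell for the error report
        for col in df.columns:
            conv = pd.to_numeric(df[col], errors="coerce")
            bad = conv.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy()][0]
                raise FormatError(
                    f"{path}: non-numeric value {df.loc[gene, col]!r} at "
                    f"gene {gene!r}, sample {col!r}"
                ) from None
        raise
    pheno = None
    if phenotype_map is not None:
        pheno = pd.Series({s: phenotype_map.get(s) for s in values.columns})
    return ExpressionMatrix(values, pheno)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data
    # keep integer matrices integer so the round trip is bit-for-bit
    if np.allclose(df.to_numpy(), np.round(df.to_numpy())) and np.isfinite(df.to_numpy()).all():
        df = df.astype(np.int64) if (np.abs(df.to_numpy()) < 2**53).all() else df
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# gene annotation

def validate_annotation(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an annotation table already in memory.

    Adds the derived ``length`` column (end minus start) and normalizes
    chromosome labels.  Returns the table indexed by gene_id.
    """
    missing = [c for c in ANNOTATION_REQUIRED if c not in table.columns]
    if missing:
        raise FormatError(f"annotation missing required columns: {missing}")
    tab = table.copy()
    tab["gene_id"] = tab["gene_id"].astype(str)
    if tab["gene_id"].duplicated().any():
        dupes = tab.loc[tab["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"duplicated gene ids in annotation: {dupes}")
    tab["chromosome"] = tab["chromosome"].map(normalize_chromosome)
    for col in ("gc_percent", "start_position", "end_position"):
        tab[col] = pd.to_numeric(tab[col], errors="raise")
    bad = tab["end_position"] < tab["start_position"]
    if bad.any():
        raise FormatError(
            f"end_position < start_position for genes {tab.loc[bad, 'gene_id'].tolist()}"
        )
    if ((tab["gc_percent"] < 0) | (tab["gc_percent"] > 100)).any():
        raise FormatError("gc_percent outside [0, 100]")
    tab["length"] = tab["end_position"] - tab["start_position"]
    if "parent_gene_id" not in tab.columns:
        tab["parent_gene_id"] = pd.NA
    return tab.set_index("gene_id", drop=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BioMart-style annotation TSV.

    Required columns: gene_id, chromosome, biotype, gc_percent,
    start_position, end_position; parent_gene_id is optional.  Gene length
    is derived as end minus start.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    return validate_annotation(df)


def write_gene_annotation(table: pd.DataFrame, path: str | Path) -> None:
    cols = ANNOTATION_REQUIRED + ["parent_gene_id"]
    out = table.reset_index(drop=True)[[c for c in cols if c in table.columns]]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated id, description,
    then members.  Lines with fewer than 3 fields are a hard error."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            sets.append(GeneSet(fields[0], fields[1], [g for g in fields[2:] if g]))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# edge lists

def write_edge_list(edges: RankedEdgeList | pd.DataFrame, path: str | Path) -> None:
    df = edges.edges if isinstance(edges, RankedEdgeList) else edges
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_edge_list(path: str | Path, method: str = "unknown") -> RankedEdgeList:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: edge list missing columns {missing}")
    df["rank"] = df["rank"].astype(int)
    return RankedEdgeList(df, method=method)


# ---------------------------------------------------------------------------
# GraphML

def write_graphml(
    edges: RankedEdgeList | pd.DataFrame,
    node_attributes: pd.DataFrame | None,
    path: str | Path,
) -> None:
    """Export an edge list as GraphML with optional per-node attributes
    (chromosome, biotype, log2FC class...)."""
    df = edges.edges if isinstance(edges, RankedEdgeList) else edges
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, score=float(row.score), rank=int(row.rank))
    if node_attributes is not None:
        for node in g.nodes:
            if node in node_attributes.index:
                for col, val in node_attributes.loc[node].items():
                    if pd.notna(val):
                        g.nodes[node][str(col)] = val if isinstance(val, (int, float)) else str(val)
    nx.write_graphml(g, path)
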