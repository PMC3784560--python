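"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: GMT gene-set files (one annotation system per file), gene x tissue
expression TSV, interaction-network edge lists, training gene lists, CNV
call tables (either 1-based closed coordinates or the BED 0-based half-open
dialect), BED gene models, and the score / Bayes output tables.  In score
tables, missing values are rendered as "-".

All coordinates are normalised to 1-based closed intervals in memory; BED
input is converted at parse time.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .annotations import AnnotationSystem
from .cohort import CALL_COLUMNS

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_training",
    "write_training",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "read_bed_genes",
    "write_bed_genes",
    "read_cnv_table",
    "write_cnv_table",
    "read_scores",
    "write_scores",
]

MISSING_TOKEN = "-"

_TYPE_ALIASES = {
    "del": "deletion",
    "deletion": "deletion",
    "loss": "deletion",
    "dup": "duplication",
    "duplication": "duplication",
    "gain": "duplication",
}


def read_gmt(
    path: str | Path, name: str | None = None, universe: Iterable[str] | None = None
) -> AnnotationSystem:
    """Parse a GMT file (category id, description, member genes, tab-separated).

    Duplicate symbols within a line are collapsed; the universe defaults to
    the union of all members unless one is supplied.
    """
    path = Path(path)
    categories: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need >= 3 tab-separated fields)"
                )
            cat = fields[0]
            if cat in categories:
                raise ValueError(f"{path}:{lineno}: duplicate category {cat!r}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise ValueError(f"{path}:{lineno}: category {cat!r} has no members")
            categories[cat] = members
    if not categories:
        raise ValueError(f"{path}: empty GMT file")
    return AnnotationSystem.from_categories(
        name or path.stem, categories, universe=universe
    )


def write_gmt(system: AnnotationSystem, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for cat, members in system.categories.items():
            fh.write("\t".join([cat, system.name, *sorted(members)]) + "\n")


def read_training(path: str | Path) -> set[str]:
    """Training gene list: one symbol per line, blanks and '#' comments ignored."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    if not genes:
        raise ValueError(f"{path}: no training genes found")
    return genes


def write_training(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(set(genes))) + "\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column gene symbols, header of tissue labels.

    Empty cells parse as missing values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:3]
        raise ValueError(f"{path}: duplicate gene symbols {dupes}")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 tissue columns")
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Two-column TSV edge list; extra columns are ignored, self-loops and
    duplicate edges are collapsed.  Node universe = union of endpoints."""
    graph = nx.Graph()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: need two tab-separated symbols")
            u, v = fields[0], fields[1]
            if u != v:
                graph.add_edge(u, v)
            else:
                graph.add_node(u)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_bed_genes(path: str | Path) -> pd.DataFrame:
    """BED gene models (chrom, start, end, name) -> 1-based closed DataFrame."""
    rows = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED gene models need 4 columns")
            chrom, start, end, gene = fields[:4]
            start_i, end_i = int(start), int(end)
            if start_i < 0 or end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: invalid BED interval")
            rows.append({"gene": gene, "chrom": chrom, "start": start_i + 1, "end": end_i})
    if not rows:
        raise ValueError(f"{path}: no gene models found")
    return pd.DataFrame(rows)


def write_bed_genes(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.assign(bed_start=genes["start"] - 1)[["chrom", "bed_start", "end", "gene"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cnv_table(path: str | Path, dialect: str = "closed") -> pd.DataFrame:
    """CNV call table with columns subject, cohort, chrom, start, end, type,
    n_probes, mean_log2.

    ``dialect="bed"`` treats coordinates as 0-based half-open and converts;
    ``dialect="closed"`` takes them as 1-based closed.  Types parse
    case-insensitively ("DEL", "loss", "duplication", ...).
    """
    if dialect not in ("closed", "bed"):
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df[list(CALL_COLUMNS)].copy()
    types = df["type"].astype(str).str.lower().map(_TYPE_ALIASES)
    if types.isna().any():
        row = int(np.flatnonzero(types.isna())[0]) + 2  # 1-based incl. header
        raise ValueError(f"{path}: row {row}: unknown call type {df['type'].iloc[row - 2]!r}")
    df["type"] = types
    if dialect == "bed":
        df["start"] = df["start"] + 1
    bad = (df["start"] < 1) | (df["end"] < df["start"])
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}: row {row}: negative or inverted coordinates")
    if (df["n_probes"] < 1).any():
        row = int(np.flatnonzero(df["n_probes"] < 1)[0]) + 2
        raise ValueError(f"{path}: row {row}: n_probes must be >= 1")
    return df


def write_cnv_table(calls: pd.DataFrame, path: str | Path) -> None:
    calls[list(CALL_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    """Score table TSV with '-' for missing values."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN])


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="gene")
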