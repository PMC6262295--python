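"""Readers and writers for the pipeline's plain-text interchange formats.

Expression tables, ortholog maps, interaction tables and pathway edge lists
are TSV; gene-set collections are standard GMT (name, description, members,
tab-separated, one set per line). Networks export as GraphML and edge-list
TSV.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .spia import PathwayGraph


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV; first column is the gene id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_ortholog_map(path) -> pd.DataFrame:
    """3-column TSV (axolotl_id, human_symbol, rat_id); empty field = unmapped."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["axolotl_id", "human_symbol", "rat_id"]
    if list(table.columns) != expected:
        raise ValueError(f"ortholog map must have columns {expected}, got {list(table.columns)}")
    return table


def write_ortholog_map(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_interactions(path) -> pd.DataFrame:
    """(node_a, node_b, score) TSV with scores in [0, 1]."""
    table = pd.read_csv(path, sep="\t")
    if not {"node_a", "node_b", "score"} <= set(table.columns):
        raise ValueError("interaction table needs columns node_a, node_b, score")
    if ((table["score"] < 0) | (table["score"] > 1)).any():
        raise ValueError("interaction scores must lie in [0, 1]")
    return table


def write_interactions(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gmt(path, background=None, kind: str = "go_like") -> GeneSetCollection:
    """Read a GMT file; background defaults to the union of all members."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, _desc, *members = parts
        sets[name] = {m for m in members if m}
    if background is None:
        background = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, background=set(background), kind=kind)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description] + sorted(members))
        for name, members in sorted(collection.sets.items())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_pathway(path, name: str | None = None) -> PathwayGraph:
    """Signed edge-list TSV (src, dst, sign) -> PathwayGraph."""
    table = pd.read_csv(path, sep="\t", dtype={"src": str, "dst": str, "sign": int})
    if not {"src", "dst", "sign"} <= set(table.columns):
        raise ValueError("pathway edge list needs columns src, dst, sign")
    if not table["sign"].isin([1, -1]).all():
        raise ValueError("pathway edge signs must be +1 or -1")
    genes = sorted(set(table["src"]) | set(table["dst"]))
    idx = {g: i for i, g in enumerate(genes)}
    beta = np.zeros((len(genes), len(genes)))
    for src, dst, sign in table[["src", "dst", "sign"]].itertuples(index=False):
        beta[idx[dst], idx[src]] = sign  # influence of src on dst
    return PathwayGraph(name=name or Path(path).stem, genes=genes, beta=beta)


def write_pathway(graph: PathwayGraph, path) -> None:
    rows = []
    for i, dst in enumerate(graph.genes):
        for j, src in enumerate(graph.genes):
            if graph.beta[i, j] != 0:
                rows.append({"src": src, "dst": dst, "sign": int(graph.beta[i, j])})
    pd.DataFrame(rows, columns=["src", "dst", "sign"]).to_csv(path, sep="\t", index=False)


def write_network(g: nx.Graph, basepath) -> None:
    """Export a network as GraphML and as an edge-list TSV."""
    base = Path(basepath)
    nx.write_graphml(g, base.with_suffix(".graphml"))
    from .network import to_edge_table

    to_edge_table(g).to_csv(base.with_suffix(".tsv"), sep="\t", index=False)
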