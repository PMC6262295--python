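"""Protein-interaction subnetworks, centralities and fold-change correlation.

Interaction tables are StringDB-like undirected weighted edge lists with
scores in [0, 1]; subnetworks are induced on gene classes within a broad
score band (default 0.15-0.999) and isolated nodes are dropped. Centralities
(betweenness, degree, local clustering) are computed on the unweighted
topology; a score-weighted mode (distance = 1 - score) is available.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

SCORE_MIN = 0.15
SCORE_MAX = 0.999


def from_table(table: pd.DataFrame) -> nx.Graph:
    """Undirected weighted graph from a (node_a, node_b, score) table."""
    g = nx.Graph()
    for a, b, s in table[["node_a", "node_b", "score"]].itertuples(index=False):
        if a == b:
            continue
        g.add_edge(a, b, score=float(s))
    return g


def induce(
    network: pd.DataFrame | nx.Graph,
    gene_set,
    *,
    score_min: float = SCORE_MIN,
    score_max: float = SCORE_MAX,
) -> nx.Graph:
    """Subgraph on ``gene_set`` keeping edges inside the score band.

    Nodes left with degree 0 are removed (count logged); an empty result is
    returned as an empty graph with a warning, not an error.
    """
    if not (0.0 <= score_min <= score_max <= 1.0):
        raise ValueError("score band must satisfy 0 <= min <= max <= 1")
    g = from_table(network) if isinstance(network, pd.DataFrame) else network
    genes = set(gene_set)
    sub = nx.Graph()
    for a, b, data in g.edges(data=True):
        if a in genes and b in genes and score_min <= data["score"] <= score_max:
            sub.add_edge(a, b, score=data["score"])
    dropped = len(genes & set(g.nodes)) - sub.number_of_nodes()
    if dropped > 0:
        log.info("induce: dropped %d isolated nodes", dropped)
    if sub.number_of_nodes() == 0:
        log.warning("induce: empty network after filtering")
    return sub


def centralities(network: nx.Graph, *, weighted: bool = False) -> pd.DataFrame:
    """Betweenness, degree centrality and clustering coefficient per node.

    Betweenness is normalised by (n-1)(n-2)/2, degree by n-1; clustering is
    the local coefficient. ``weighted=True`` uses distance = 1 - score for
    shortest paths (scores are association probabilities, not costs).
    """
    if network.number_of_nodes() == 0:
        raise ValueError("centralities of an empty network")
    if weighted:
        for _, _, d in network.edges(data=True):
            d["distance"] = 1.0 - d["score"]
        betw = nx.betweenness_centrality(network, normalized=True, weight="distance")
    else:
        betw = nx.betweenness_centrality(network, normalized=True)
    deg = nx.degree_centrality(network)
    clust = nx.clustering(network)
    return pd.DataFrame(
        {
            "node": list(network.nodes),
            "betweenness": [betw[v] for v in network.nodes],
            "degree_centrality": [deg[v] for v in network.nodes],
            "clustering": [clust[v] for v in network.nodes],
        }
    ).set_index("node", drop=False)


def centrality_fc_correlation(
    records: pd.DataFrame,
    *,
    measures=("betweenness", "degree_centrality", "clustering"),
    fc_column: str = "avg_fc",
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlation of |average log fold-change| with each centrality measure.

    ``records`` carries one stratum (one species, one direction); callers run
    it per stratum to mirror the per-panel analysis. Zero-variance input is
    flagged as undefined rather than returned as NaN.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    rows = []
    fc = records[fc_column].abs().to_numpy(dtype=float)
    for m in measures:
        x = records[m].to_numpy(dtype=float)
        row = {"measure": m, "n": len(records), "method": method}
        if len(records) < 3 or not (np.isfinite(x).all() and np.isfinite(fc).all()):
            row.update(coefficient=None, p=None, undefined=True)
        elif np.ptp(x) == 0.0 or np.ptp(fc) == 0.0:
            row.update(coefficient=None, p=None, undefined=True)
        else:
            if method == "spearman":
                r, p = stats.spearmanr(x, fc)
            else:
                r, p = stats.pearsonr(x, fc)
            row.update(coefficient=float(r), p=float(p), undefined=False)
        rows.append(row)
    return pd.DataFrame(rows, columns=["measure", "n", "method", "coefficient", "p", "undefined"])


def fuse_tf_network(
    tf: str,
    targets,
    network: nx.Graph,
    *,
    score_min: float = SCORE_MIN,
    score_max: float = SCORE_MAX,
) -> tuple[nx.Graph, dict]:
    """Fuse a TF's predicted targets with its first neighbors in a network.

    Node set = {tf} u (targets n network nodes) u firstNeighbors(tf), edges
    induced from ``network`` within the score band. Overlapping genes are
    counted once; the sizes of both sources and their overlap are reported so
    any counting convention can be audited.
    """
    nodes = set(network.nodes)
    targets_in = set(targets) & nodes
    if tf in nodes:
        neighbors = set(network.neighbors(tf))
        seed = {tf} | targets_in | neighbors
    else:
        log.warning("fuse_tf_network: %s absent from network, using targets only", tf)
        neighbors = set()
        seed = set(targets_in)
    fused = induce(network, seed, score_min=score_min, score_max=score_max)
    sizes = {
        "tf_in_network": tf in nodes,
        "n_targets_in_network": len(targets_in),
        "n_first_neighbors": len(neighbors),
        "n_overlap": len(targets_in & neighbors),
        "n_union": len(seed),
        "n_fused_nodes": fused.number_of_nodes(),
        "n_fused_edges": fused.number_of_edges(),
    }
    return fused, sizes


def extract_term_subnetwork(network: nx.Graph, term_genes) -> nx.Graph:
    """Induced subgraph on a term's member genes, isolated nodes dropped."""
    return induce(network, set(term_genes), score_min=0.0, score_max=1.0)


def to_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [(a, b, d.get("score", np.nan)) for a, b, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
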