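"""Two-evidence signaling pathway impact analysis.

For each signed pathway graph the observed log2 fold-changes of its
differentially expressed genes (dE) are propagated through the topology:

    PF(g_i) = dE(g_i) + sum_j B_ij PF(g_j),   B_ij = beta_ij / outdegree(g_j)

solved as the linear system (I - B) PF = dE; the net accumulated
perturbation is tA = sum_i (PF_i - dE_i). Two p-values are combined:
pNDE, the hypergeometric overrepresentation of DE genes on the pathway, and
pPERT, a bootstrap tail probability of |tA| under random placement of the
observed fold-changes, via pG = c - c ln c with c = pNDE * pPERT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve

from .diffexpr import bh_adjust
from .enrichment import hypergeom_upper

log = logging.getLogger(__name__)

COND_LIMIT = 1e10  # (I - B) condition number above which a pathway is unsolvable


@dataclass
class PathwayGraph:
    """Signed directed pathway: beta[i, j] in {+1, -1, 0} is j's influence on i."""

    name: str
    genes: list
    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        n = len(self.genes)
        if self.beta.shape != (n, n):
            raise ValueError("beta must be square over the gene list")
        if np.any(np.diag(self.beta) != 0):
            raise ValueError("beta diagonal must be zero (no self-influence)")

    def normalized(self) -> np.ndarray:
        """B = beta with each column divided by its source gene's outdegree."""
        out = np.abs(self.beta).sum(axis=0)  # outdegree of column gene j
        b = self.beta.copy()
        nz = out > 0
        b[:, nz] = b[:, nz] / out[nz]
        return b


class SingularPathwayError(ValueError):
    """(I - B) is numerically singular; the pathway cannot be propagated."""


def _system(graph: PathwayGraph) -> np.ndarray:
    m = np.eye(len(graph.genes)) - graph.normalized()
    if np.linalg.cond(m) > COND_LIMIT:
        raise SingularPathwayError(graph.name)
    return m

def perturbation(graph: PathwayGraph, de_logfc: dict) -> tuple[np.ndarray, float]:
    """Propagate fold-changes through the pathway; returns (PF per gene, tA).

    ``de_logfc`` maps gene -> log2 fold-change for DE genes; pathway genes
    absent from it contribute dE = 0.
    """
    de = np.array([float(de_logfc.get(g, 0.0)) for g in graph.genes])
    m = _system(graph)
    pf = np.linalg.solve(m, de)
    ta = float((pf - de).sum())
    return pf, ta


def p_nde(pathway_genes, de_genes, background) -> float:
    """Hypergeometric upper tail of the DE-gene count on the pathway."""
    background = set(background)
    path = set(pathway_genes) & background
    de = set(de_genes) & background
    k = len(path & de)
    return hypergeom_upper(k, len(path), len(de), len(background))


def p_pert(
    graph: PathwayGraph,
    ta_obs: float,
    de_logfc_pool,
    n_de_on_pathway: int,
    *,
    n_boot: int = 2000,
    rng=None,
) -> float:
    """Bootstrap tail probability of the observed net perturbation.

    The null reassigns ``n_de_on_pathway`` fold-changes, drawn with
    replacement from the observed DE pool, to random pathway genes and
    recomputes tA. The p-value is two-sided around the null median with
    add-one smoothing: (1 + #{|tA0 - med| >= |tA - med|}) / (1 + n_boot).
    """
    pool = np.asarray(list(de_logfc_pool), dtype=float)
    n_genes = len(graph.genes)
    if n_de_on_pathway == 0 or pool.size == 0:
        return 1.0
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = _system(graph)
    lu = lu_factor(m)
    # tA is linear in dE, so all bootstrap systems solve in one factorised call
    de_null = np.zeros((n_genes, n_boot))
    idx = np.argsort(rng.random((n_boot, n_genes)), axis=1)[:, :n_de_on_pathway]
    vals = rng.choice(pool, size=(n_boot, n_de_on_pathway), replace=True)
    de_null[idx.T, np.arange(n_boot)[None, :]] = vals.T
    pf_null = lu_solve(lu, de_null)
    ta_null = (pf_null - de_null).sum(axis=0)
    med = float(np.median(ta_null))
    exceed = int(np.sum(np.abs(ta_null - med) >= abs(ta_obs - med)))
    return (1 + exceed) / (1 + n_boot)


def combine(p_nde_val: float, p_pert_val: float) -> float:
    """Fisher-product combination pG = c - c ln c, c = pNDE * pPERT."""
    for p in (p_nde_val, p_pert_val):
        if not (0.0 < p <= 1.0):
            raise ValueError("evidence p-values must lie in (0, 1]")
    c = p_nde_val * p_pert_val
    return float(c - c * np.log(c)) if c < 1.0 else 1.0


@dataclass
class SpiaResult:
    pathway: str
    t_a: float
    p_nde: float
    p_pert: float
    p_g: float
    p_g_adj: float = np.nan
    status: str = "none"
    n_de_on_pathway: int = 0
    skipped: bool = False
    skip_reason: str = ""


def spia_run(
    pathways: list[PathwayGraph],
    de_logfc: dict,
    background,
    *,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the two-evidence analysis over a pathway collection.

    ``de_logfc`` maps DE gene -> log2 fold-change (the DE table); the
    background is the tested universe. One row per pathway with tA, pNDE,
    pPERT, pG and BH-adjusted pG; numerically singular pathways are flagged
    and excluded from correction. Status is activated/inhibited by sign(tA)
    when pG_adj <= alpha.
    """
    rng = np.random.default_rng(seed)
    de_genes = set(de_logfc)
    pool = [de_logfc[g] for g in sorted(de_genes)]
    rows = []
    for graph in pathways:
        on_path = sorted(set(graph.genes) & de_genes)
        try:
            _, ta = perturbation(graph, de_logfc)
        except SingularPathwayError:
            log.warning("spia: pathway %s singular, skipped", graph.name)
            rows.append(SpiaResult(graph.name, np.nan, np.nan, np.nan, np.nan,
                                   skipped=True, skip_reason="singular system"))
            continue
        pnde = p_nde(graph.genes, de_genes, background)
        ppert = p_pert(graph, ta, pool, len(on_path), n_boot=n_boot, rng=rng)
        rows.append(SpiaResult(graph.name, ta, pnde, ppert, combine(pnde, ppert),
                               n_de_on_pathway=len(on_path)))
    table = pd.DataFrame([vars(r) for r in rows])
    if len(table):
        ok = ~table["skipped"]
        if ok.any():
            table.loc[ok, "p_g_adj"] = bh_adjust(table.loc[ok, "p_g"].to_numpy())
            sig = ok & (table["p_g_adj"] <= alpha)
            table.loc[sig & (table["t_a"] > 0), "status"] = "activated"
            table.loc[sig & (table["t_a"] < 0), "status"] = "inhibited"
        table = table.sort_values(["p_g_adj", "pathway"], kind="mergesort").reset_index(drop=True)
    return table


def evidence_plot_data(
    pathway: PathwayGraph,
    quadrant_table: pd.DataFrame,
    rat_consistent,
    ax_consistent,
) -> pd.DataFrame:
    """Per-gene average fold-changes on a pathway, flagged by species evidence.

    One row per pathway gene found in the shared-gene table, with each
    species' average fold-change and whether the gene sits in the rat-only,
    axolotl-only or both consistent sets (the scatter behind the two-species
    pathway comparison).
    """
    rat_set, ax_set = set(rat_consistent), set(ax_consistent)
    rows = []
    for g in pathway.genes:
        in_rat, in_ax = g in rat_set, g in ax_set
        if not (in_rat or in_ax):
            continue
        row = {"gene": g,
               "avg_rat_fc": float(quadrant_table.loc[g, "avg_rat_fc"]) if g in quadrant_table.index else np.nan,
               "avg_ax_fc": float(quadrant_table.loc[g, "avg_ax_fc"]) if g in quadrant_table.index else np.nan,
               "evidence": "both" if in_rat and in_ax else ("rat" if in_rat else "axolotl")}
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", "avg_rat_fc", "avg_ax_fc", "evidence"])
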