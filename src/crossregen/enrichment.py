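"""Hypergeometric overrepresentation of gene-set collections.

Covers both GO-style collections (flat sets combining the three ontology
categories; parent-term propagation must be done upstream) and
transcription-factor-target collections consumed as precomputed GMT sets.
The upper-tail p is accumulated in log space for numerical stability and
BH-corrected across the tested terms of a collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .diffexpr import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over a defined background universe."""

    sets: dict[str, set]
    background: set
    kind: str = "go_like"  # or "tft_like"

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            extra = set(members) - self.background
            if extra:
                raise ValueError(
                    f"gene set {name!r} has {len(extra)} members outside the background"
                )


def restrict_to_background(
    collection: GeneSetCollection, background
) -> tuple[GeneSetCollection, int]:
    """Intersect every set with a new background universe.

    Members outside the background are dropped (count returned); sets left
    empty are removed with a log line. This is how externally supplied GMT
    collections are reconciled with the array/ortholog universe.
    """
    background = set(background)
    sets = {}
    dropped = 0
    for name, members in collection.sets.items():
        kept = members & background
        dropped += len(members) - len(kept)
        if kept:
            sets[name] = kept
        else:
            log.info("restrict_to_background: set %s empty after filtering, removed", name)
    return GeneSetCollection(sets=sets, background=background, kind=collection.kind), dropped


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Log-space accumulation of the pmf over the upper tail; k = 0 gives 1.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    logp = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def enrich(
    query,
    collection: GeneSetCollection,
    *,
    min_hits: int = 1,
) -> pd.DataFrame:
    """Overrepresentation of every collection term in a query gene list.

    Query genes outside the background are dropped (logged). Terms with at
    least ``min_hits`` query hits are tested; BH correction spans the tested
    terms. Ranked by adjusted p, then enrichment ratio (descending), then
    term name.
    """
    query = set(query)
    outside = query - collection.background
    if outside:
        log.info("enrich: dropped %d query genes outside the background", len(outside))
        query -= outside
    N = len(collection.background)
    n = len(query)
    cols = ["term", "k", "K", "n", "N", "p_raw", "p_adj", "ratio"]
    if n == 0:
        log.warning("enrich: empty query after background filtering")
        return pd.DataFrame(columns=cols)
    rows = []
    for term, members in collection.sets.items():
        k = len(query & members)
        if k < min_hits:
            continue
        K = len(members)
        p = hypergeom_upper(k, K, n, N)
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "p_raw": p, "ratio": (k / n) / (K / N)})
    if not rows:
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    table = table.sort_values(
        ["p_adj", "ratio", "term"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table[cols]


def tft_rank(
    gene_classes: dict[str, set],
    tft_collection: GeneSetCollection,
) -> dict[str, pd.DataFrame]:
    """Per-class transcription-factor ranking against a TFT collection.

    For each class of genes (e.g. a quadrant group or direction list) every
    TF's target set is tested for overrepresentation; TFs are ranked by
    adjusted p with ties broken by larger hit count then name. The top row is
    the class's candidate regulator.
    """
    usable = {}
    for tf, targets in tft_collection.sets.items():
        inter = targets & tft_collection.background
        if not inter:
            log.info("tft_rank: TF %s has no targets in background, skipped", tf)
            continue
        usable[tf] = inter
    coll = GeneSetCollection(usable, tft_collection.background, kind="tft_like") if usable else tft_collection
    out = {}
    for label, genes in gene_classes.items():
        table = enrich(genes, coll)
        if len(table):
            table = table.sort_values(
                ["p_adj", "k", "term"], ascending=[True, False, True], kind="mergesort"
            ).reset_index(drop=True)
            table = table.rename(columns={"term": "tf", "k": "hits"})
        else:
            table = pd.DataFrame(columns=["tf", "hits", "K", "n", "N", "p_raw", "p_adj", "ratio"])
        out[label] = table
    return out
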