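"""Ortholog-anchored cross-species intersection and quadrant classification.

Both species' per-timepoint DE tables are re-keyed to a shared human-symbol
anchor, filtered for temporal consistency (significant with the same sign at
every timepoint), intersected across species and split into four quadrant
groups by the sign of the average log fold-change in each species:

    group 1  axolotl up,   rat down
    group 2  up in both
    group 3  down in both
    group 4  axolotl down, rat up
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GROUP_LABELS = {
    1: "axolotl-up / rat-down",
    2: "up in both",
    3: "down in both",
    4: "axolotl-down / rat-up",
}


@dataclass
class OrthologMap:
    """Triples (axolotl_id, human_symbol, rat_id); empty field = unmapped."""

    table: pd.DataFrame  # columns: axolotl_id, human_symbol, rat_id

    def species_map(self, species: str) -> pd.DataFrame:
        col = f"{species}_id"
        if col not in self.table.columns:
            raise KeyError(f"species {species!r} not in ortholog map")
        sub = self.table[[col, "human_symbol"]].copy()
        sub = sub[(sub[col] != "") & sub[col].notna()
                  & (sub["human_symbol"] != "") & sub["human_symbol"].notna()]
        return sub.rename(columns={col: "gene_id"})


def map_to_anchor(
    de_records: pd.DataFrame,
    ortholog_map: OrthologMap,
    species: str,
) -> tuple[pd.DataFrame, int]:
    """Re-key one stratum's DE table by human symbol.

    Unmapped genes are dropped (count returned). When several source ids map
    to one human symbol, the record with the smallest adjusted p is kept.
    Returns ``(records keyed by human_symbol, n_dropped_unmapped)``.
    """
    smap = ortholog_map.species_map(species)
    merged = de_records.reset_index(drop=True).merge(smap, on="gene_id", how="left")
    unmapped = int(merged["human_symbol"].isna().sum())
    mapped = merged.dropna(subset=["human_symbol"])
    # many-to-one collapse: best (smallest) adjusted p per human symbol
    mapped = mapped.sort_values(["p_adj", "gene_id"], kind="mergesort")
    mapped = mapped.drop_duplicates(subset="human_symbol", keep="first")
    dup = mapped["human_symbol"].duplicated()
    if dup.any():
        raise ValueError("ambiguous ortholog mapping after collapse")
    if unmapped:
        log.info("map_to_anchor[%s]: dropped %d unmapped genes", species, unmapped)
    return mapped.set_index("human_symbol", drop=False), unmapped


def consistent_set(per_timepoint: dict[str, pd.DataFrame]) -> pd.Series:
    """Genes significant with the same direction at every timepoint.

    ``per_timepoint`` maps timepoint label -> anchored DE table (indexed by
    human symbol, with ``significant`` and ``direction`` columns). Returns a
    Series gene -> direction (+1 / -1).
    """
    if not per_timepoint:
        raise ValueError("no timepoints supplied")
    directions: pd.DataFrame | None = None
    for tp, rec in per_timepoint.items():
        sig = rec[rec["significant"]]
        col = sig["direction"].rename(tp)
        directions = col.to_frame() if directions is None else directions.join(col, how="inner")
    if directions is None or directions.empty:
        return pd.Series(dtype=int)
    same_sign = directions.nunique(axis=1) == 1
    consistent = directions.loc[same_sign].iloc[:, 0].astype(int)
    consistent.name = "direction"
    return consistent.sort_index()


def classify_quadrants(
    rat_anchored: dict[str, pd.DataFrame],
    ax_anchored: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Shared-gene quadrant table over the cross-species consistent intersection.

    One row per human symbol present in both species' consistent sets, with
    per-timepoint log2 fold-changes for both species, the per-species average
    fold-change and the quadrant group (1-4).
    """
    rat_cons = consistent_set(rat_anchored)
    ax_cons = consistent_set(ax_anchored)
    shared = sorted(set(rat_cons.index) & set(ax_cons.index))
    timepoints = list(rat_anchored)
    rows = []
    for symbol in shared:
        row: dict = {"human_symbol": symbol}
        for tp in timepoints:
            row[f"rat_fc_{tp}"] = float(rat_anchored[tp].loc[symbol, "log2_fc"])
        for tp in ax_anchored:
            row[f"ax_fc_{tp}"] = float(ax_anchored[tp].loc[symbol, "log2_fc"])
        avg_rat = float(np.mean([row[f"rat_fc_{tp}"] for tp in timepoints]))
        avg_ax = float(np.mean([row[f"ax_fc_{tp}"] for tp in ax_anchored]))
        if avg_rat == 0.0 or avg_ax == 0.0:
            raise ValueError(
                f"{symbol}: zero average fold-change should be impossible for "
                "genes passing the significance and fold-change filters"
            )
        if avg_ax > 0:
            group = 1 if avg_rat < 0 else 2
        else:
            group = 3 if avg_rat < 0 else 4
        row["avg_rat_fc"] = avg_rat
        row["avg_ax_fc"] = avg_ax
        row["group"] = group
        rows.append(row)
    cols = (
        ["human_symbol"]
        + [f"rat_fc_{tp}" for tp in timepoints]
        + [f"ax_fc_{tp}" for tp in ax_anchored]
        + ["avg_rat_fc", "avg_ax_fc", "group"]
    )
    table = pd.DataFrame(rows, columns=cols)
    return table.set_index("human_symbol", drop=False)


@dataclass
class GroupSummary:
    counts: dict[int, int]
    pct_ax_down: float | None  # (n3+n4)/total
    pct_ax_up: float | None  # (n1+n2)/total
    pct_ax_down_rat_up: float | None  # n4/(n3+n4)
    pct_ax_up_rat_down: float | None  # n1/(n1+n2)
    undefined: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict:
        out = {f"n{g}": self.counts[g] for g in (1, 2, 3, 4)}
        out["total"] = self.total
        for name in ("pct_ax_down", "pct_ax_up", "pct_ax_down_rat_up", "pct_ax_up_rat_down"):
            val = getattr(self, name)
            out[name] = None if val is None else round(val, 6)
            out[f"{name}_display"] = None if val is None else round(val)
        out["undefined"] = list(self.undefined)
        return out


def group_summary(table: pd.DataFrame) -> GroupSummary:
    """Counts and percentages per quadrant group.

    Percentages are on a 0-100 scale; an undefined ratio (empty denominator)
    is reported as None and flagged rather than propagated as NaN.
    """
    counts = {g: int((table["group"] == g).sum()) for g in (1, 2, 3, 4)} if len(table) else {g: 0 for g in (1, 2, 3, 4)}
    total = sum(counts.values())
    undefined = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return 100.0 * num / den

    return GroupSummary(
        counts=counts,
        pct_ax_down=ratio(counts[3] + counts[4], total, "pct_ax_down"),
        pct_ax_up=ratio(counts[1] + counts[2], total, "pct_ax_up"),
        pct_ax_down_rat_up=ratio(counts[4], counts[3] + counts[4], "pct_ax_down_rat_up"),
        pct_ax_up_rat_down=ratio(counts[1], counts[1] + counts[2], "pct_ax_up_rat_down"),
        undefined=undefined,
    )


def top_genes(table: pd.DataFrame, group: int, n: int, per_species: str) -> pd.DataFrame:
    """Top-``n`` genes of one quadrant group by |average log fold-change|.

    Ranked in the named species (``rat`` or ``ax``), descending; ties broken
    lexicographically by symbol so the ranking is deterministic.
    """
    col = {"rat": "avg_rat_fc", "ax": "avg_ax_fc", "axolotl": "avg_ax_fc"}[per_species]
    sub = table[table["group"] == group].reset_index(drop=True)
    sub["_abs"] = sub[col].abs()
    sub = sub.sort_values(["_abs", "human_symbol"], ascending=[False, True], kind="mergesort")
    return sub.drop(columns="_abs").head(n)


def shared_per_timepoint(
    rat_anchored: dict[str, pd.DataFrame],
    ax_anchored: dict[str, pd.DataFrame],
    direction: int,
    gene_filter: set | None = None,
) -> dict[str, set]:
    """Per-timepoint shared genes with a given direction, no cross-timepoint filter.

    For each timepoint independently: genes significant in both species with
    ``direction``, optionally restricted to an annotation set (e.g. matrix
    genes). Mirrors the day-by-day shared-gene counts rather than the
    consistency-filtered intersection.
    """
    out: dict[str, set] = {}
    for tp in rat_anchored:
        rat = rat_anchored[tp]
        ax = ax_anchored[tp]
        rat_sel = set(rat.index[rat["significant"] & (rat["direction"] == direction)])
        ax_sel = set(ax.index[ax["significant"] & (ax["direction"] == direction)])
        shared = rat_sel & ax_sel
        if gene_filter is not None:
            shared &= set(gene_filter)
        out[tp] = shared
    return out


def parallel_coords(table: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Tidy (gene, species, timepoint, log2_fc) export for trajectory plots."""
    if genes is not None:
        table = table.loc[table.index.intersection(list(genes))]
    rows = []
    for symbol, rec in table.iterrows():
        for col in table.columns:
            for species, prefix in (("rat", "rat_fc_"), ("axolotl", "ax_fc_")):
                if col.startswith(prefix):
                    rows.append(
                        {
                            "gene": symbol,
                            "species": species,
                            "timepoint": col[len(prefix):],
                            "log2_fc": float(rec[col]),
                        }
                    )
    return pd.DataFrame(rows, columns=["gene", "species", "timepoint", "log2_fc"])
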