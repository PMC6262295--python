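"""Interaction subnetworks, centrality/fold-change correlation, TF fusion.

Induces score-banded (0.15-0.999) subnetworks on each quadrant group,
computes betweenness / degree centrality / clustering coefficient, and
correlates each measure with |average log2 fold-change| per species and
direction stratum. Finally fuses the top rat-up TF's predicted targets
with its first neighbors in the rat-upregulated network.
"""

import pandas as pd
from pathlib import Path

from crossregen import enrichment, io, network
from crossregen.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
CONFIG = ROOT / "results" / "synthetic_inputs" / "config.yaml"
QUADRANTS = ROOT / "results" / "intersection" / "shared_genes_quadrants.tsv"
TFT_RAT_UP = ROOT / "results" / "enrichment" / "tft_rat_up.tsv"
OUT = ROOT / "results" / "networks"


def main():
    config = PipelineConfig.from_yaml(CONFIG)
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(QUADRANTS, sep="\t").set_index("human_symbol", drop=False)
    interactions = io.read_interactions(config.interactions)
    band = dict(score_min=config.score_min, score_max=config.score_max)

    groups = {f"group{g}": set(table.index[table["group"] == g]) for g in (1, 2, 3, 4)}
    for label, genes in groups.items():
        sub = network.induce(interactions, genes, **band)
        io.write_network(sub, OUT / f"network_{label}")
        print(f"{label}: {sub.number_of_nodes()} connected nodes, "
              f"{sub.number_of_edges()} edges")

    strata = {
        ("rat", "up"): (groups["group2"] | groups["group4"], "avg_rat_fc"),
        ("rat", "down"): (groups["group1"] | groups["group3"], "avg_rat_fc"),
        ("axolotl", "up"): (groups["group1"] | groups["group2"], "avg_ax_fc"),
        ("axolotl", "down"): (groups["group3"] | groups["group4"], "avg_ax_fc"),
    }
    rows = []
    for (sp, direction), (genes, fc_col) in strata.items():
        sub = network.induce(interactions, genes, **band)
        if sub.number_of_nodes() == 0:
            continue
        cents = network.centralities(sub)
        cents["avg_fc"] = table.loc[cents.index, fc_col]
        cents.reset_index(drop=True).to_csv(OUT / f"centrality_{sp}_{direction}.tsv",
                                            sep="\t", index=False)
        corr = network.centrality_fc_correlation(cents, method=config.correlation)
        corr.insert(0, "species", sp)
        corr.insert(1, "direction", direction)
        rows.append(corr)
    corr_table = pd.concat(rows, ignore_index=True)
    corr_table.to_csv(OUT / "centrality_fc_correlation.tsv", sep="\t", index=False)
    print("\ncentrality vs |avg fc| correlations "
          f"({config.correlation}):")
    print(corr_table.to_string(index=False))

    top_tf = pd.read_csv(TFT_RAT_UP, sep="\t").iloc[0]["tf"]
    tft = io.read_gmt(config.tft_gmt, kind="tft_like")
    rat_up_net = network.induce(interactions, strata[("rat", "up")][0], **band)
    fused, sizes = network.fuse_tf_network(top_tf, tft.sets.get(top_tf, set()),
                                           rat_up_net, **band)
    io.write_network(fused, OUT / "fused_tf_network")
    print(f"\nfused {top_tf} network: {sizes}")


if __name__ == "__main__":
    main()
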