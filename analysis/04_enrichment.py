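"""Gene-set and TF-target overrepresentation of the quadrant groups.

Hypergeometric tests against the GO-like collection (per quadrant group)
and the TF-target collection (per group and per direction class), both
BH-corrected. On the synthetic bundle the planted matrix-like term should
top group 2 and the planted TF should top the rat-upregulated class.
"""

import pandas as pd
from pathlib import Path

from crossregen import enrichment, io
from crossregen.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
CONFIG = ROOT / "results" / "synthetic_inputs" / "config.yaml"
QUADRANTS = ROOT / "results" / "intersection" / "shared_genes_quadrants.tsv"
OUT = ROOT / "results" / "enrichment"


def main():
    config = PipelineConfig.from_yaml(CONFIG)
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(QUADRANTS, sep="\t").set_index("human_symbol", drop=False)
    universe = set(io.read_ortholog_map(config.ortholog_map)["human_symbol"])
    go, _ = enrichment.restrict_to_background(
        io.read_gmt(config.go_gmt, kind="go_like"), universe)
    tft, _ = enrichment.restrict_to_background(
        io.read_gmt(config.tft_gmt, kind="tft_like"), universe)

    groups = {f"group{g}": set(table.index[table["group"] == g]) for g in (1, 2, 3, 4)}
    for label, genes in groups.items():
        res = enrichment.enrich(genes, go)
        res.to_csv(OUT / f"go_{label}.tsv", sep="\t", index=False)
        top = res.iloc[0] if len(res) else None
        print(f"{label}: top term "
              + (f"{top['term']} (k={top['k']}/{top['K']}, p_adj={top['p_adj']:.2e})"
                 if top is not None else "none"))

    classes = dict(groups,
                   rat_up=groups["group2"] | groups["group4"],
                   rat_down=groups["group1"] | groups["group3"],
                   ax_up=groups["group1"] | groups["group2"],
                   ax_down=groups["group3"] | groups["group4"])
    rankings = enrichment.tft_rank(classes, tft)
    for label, res in rankings.items():
        res.to_csv(OUT / f"tft_{label}.tsv", sep="\t", index=False)
    best = rankings["rat_up"].iloc[0]
    print(f"\nrat-upregulated class: top TF {best['tf']} "
          f"({best['hits']} hits, p_adj={best['p_adj']:.2e})")


if __name__ == "__main__":
    main()
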