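"""Ortholog-anchored cross-species intersection and quadrant classification.

Re-keys both species' DE tables to human symbols, keeps genes significant
with a stable sign at all three timepoints in both species, and splits the
shared set into the four quadrant groups. Prints the group counts and the
derived percentages, and writes the shared-gene table, top-gene lists,
per-timepoint shared sets and the parallel-coordinates export.
"""

import json
from pathlib import Path

from crossregen import diffexpr, intersect, io
from crossregen.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
CONFIG = ROOT / "results" / "synthetic_inputs" / "config.yaml"
OUT = ROOT / "results" / "intersection"


def main():
    config = PipelineConfig.from_yaml(CONFIG)
    OUT.mkdir(parents=True, exist_ok=True)
    omap = intersect.OrthologMap(io.read_ortholog_map(config.ortholog_map))
    kw = dict(alpha=config.alpha, fc_cutoff=config.fc_cutoff, fc_scale=config.fc_scale)
    anchored = {}
    for species, path in (("rat", config.rat_expression),
                          ("axolotl", config.axolotl_expression)):
        expr = io.read_expression(path)
        strata = diffexpr.de_all_strata(expr, species, config.timepoints, **kw)
        anchored[species] = {}
        for tp, table in strata.items():
            anchored[species][tp], dropped = intersect.map_to_anchor(table, omap, species)
            print(f"{species} {tp}: dropped {dropped} genes without ortholog anchor")

    table = intersect.classify_quadrants(anchored["rat"], anchored["axolotl"])
    table.reset_index(drop=True).to_csv(OUT / "shared_genes_quadrants.tsv", sep="\t", index=False)
    summary = intersect.group_summary(table)
    (OUT / "group_summary.json").write_text(json.dumps(summary.as_dict(), indent=2))
    d = summary.as_dict()
    print(f"\nshared consistent genes: {summary.total}")
    print(f"groups 1-4: {d['n1']}, {d['n2']}, {d['n3']}, {d['n4']}")
    print(f"axolotl-down share: {d['pct_ax_down_display']}% "
          f"(of which rat-up {d['pct_ax_down_rat_up_display']}%)")
    print(f"axolotl-up share:   {d['pct_ax_up_display']}% "
          f"(of which rat-down {d['pct_ax_up_rat_down_display']}%)")

    for g in (1, 2, 3, 4):
        for sp in ("rat", "ax"):
            intersect.top_genes(table, g, config.top_n, sp).to_csv(
                OUT / f"top_genes_group{g}_{sp}.tsv", sep="\t", index=False)
    intersect.parallel_coords(table).to_csv(OUT / "parallel_coordinates.tsv",
                                            sep="\t", index=False)
    shared = {
        f"{lbl}_{tp}": sorted(genes)
        for lbl, direction in (("up", 1), ("down", -1))
        for tp, genes in intersect.shared_per_timepoint(
            anchored["rat"], anchored["axolotl"], direction).items()
    }
    (OUT / "shared_per_timepoint.json").write_text(json.dumps(shared, indent=2))
    print("\nshared genes per timepoint (no consistency filter): "
          + ", ".join(f"{k}={len(v)}" for k, v in shared.items()))


if __name__ == "__main__":
    main()
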