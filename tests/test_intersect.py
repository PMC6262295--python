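"""Ortholog anchoring, temporal consistency, quadrant classification."""

import numpy as np
import pandas as pd
import pytest

from crossregen import diffexpr, intersect
from crossregen.intersect import OrthologMap
from crossregen.simulate import SyntheticDesign, generate_experiment

from conftest import quadrant_table_from_counts, run_de_and_anchor


def make_records(rows):
    defaults = {"p_adj": 0.01, "p_raw": 0.001, "significant": True}
    full = [{**defaults, **r, "direction": int(np.sign(r["log2_fc"]))} for r in rows]
    return pd.DataFrame(full).set_index("gene_id", drop=False)


def anchored(rows):
    """Records already keyed by human symbol (identity anchoring)."""
    table = make_records(rows)
    table.index.name = "human_symbol"
    table = table.rename(columns={"gene_id": "human_symbol"})
    return table


class TestMapToAnchor:
    def map_of(self, pairs):
        return OrthologMap(pd.DataFrame(
            [{"axolotl_id": a, "human_symbol": h, "rat_id": r} for a, h, r in pairs]
        ))

    def test_unmapped_genes_dropped_and_counted(self):
        omap = self.map_of([("ax1", "H1", "r1")])
        rec = make_records([{"gene_id": "r1", "log2_fc": 1.0},
                            {"gene_id": "r2", "log2_fc": 2.0}])
        out, dropped = intersect.map_to_anchor(rec, omap, "rat")
        assert list(out.index) == ["H1"]
        assert dropped == 1

    def test_identity_map_preserves_keys(self):
        omap = self.map_of([("a1", "G1", "G1"), ("a2", "G2", "G2")])
        rec = make_records([{"gene_id": "G1", "log2_fc": 1.0},
                            {"gene_id": "G2", "log2_fc": -1.0}])
        out, dropped = intersect.map_to_anchor(rec, omap, "rat")
        assert set(out.index) == {"G1", "G2"} and dropped == 0

    def test_many_to_one_keeps_smallest_p_adj(self):
        omap = self.map_of([("a1", "H1", "r1"), ("a2", "H1", "r2")])
        rec = make_records([{"gene_id": "r1", "log2_fc": 1.0, "p_adj": 0.04},
                            {"gene_id": "r2", "log2_fc": 2.0, "p_adj": 0.01}])
        out, _ = intersect.map_to_anchor(rec, omap, "rat")
        assert out.loc["H1", "gene_id"] == "r2"

    def test_synthetic_unmapped_fraction_count_matches_truth(self):
        design = SyntheticDesign(n_genes=100, quadrant_counts=(5, 5, 5, 5),
                                 n_inconsistent=10, n_species_specific=10, seed=4)
        rat, _, ortho, _ = generate_experiment(design)
        rec = diffexpr.de_table(rat, "rat", "d1")
        out, dropped = intersect.map_to_anchor(rec, OrthologMap(ortho), "rat")
        assert dropped == design.n_species_specific
        assert len(out) == design.n_genes - design.n_species_specific


class TestConsistentSet:
    def test_gene_missing_significance_at_one_timepoint_excluded(self):
        per_tp = {
            "d1": anchored([{"gene_id": "G1", "log2_fc": 1.0}]),
            "d3": anchored([{"gene_id": "G1", "log2_fc": 1.0}]),
            "d7": anchored([{"gene_id": "G1", "log2_fc": 1.0, "significant": False}]),
        }
        assert len(intersect.consistent_set(per_tp)) == 0

    def test_sign_flip_across_timepoints_excluded(self):
        per_tp = {
            "d1": anchored([{"gene_id": "G1", "log2_fc": 1.0}]),
            "d3": anchored([{"gene_id": "G1", "log2_fc": 1.0}]),
            "d7": anchored([{"gene_id": "G1", "log2_fc": -1.0}]),
        }
        assert len(intersect.consistent_set(per_tp)) == 0

    def test_consistent_gene_included_with_direction(self):
        per_tp = {
            tp: anchored([{"gene_id": "G1", "log2_fc": 0.8},
                          {"gene_id": "G2", "log2_fc": -0.8}])
            for tp in ("d1", "d3", "d7")
        }
        out = intersect.consistent_set(per_tp)
        assert out["G1"] == 1 and out["G2"] == -1

    def test_planted_genes_survive_filter(self, small_anchored):
        rat_anchor, _, truth = small_anchored
        cons = intersect.consistent_set(rat_anchor)
        for g in (2, 4):  # rat-up groups
            for sym in truth.genes_in_group(g):
                assert cons.get(sym) == 1

    def test_antitone_in_alpha(self, small_experiment):
        rat_expr, ax_expr, ortho, _ = small_experiment
        rat_loose, _ = run_de_and_anchor(rat_expr, ax_expr, ortho, alpha=0.05)
        rat_tight, _ = run_de_and_anchor(rat_expr, ax_expr, ortho, alpha=0.001)
        loose = set(intersect.consistent_set(rat_loose).index)
        tight = set(intersect.consistent_set(rat_tight).index)
        assert tight <= loose


class TestClassifyQuadrants:
    def two_species(self, ax_fc, rat_fc):
        rat = {tp: anchored([{"gene_id": "G1", "log2_fc": rat_fc}]) for tp in ("d1", "d3", "d7")}
        ax = {tp: anchored([{"gene_id": "G1", "log2_fc": ax_fc}]) for tp in ("d1", "d3", "d7")}
        return intersect.classify_quadrants(rat, ax)

    @pytest.mark.parametrize(
        "ax_fc,rat_fc,group",
        [(1.0, -1.0, 1), (1.0, 1.0, 2), (-1.0, -1.0, 3), (-1.0, 1.0, 4)],
    )
    def test_sign_combinations_map_to_groups(self, ax_fc, rat_fc, group):
        table = self.two_species(ax_fc, rat_fc)
        assert table.loc["G1", "group"] == group

    def test_empty_intersection_gives_empty_table(self):
        rat = {tp: anchored([{"gene_id": "G1", "log2_fc": 1.0}]) for tp in ("d1",)}
        ax = {tp: anchored([{"gene_id": "G2", "log2_fc": 1.0}]) for tp in ("d1",)}
        table = intersect.classify_quadrants(rat, ax)
        assert len(table) == 0

    def test_partition_and_conservation(self, small_quadrants):
        table, _ = small_quadrants
        assert table["group"].isin([1, 2, 3, 4]).all()
        assert table.index.is_unique
        counts = intersect.group_summary(table).counts
        assert sum(counts.values()) == len(table)

    def test_planted_recovery_at_low_noise(self, small_quadrants):
        table, truth = small_quadrants
        for g in (1, 2, 3, 4):
            assert set(table.index[table["group"] == g]) == truth.genes_in_group(g)


class TestGroupSummary:
    def test_paper_count_arithmetic(self):
        """Counts (77, 41, 32, 132): 58% axolotl-down, ~80% of those rat-up."""
        s = intersect.group_summary(quadrant_table_from_counts((77, 41, 32, 132)))
        assert s.total == 282
        assert s.pct_ax_down == pytest.approx(100 * 164 / 282)
        assert round(s.pct_ax_down) == 58
        assert round(s.pct_ax_up) == 42
        assert s.pct_ax_down_rat_up == pytest.approx(100 * 132 / 164)
        assert round(s.pct_ax_down_rat_up) == 80
        assert s.pct_ax_up_rat_down == pytest.approx(100 * 77 / 118)

    def test_single_gene_flags_undefined_ratio(self):
        s = intersect.group_summary(quadrant_table_from_counts((1, 0, 0, 0)))
        assert s.pct_ax_up == pytest.approx(100.0)
        assert s.pct_ax_down_rat_up is None
        assert "pct_ax_down_rat_up" in s.undefined

    def test_empty_table_is_all_zero_and_flagged(self):
        s = intersect.group_summary(quadrant_table_from_counts((0, 0, 0, 0)))
        assert s.total == 0
        assert s.pct_ax_down is None and "pct_ax_down" in s.undefined


class TestTopGenes:
    def table(self):
        rows = [("A", 2.0, 1.0), ("B", -3.0, 1.0), ("C", 3.0, 1.0), ("D", 3.0, 1.0)]
        t = pd.DataFrame(
            [{"human_symbol": s, "avg_rat_fc": r, "avg_ax_fc": a, "group": 2}
             for s, r, a in rows]
        )
        return t.set_index("human_symbol", drop=False)

    def test_ranked_by_abs_fc_with_alphabetical_ties(self):
        top = intersect.top_genes(self.table(), 2, 3, "rat")
        assert list(top["human_symbol"]) == ["B", "C", "D"]

    def test_n_larger_than_group_returns_all(self):
        assert len(intersect.top_genes(self.table(), 2, 99, "rat")) == 4

    def test_largest_planted_effect_ranks_first(self, small_quadrants):
        table, truth = small_quadrants
        top = intersect.top_genes(table, 2, 1, "rat")
        g2 = truth.genes_in_group(2)
        true_mags = truth.effects.loc[sorted(g2)].filter(like="rat").abs().mean(axis=1)
        assert top.iloc[0]["human_symbol"] in set(true_mags[true_mags == true_mags.max()].index)


class TestSharedPerTimepoint:
    def test_gene_shared_at_one_timepoint_only(self):
        rat = {
            "d1": anchored([{"gene_id": "G1", "log2_fc": 1.0}]),
            "d3": anchored([{"gene_id": "G1", "log2_fc": 1.0, "significant": False}]),
        }
        ax = {
            "d1": anchored([{"gene_id": "G1", "log2_fc": 1.0}]),
            "d3": anchored([{"gene_id": "G1", "log2_fc": 1.0}]),
        }
        out = intersect.shared_per_timepoint(rat, ax, 1)
        assert out["d1"] == {"G1"} and out["d3"] == set()

    def test_disjoint_filter_set_empties_everything(self, small_anchored):
        rat_anchor, ax_anchor, _ = small_anchored
        out = intersect.shared_per_timepoint(rat_anchor, ax_anchor, 1, gene_filter={"NOPE"})
        assert all(v == set() for v in out.values())

    def test_filter_set_restricts_to_annotation(self, small_anchored):
        rat_anchor, ax_anchor, truth = small_anchored
        matrix_like = truth.genes_in_group(2)
        out = intersect.shared_per_timepoint(rat_anchor, ax_anchor, 1, gene_filter=matrix_like)
        for tp, genes in out.items():
            assert genes <= matrix_like
            assert genes  # planted up-both genes present every day


class TestParallelCoords:
    def test_row_count_is_genes_x_species_x_timepoints(self, small_quadrants):
        table, _ = small_quadrants
        one = table.iloc[[0]]
        tidy = intersect.parallel_coords(one)
        assert len(tidy) == 6
        assert set(tidy["species"]) == {"rat", "axolotl"}

    def test_empty_input_gives_header_only(self, small_quadrants):
        table, _ = small_quadrants
        tidy = intersect.parallel_coords(table.iloc[0:0])
        assert list(tidy.columns) == ["gene", "species", "timepoint", "log2_fc"]
        assert len(tidy) == 0

    def test_round_trip_reshape(self, small_quadrants):
        table, _ = small_quadrants
        tidy = intersect.parallel_coords(table)
        wide = tidy.pivot(index="gene", columns=["species", "timepoint"], values="log2_fc")
        for tp in ("d1", "d3", "d7"):
            assert np.allclose(wide[("rat", tp)].loc[table.index], table[f"rat_fc_{tp}"])
            assert np.allclose(wide[("axolotl", tp)].loc[table.index], table[f"ax_fc_{tp}"])
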