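import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from crossregen import diffexpr, intersect
from crossregen.simulate import SyntheticDesign, generate_experiment

TIMEPOINTS = ("d1", "d3", "d7")


@pytest.fixture(scope="session")
def small_design():
    """Small, high-power design used by most integration tests."""
    return SyntheticDesign(
        n_genes=200,
        quadrant_counts=(15, 10, 8, 20),
        n_inconsistent=20,
        n_species_specific=20,
        effect_size=3.0,
        within_group_sd=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_experiment(small_design):
    return generate_experiment(small_design)


def run_de_and_anchor(rat_expr, ax_expr, ortho, timepoints=TIMEPOINTS, **de_kw):
    """DE on both species and ortholog anchoring; shared helper."""
    omap = intersect.OrthologMap(ortho)
    rat_de = diffexpr.de_all_strata(rat_expr, "rat", timepoints, **de_kw)
    ax_de = diffexpr.de_all_strata(ax_expr, "axolotl", timepoints, **de_kw)
    rat_anchor = {tp: intersect.map_to_anchor(t, omap, "rat")[0] for tp, t in rat_de.items()}
    ax_anchor = {tp: intersect.map_to_anchor(t, omap, "axolotl")[0] for tp, t in ax_de.items()}
    return rat_anchor, ax_anchor


@pytest.fixture(scope="session")
def small_anchored(small_experiment):
    rat_expr, ax_expr, ortho, truth = small_experiment
    rat_anchor, ax_anchor = run_de_and_anchor(rat_expr, ax_expr, ortho)
    return rat_anchor, ax_anchor, truth


@pytest.fixture(scope="session")
def small_quadrants(small_anchored):
    rat_anchor, ax_anchor, truth = small_anchored
    return intersect.classify_quadrants(rat_anchor, ax_anchor), truth


def quadrant_table_from_counts(counts):
    """Minimal shared-gene table with the given group sizes (for summaries)."""
    signs = {1: (1.0, -1.0), 2: (1.0, 1.0), 3: (-1.0, -1.0), 4: (-1.0, 1.0)}
    rows = []
    i = 0
    for g, n in zip((1, 2, 3, 4), counts):
        ax_s, rat_s = signs[g]
        for _ in range(n):
            rows.append(
                {"human_symbol": f"G{i:04d}", "avg_rat_fc": rat_s, "avg_ax_fc": ax_s, "group": g}
            )
            i += 1
    table = pd.DataFrame(rows, columns=["human_symbol", "avg_rat_fc", "avg_ax_fc", "group"])
    return table.set_index("human_symbol", drop=False)
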