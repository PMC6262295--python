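"""Synthetic two-species, three-timepoint injury experiments with planted truth.

Emulates the study design the pipeline targets: a rat arm with 4 injured
vs. 4 control replicates and an axolotl arm with 3 vs. 3, each profiled at
days 1, 3 and 7 post-injury, with partial ortholog coverage between the
species. Expression is simulated directly on the log2 scale
(baseline ~ Normal(8, 1), microarray-like); injured-arm values add the
gene's true log2 fold-change plus Gaussian residual noise. A designated set
of genes is planted into the four quadrant groups:

    group 1  axolotl up,   rat down        group 2  up in both
    group 3  down in both                  group 4  axolotl down, rat up

so every downstream stage (differential expression, consistency filter,
quadrant intersection, enrichment, networks, pathway impact) has a known
ground truth. Also provides generators for StringDB-like interaction
tables, GMT gene-set collections with a planted term, and signed pathway
graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .spia import PathwayGraph

TIMEPOINTS = ("d1", "d3", "d7")
# per-species sign of the true effect in each quadrant group: (axolotl, rat)
GROUP_SIGNS = {1: (+1, -1), 2: (+1, +1), 3: (-1, -1), 4: (-1, +1)}


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one simulated cross-species injury experiment.

    ``quadrant_counts`` plants genes into groups 1-4; ``n_inconsistent``
    genes carry effects that violate temporal consistency (sign flip or a
    silent timepoint) and must be filtered out downstream;
    ``n_species_specific`` genes appear on the arrays but have no ortholog
    anchor. Remaining genes up to ``n_genes`` are null in both species.
    ``effect_size`` is the mean |log2 fold-change| of planted genes and
    ``within_group_sd`` the residual SD, both in log2 units.
    """

    n_genes: int = 1000
    quadrant_counts: tuple[int, int, int, int] = (77, 41, 32, 132)
    n_inconsistent: int = 100
    n_species_specific: int = 100
    effect_size: float = 2.0
    within_group_sd: float = 0.3
    replicates_rat: int = 4
    replicates_axolotl: int = 3
    timepoints: tuple[str, ...] = TIMEPOINTS
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    pooled_axolotl_variance: bool = True  # each axolotl replicate pools 10 cords: sd/sqrt(10)
    seed: int = 0

    def __post_init__(self):
        planted = sum(self.quadrant_counts)
        if planted + self.n_inconsistent + self.n_species_specific > self.n_genes:
            raise ValueError("planted + inconsistent + species-specific exceeds n_genes")
        if self.effect_size <= 0 or self.within_group_sd <= 0:
            raise ValueError("effect_size and within_group_sd must be positive")
        if self.replicates_rat < 2 or self.replicates_axolotl < 2:
            raise ValueError("need >= 2 replicates per arm for the t-test")
        if len(self.timepoints) < 1:
            raise ValueError("need at least one timepoint")


@dataclass
class PlantedTruth:
    """Ground truth: per-gene group label and per-species true effects."""

    group: dict  # human symbol -> group in {1,2,3,4} or 0 (none)
    effects: pd.DataFrame  # index human symbol; columns <species>_<tp> true log2 fc

    def genes_in_group(self, g: int) -> set:
        return {sym for sym, grp in self.group.items() if grp == g}


def _symbols(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(n)]


def generate_experiment(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Simulate the two-species experiment described by ``design``.

    Returns ``(rat_expression, axolotl_expression, ortholog_map, truth)``.
    Expression tables are genes x samples with columns
    ``<species>_<timepoint>_<arm>_<rep>``; the ortholog map covers every
    mapped gene and omits the species-specific ones. Identical designs
    (including seed) give identical output.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    symbols = _symbols(n)
    rat_ids = [f"RAT{i:05d}" for i in range(n)]
    ax_ids = [f"AMEX{i:05d}" for i in range(n)]

    group = dict.fromkeys(symbols, 0)
    pos = 0
    for g, count in zip((1, 2, 3, 4), design.quadrant_counts):
        for sym in symbols[pos:pos + count]:
            group[sym] = g
        pos += count
    inconsistent = symbols[pos:pos + design.n_inconsistent]
    pos += design.n_inconsistent
    specific = symbols[pos:pos + design.n_species_specific]

    tps = list(design.timepoints)
    effects = pd.DataFrame(
        0.0, index=symbols,
        columns=[f"{sp}_{tp}" for sp in ("rat", "axolotl") for tp in tps],
    )
    # planted genes: per-species effect with the group's sign, magnitude =
    # effect_size (so the mean |log2 fc| is exactly effect_size), constant
    # across timepoints so the temporal-consistency filter keeps them
    for sym in symbols[:sum(design.quadrant_counts)]:
        ax_sign, rat_sign = GROUP_SIGNS[group[sym]]
        for sp, sign in (("rat", rat_sign), ("axolotl", ax_sign)):
            for tp in tps:
                effects.loc[sym, f"{sp}_{tp}"] = sign * design.effect_size
    # inconsistent genes: strong effects but sign-flipped or silent at one
    # timepoint in one species, so the consistency filter must reject them
    for sym in inconsistent:
        sp = rng.choice(["rat", "axolotl"])
        other = "axolotl" if sp == "rat" else "rat"
        sign = rng.choice([-1.0, 1.0])
        mag = design.effect_size * rng.uniform(0.75, 1.25)
        for tp in tps:
            effects.loc[sym, f"{sp}_{tp}"] = sign * mag
            effects.loc[sym, f"{other}_{tp}"] = sign * mag
        bad_tp = rng.choice(tps)
        effects.loc[sym, f"{sp}_{bad_tp}"] = -sign * mag if rng.random() < 0.5 else 0.0
    # species-specific genes: real effect in one species, no ortholog anchor
    for sym in specific:
        sp = rng.choice(["rat", "axolotl"])
        sign = rng.choice([-1.0, 1.0])
        mag = design.effect_size * rng.uniform(0.75, 1.25)
        for tp in tps:
            effects.loc[sym, f"{sp}_{tp}"] = sign * mag

    def expression(species: str, ids: list[str], n_rep: int, sd: float) -> pd.DataFrame:
        baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=n)
        cols, data = [], []
        for tp in tps:
            true_fc = effects[f"{species}_{tp}"].to_numpy()
            for arm, shift in (("control", 0.0), ("injured", true_fc)):
                for rep in range(1, n_rep + 1):
                    cols.append(f"{species}_{tp}_{arm}_{rep}")
                    data.append(baseline + shift + rng.normal(0.0, sd, size=n))
        return pd.DataFrame(np.column_stack(data), index=ids, columns=cols)

    ax_sd = design.within_group_sd / np.sqrt(10) if design.pooled_axolotl_variance else design.within_group_sd
    rat_expr = expression("rat", rat_ids, design.replicates_rat, design.within_group_sd)
    ax_expr = expression("axolotl", ax_ids, design.replicates_axolotl, ax_sd)

    specific_set = set(specific)
    rows = []
    for sym, rid, aid in zip(symbols, rat_ids, ax_ids):
        if sym in specific_set:
            continue
        rows.append({"axolotl_id": aid, "human_symbol": sym, "rat_id": rid})
    ortho = pd.DataFrame(rows, columns=["axolotl_id", "human_symbol", "rat_id"])

    truth = PlantedTruth(group=group, effects=effects)
    return rat_expr, ax_expr, ortho, truth


def generate_network(
    genes,
    edges_per_node: int = 2,
    score_range: tuple[float, float] = (0.15, 0.999),
    seed: int = 0,
) -> pd.DataFrame:
    """Scale-free-like interaction table over ``genes``.

    Preferential attachment (Barabasi-Albert) topology; scores uniform in
    the closed ``score_range``. No self-loops or duplicate edges.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a network")
    rng = np.random.default_rng(seed)
    m = min(edges_per_node, len(genes) - 1)
    g = nx.barabasi_albert_graph(len(genes), m, seed=int(rng.integers(2**31)))
    rows = [
        {"node_a": genes[a], "node_b": genes[b],
         "score": rng.uniform(score_range[0], score_range[1])}
        for a, b in sorted(g.edges())
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "score"])


def generate_genesets(
    genes,
    n_terms: int = 20,
    size_range: tuple[int, int] = (10, 50),
    planted_term: tuple[str, set] | None = None,
    seed: int = 0,
    kind: str = "go_like",
    name_prefix: str = "TERM",
):
    """Random GMT-style collection over ``genes`` plus an optional planted term.

    The planted term covers exactly its designated member genes, so a query
    equal to those genes attains the smallest possible enrichment p for the
    term's size. Background = all ``genes``.
    """
    from .enrichment import GeneSetCollection

    genes = list(genes)
    rng = np.random.default_rng(seed)
    sets: dict[str, set] = {}
    for i in range(n_terms):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(genes))
        members = set(rng.choice(genes, size=size, replace=False))
        sets[f"{name_prefix}_{i:03d}"] = members
    if planted_term is not None:
        name, members = planted_term
        members = set(members) & set(genes)
        if not members:
            raise ValueError("planted term has no members inside the universe")
        sets[name] = members
    return GeneSetCollection(sets=sets, background=set(genes), kind=kind)


def generate_pathway(
    n_genes: int,
    activation_prob: float = 0.8,
    seed: int = 0,
    *,
    genes=None,
    edge_prob: float = 0.3,
    acyclic: bool = True,
    name: str = "synthetic_pathway",
) -> PathwayGraph:
    """Random signed directed pathway graph.

    Each ordered gene pair receives an edge with probability ``edge_prob``;
    the sign is +1 (activation) with probability ``activation_prob``, else
    -1 (inhibition). With ``acyclic=True`` edges only run forward along a
    random gene order, so a topological order exists and the propagation
    system is always solvable.
    """
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"PGENE{i:03d}" for i in range(n_genes)]
    genes = list(genes)
    order = rng.permutation(len(genes))
    rank = np.argsort(order)
    beta = np.zeros((len(genes), len(genes)))
    for j in range(len(genes)):
        for i in range(len(genes)):
            if i == j:
                continue
            if acyclic and rank[i] <= rank[j]:
                continue
            if rng.random() < edge_prob:
                beta[i, j] = 1.0 if rng.random() < activation_prob else -1.0
    return PathwayGraph(name=name, genes=genes, beta=beta)
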