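"""Per-species, per-timepoint differential expression on log2-scale tables.

Each species x timepoint stratum is tested independently (injured vs.
control arms), corrected with Benjamini-Hochberg within the stratum, and
filtered on adjusted p-value and fold-change. Expression values are assumed
already normalised and on the log2 scale, so the log2 fold-change is a
simple difference of arm means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05
DEFAULT_FC_CUTOFF = 1.5  # linear fold-change, i.e. |log2 fc| >= log2(1.5)


@dataclass(frozen=True)
class DERecord:
    """Differential-expression result for one gene in one stratum."""

    gene_id: str
    species: str
    timepoint: str
    log2_fc: float
    p_raw: float
    p_adj: float
    significant: bool
    direction: int  # sign(log2_fc)


def test_gene(injured, control, *, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided t-test of injured vs. control log2 expression.

    Returns ``(log2_fc, p_raw)`` with ``log2_fc = mean(injured) - mean(control)``.
    Welch's unequal-variance test by default; set ``equal_var=True`` for the
    pooled-variance Student variant. Degenerate zero-variance input with equal
    means yields p = 1 by convention.
    """
    injured = np.asarray(injured, dtype=float)
    control = np.asarray(control, dtype=float)
    if injured.size < 2 or control.size < 2:
        raise ValueError("t-test requires at least 2 values per arm")
    if not (np.all(np.isfinite(injured)) and np.all(np.isfinite(control))):
        raise ValueError("non-finite expression values")
    log2_fc = float(injured.mean() - control.mean())
    if injured.var(ddof=1) == 0.0 and control.var(ddof=1) == 0.0:
        p = 1.0 if log2_fc == 0.0 else 0.0
        return log2_fc, p
    res = stats.ttest_ind(injured, control, equal_var=equal_var)
    p = float(res.pvalue)
    if math.isnan(p):  # residual degenerate cases
        p = 1.0
    return log2_fc, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Monotone (cumulative minimum from the largest rank) and capped at 1.
    Raises if any input lies outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fc_threshold_log2(fc_cutoff: float, fc_scale: str) -> float:
    if fc_scale == "linear":
        if fc_cutoff <= 1.0:
            raise ValueError("linear fold-change cutoff must exceed 1")
        return math.log2(fc_cutoff)
    if fc_scale == "log":
        if fc_cutoff <= 0.0:
            raise ValueError("log fold-change cutoff must be positive")
        return fc_cutoff
    raise ValueError(f"unknown fc_scale {fc_scale!r}")


def de_table(
    expression: pd.DataFrame,
    species: str,
    timepoint: str,
    *,
    alpha: float = DEFAULT_ALPHA,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    fc_scale: str = "linear",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Differential expression for one species x timepoint stratum.

    ``expression`` is genes x samples with columns named
    ``<species>_<timepoint>_<arm>_<rep>`` (arm in {injured, control}).
    Tests are vectorised across genes; BH is applied within the stratum.
    """
    prefix = f"{species}_{timepoint}_"
    inj_cols = [c for c in expression.columns if c.startswith(prefix + "injured")]
    ctl_cols = [c for c in expression.columns if c.startswith(prefix + "control")]
    if len(inj_cols) < 2 or len(ctl_cols) < 2:
        raise ValueError(
            f"stratum {species}/{timepoint}: need >= 2 replicates per arm "
            f"(found {len(inj_cols)} injured, {len(ctl_cols)} control)"
        )
    inj = expression[inj_cols].to_numpy(dtype=float)
    ctl = expression[ctl_cols].to_numpy(dtype=float)
    log2_fc = inj.mean(axis=1) - ctl.mean(axis=1)
    res = stats.ttest_ind(inj, ctl, axis=1, equal_var=equal_var)
    p_raw = np.asarray(res.pvalue, dtype=float)
    # zero variance in both arms: p = 1 when means agree, else ~0
    degenerate = np.isnan(p_raw)
    p_raw[degenerate & (log2_fc == 0.0)] = 1.0
    p_raw[degenerate & (log2_fc != 0.0)] = 0.0
    p_adj = bh_adjust(p_raw)
    thr = _fc_threshold_log2(fc_cutoff, fc_scale)
    significant = (p_adj <= alpha) & (np.abs(log2_fc) >= thr)
    return pd.DataFrame(
        {
            "gene_id": expression.index,
            "species": species,
            "timepoint": timepoint,
            "log2_fc": log2_fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": significant,
            "direction": np.sign(log2_fc).astype(int),
        }
    ).set_index("gene_id", drop=False)


def de_all_strata(
    expression: pd.DataFrame,
    species: str,
    timepoints,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """DE tables for every timepoint of one species, keyed by timepoint."""
    return {tp: de_table(expression, species, tp, **kwargs) for tp in timepoints}


def select_degs(
    records: pd.DataFrame,
    *,
    alpha: float = DEFAULT_ALPHA,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    fc_scale: str = "linear",
) -> dict[str, set]:
    """Partition a stratum's DE table into up- and downregulated gene sets.

    Thresholds are inclusive: p_adj <= alpha and |fold-change| >= cutoff.
    A gene with log2_fc exactly 0 is never selected.
    """
    thr = _fc_threshold_log2(fc_cutoff, fc_scale)
    passing = records[(records["p_adj"] <= alpha) & (records["log2_fc"].abs() >= thr)]
    up = set(passing.loc[passing["log2_fc"] > 0, "gene_id"])
    down = set(passing.loc[passing["log2_fc"] < 0, "gene_id"])
    return {"up": up, "down": down}
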