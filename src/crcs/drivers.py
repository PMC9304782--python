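"""Driver-gene prioritization from classifier score distributions.

Scores from cancer cohorts are grouped by (cancer type, gene) and compared
gene-by-gene against control (population) score groups with a one-sided
Mann-Whitney U test (cancer > control).  Within each cancer type the gene
p-values are Holm-Sidak corrected.  Genes recurrently significant across
cancer types are selected, and enrichment of known driver genes among the
significant adjusted p-values is tested with a one-sided two-sample
Kolmogorov-Smirnov test on the -log10 adjusted p-values.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .stats import mannwhitney_greater

logger = logging.getLogger("crcs")

__all__ = [
    "ScoreGroup",
    "group_scores",
    "gene_significance",
    "holm_sidak",
    "correct_within_cancer_types",
    "recurrent_gene_selection",
    "driver_enrichment_ks",
    "NEG_LOG10_FLOOR",
]

#: -log10 cap substituted for adjusted p-values that underflow to zero.
NEG_LOG10_FLOOR = -math.log10(sys.float_info.min)

#: Default minimum number of scores for a (cancer type, gene) group.
DEFAULT_MIN_GROUP_SIZE = 5


@dataclass(frozen=True)
class ScoreGroup:
    cancer_type: Optional[str]
    gene_symbol: str
    scores: tuple[float, ...]


def group_scores(
    scored: pd.DataFrame,
    by_cancer_type: bool = True,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> list[ScoreGroup]:
    """Group scores by (cancer type, gene); drop groups below the cutoff.

    *scored* needs columns ``gene_symbol`` and ``score`` plus
    ``cancer_type`` when *by_cancer_type*.  Groups with fewer than
    *min_group_size* scores are dropped (i.e. groups of >= 5 survive at the
    default cutoff).
    """
    if min_group_size < 1:
        raise ValueError("min_group_size must be >= 1")
    keys = ["cancer_type", "gene_symbol"] if by_cancer_type else ["gene_symbol"]
    out = []
    for key, sub in scored.groupby(keys, sort=True):
        if len(sub) < min_group_size:
            continue
        if by_cancer_type:
            ct, gene = key
        else:
            ct, gene = None, key[0] if isinstance(key, tuple) else key
        out.append(ScoreGroup(ct, gene, tuple(float(x) for x in sub["score"])))
    return out


def gene_significance(
    cancer_groups: Sequence[ScoreGroup],
    control_groups: Sequence[ScoreGroup],
) -> pd.DataFrame:
    """Raw one-sided (cancer > control) p per (cancer type, gene).

    Control groups are keyed by gene alone; genes missing from the control
    side are skipped and counted in the log.
    """
    controls: Mapping[str, ScoreGroup] = {g.gene_symbol: g for g in control_groups}
    rows = []
    skipped = 0
    for cg in cancer_groups:
        ctrl = controls.get(cg.gene_symbol)
        if ctrl is None:
            skipped += 1
            continue
        p = mannwhitney_greater(cg.scores, ctrl.scores)
        rows.append((cg.cancer_type, cg.gene_symbol, p))
    if skipped:
        logger.info("gene_significance: skipped %d gene group(s) missing controls", skipped)
    return pd.DataFrame(rows, columns=["cancer_type", "gene", "raw_p"])


def holm_sidak(pvals) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in input order.

    adj_(i) = max_{j <= i} [1 - (1 - p_(j))^(m - j + 1)] on the ascending
    order statistics, clipped to 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="holm-sidak")
    return adj


def correct_within_cancer_types(
    table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Holm-Sidak correction applied per cancer type across its genes."""
    out = table.copy()
    out["adjusted_p"] = np.nan
    for ct, sub in out.groupby("cancer_type"):
        out.loc[sub.index, "adjusted_p"] = holm_sidak(sub["raw_p"].to_numpy())
    out["significant"] = out["adjusted_p"] < alpha
    return out


def recurrent_gene_selection(
    table: pd.DataFrame,
    min_cancer_types: int = 10,
    min_genes_per_type: int = 6,
) -> tuple[set[str], set[str]]:
    """Select recurrently significant genes, then prune sparse cancer types.

    Genes significant in at least *min_cancer_types* cancer types are kept;
    cancer types retaining fewer than *min_genes_per_type* of those genes
    are then dropped (the default drops types with <= 5 genes).
    """
    sig = table[table["significant"]]
    if sig.empty:
        return set(), set()
    per_gene = sig.groupby("gene")["cancer_type"].nunique()
    genes = set(per_gene[per_gene >= min_cancer_types].index)
    sub = sig[sig["gene"].isin(genes)]
    per_type = sub.groupby("cancer_type")["gene"].nunique()
    types = set(per_type[per_type >= min_genes_per_type].index)
    return genes, types


def neg_log10(p: np.ndarray) -> np.ndarray:
    """-log10 with zero p-values replaced by a machine-precision cap."""
    p = np.asarray(p, dtype=float)
    out = np.empty_like(p)
    zero = p <= 0
    if zero.any():
        logger.info("neg_log10: %d zero p-value(s) floored", int(zero.sum()))
    out[zero] = NEG_LOG10_FLOOR
    out[~zero] = -np.log10(p[~zero])
    return out


def driver_enrichment_ks(
    adjusted_p_known_drivers, adjusted_p_all_genes
) -> float:
    """One-sided KS p that known drivers have larger -log10 adjusted p.

    Alternative: the driver-gene transformed values are stochastically
    larger than those of the full gene population.
    """
    drivers = np.asarray(adjusted_p_known_drivers, dtype=float)
    allg = np.asarray(adjusted_p_all_genes, dtype=float)
    if drivers.size == 0 or allg.size == 0:
        raise ValueError("both samples must be nonempty")
    x = neg_log10(drivers)
    y = neg_log10(allg)
    # 'less': CDF of x lies below CDF of y, i.e. x stochastically larger
    res = sps.ks_2samp(x, y, alternative="less")
    return float(res.pvalue)
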