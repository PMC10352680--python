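"""Two-group differential expression with p-value and fold-change cutoffs.

Genes are called differentially expressed when a two-sided Welch
(unequal-variance) t-test gives p below the significance threshold *and* the
absolute log2 fold change (case mean minus control mean, data already on the
log2 scale) exceeds the fold-change threshold.  The default thresholds are
p < 0.05 and |log2FC| > log2(1.2) = 0.2630344, both strict.

No multiple-testing correction enters the call itself; a Benjamini–Hochberg
adjusted column is emitted for information only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CASE, CONTROL, ExpressionMatrix

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"


def log2fc_threshold(fold_change: float) -> float:
    """Log2 fold-change cutoff equivalent to a linear fold change.

    A symmetric cutoff: genes pass when |log2FC| exceeds the returned value,
    i.e. linear fold change >= ``fold_change`` or <= 1/``fold_change``.

    >>> round(log2fc_threshold(1.2), 7)
    0.2630344
    """
    if fold_change <= 1:
        raise ValueError("fold_change must be > 1")
    return float(np.log2(fold_change))


@dataclass(frozen=True)
class Thresholds:
    """Significance and effect-size cutoffs for the DEG call (both strict)."""

    p_threshold: float = 0.05
    fc_threshold: float = log2fc_threshold(1.2)

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.fc_threshold <= 0:
            raise ValueError("thresholds must be strictly positive")


def run_differential_expression(
    expr: ExpressionMatrix, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Welch-test every gene and flag DEGs per the thresholds.

    Returns
    -------
    pandas.DataFrame
        Indexed by gene; columns ``log2fc`` (case mean − control mean),
        ``p_value``, ``adj_p`` (Benjamini–Hochberg, informational),
        ``is_deg``, ``direction`` (up/down/unchanged).

    Notes
    -----
    Genes with zero variance in both groups get p = 0 when the group means
    differ and p = 1 when they coincide (the limiting behaviour of the test
    statistic as the pooled variance vanishes).
    """
    case = expr.group_values(CASE).to_numpy()
    ctrl = expr.group_values(CONTROL).to_numpy()

    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)

    degenerate = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    p[degenerate] = np.where(log2fc[degenerate] != 0.0, 0.0, 1.0)
    p = np.nan_to_num(p, nan=1.0)

    adj_p = multipletests(p, method="fdr_bh")[1]
    is_deg = (p < thresholds.p_threshold) & (np.abs(log2fc) > thresholds.fc_threshold)
    direction = np.where(~is_deg, UNCHANGED, np.where(log2fc > 0, UP, DOWN))

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": adj_p,
            "is_deg": is_deg,
            "direction": direction,
        },
        index=pd.Index(expr.gene_ids, name="gene"),
    )


def deg_genes(deg_table: pd.DataFrame) -> list[str]:
    """Gene ids flagged as differentially expressed, in table order."""
    return list(deg_table.index[deg_table["is_deg"]])
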