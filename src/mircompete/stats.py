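"""Expression-association statistics for the BPP-AUC affinity proxy.

Given per-miRNA AUC scores and expression tables for two genotypes (a
wild-type and a Dicer-reduced condition), this module fits per-genotype
least-squares regressions of log10 expression on AUC, compares the two
slopes with a t statistic, and correlates the between-genotype expression
fold change with AUC after removing extreme fold-change outliers.

The slope comparison is, deliberately, the formula as printed in the source
analysis::

    t = (beta_a - beta_b) / (SE_a + SE_b)

with the SEs *summed* in the denominator. The conventional quadrature
denominator ``sqrt(SE_a^2 + SE_b^2)`` is available via
``variant='quadrature'``; since ``SE_a + SE_b >= sqrt(SE_a^2 + SE_b^2)``
the printed form is conservative. Degrees of freedom are
``n_a + n_b - 4`` (two parameters estimated per regression).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AssociationResult",
    "SlopeComparison",
    "ExpressionTable",
    "pearson_with_regression",
    "slope_ttest",
    "two_tailed_p_from_t",
    "fold_change_association",
    "genotype_regressions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationResult:
    """OLS + Pearson summary of a bivariate association."""

    n: int
    r: float
    p: float
    intercept: float
    slope: float
    slope_se: float


@dataclass(frozen=True)
class SlopeComparison:
    t: float
    df: int
    p: float


class ExpressionTable:
    """Per-miRNA expression across conditions, keyed by miRNA id.

    Wraps a DataFrame with an ``id`` column plus one non-negative expression
    column per condition. log10 transforms and fold changes drop miRNAs
    with non-positive expression in the relevant columns (logged).
    """

    def __init__(self, data: pd.DataFrame):
        if "id" not in data.columns:
            raise ValueError("expression table needs an 'id' column")
        if data["id"].duplicated().any():
            dupes = data.loc[data["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate miRNA ids: {dupes}")
        conditions = [c for c in data.columns if c != "id"]
        if not conditions:
            raise ValueError("expression table needs at least one condition column")
        for c in conditions:
            if (data[c] < 0).any():
                raise ValueError(f"negative expression in condition {c!r}")
        self.data = data.reset_index(drop=True)
        self.conditions = conditions

    def log10_expression(self, condition: str) -> pd.Series:
        """log10 expression indexed by id; zero-expression rows are dropped."""
        col = self.data.set_index("id")[condition]
        zero = col[col <= 0]
        if len(zero):
            logger.info(
                "excluding %d miRNAs with non-positive %s expression from log10: %s",
                len(zero), condition, list(zero.index),
            )
        return np.log10(col[col > 0]).rename(f"log10_{condition}")

    def fold_change(self, condition: str, reference: str) -> pd.Series:
        """Per-miRNA expression ratio condition/reference, indexed by id.

        Rows with zero reference expression are dropped (ratio undefined).
        """
        d = self.data.set_index("id")
        ref = d[reference]
        bad = ref[ref <= 0]
        if len(bad):
            logger.info(
                "excluding %d miRNAs with zero %s (reference) expression from "
                "fold change: %s", len(bad), reference, list(bad.index),
            )
        keep = ref > 0
        return (d.loc[keep, condition] / ref[keep]).rename("fold_change")


def pearson_with_regression(auc, y) -> AssociationResult:
    """Pearson r (two-tailed p, t-distributed with n-2 df) plus OLS line.

    ``slope_se`` is the standard error of the OLS slope.
    """
    x = np.asarray(auc, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("auc and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input; association undefined")
    fit = sps.linregress(x, y)
    return AssociationResult(
        n=x.size,
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
    )


def two_tailed_p_from_t(t: float, df: int) -> float:
    """Two-tailed p-value of a t statistic."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * sps.t.sf(abs(t), df))


def slope_ttest(
    a: AssociationResult, b: AssociationResult, *, variant: str = "printed"
) -> SlopeComparison:
    """Compare two regression slopes.

    ``variant='printed'`` uses ``(slope_a - slope_b) / (SE_a + SE_b)``;
    ``variant='quadrature'`` uses the conventional
    ``sqrt(SE_a^2 + SE_b^2)`` denominator. df = n_a + n_b - 4.
    """
    if variant == "printed":
        denom = a.slope_se + b.slope_se
    elif variant == "quadrature":
        denom = math.hypot(a.slope_se, b.slope_se)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if denom == 0:
        raise ValueError("slope standard errors sum to zero; t undefined")
    t = (a.slope - b.slope) / denom
    df = a.n + b.n - 4
    return SlopeComparison(t=float(t), df=df, p=two_tailed_p_from_t(t, df))


def fold_change_association(
    table: ExpressionTable,
    aucs: pd.DataFrame,
    *,
    condition: str,
    reference: str,
    outlier_cap: float = 4.0,
) -> tuple[AssociationResult, pd.DataFrame]:
    """Correlate per-miRNA expression fold change with AUC.

    Joins the expression table with the AUC table on id, computes fold
    change condition/reference, removes rows with fold change above
    ``outlier_cap`` (pass ``math.inf`` to disable), and regresses fold
    change on AUC. Returns the association plus a per-miRNA detail frame
    with a ``filtered`` flag.
    """
    if "id" not in aucs.columns or "auc" not in aucs.columns:
        raise ValueError("aucs must have 'id' and 'auc' columns")
    fc = table.fold_change(condition, reference)
    detail = (
        aucs.set_index("id")[["auc"]]
        .join(fc, how="inner")
        .dropna()
        .reset_index()
    )
    if detail.empty:
        raise ValueError("no overlapping miRNA ids between expression and AUC tables")
    detail["filtered"] = detail["fold_change"] > outlier_cap
    kept = detail[~detail["filtered"]]
    if len(kept) < 3:
        raise ValueError(
            f"only {len(kept)} miRNAs survive the fold-change cap {outlier_cap}; need >= 3"
        )
    assoc = pearson_with_regression(kept["auc"], kept["fold_change"])
    return assoc, detail


def genotype_regressions(
    table: ExpressionTable, aucs: pd.DataFrame, conditions: tuple[str, ...] | None = None
) -> dict[str, AssociationResult]:
    """Per-genotype OLS of log10 expression on AUC, keyed by condition name."""
    if conditions is None:
        conditions = tuple(table.conditions)
    scores = aucs.set_index("id")["auc"]
    out = {}
    for cond in conditions:
        y = table.log10_expression(cond)
        joined = pd.concat([scores, y], axis=1, join="inner").dropna()
        out[cond] = pearson_with_regression(joined["auc"], joined.iloc[:, 1])
    return out
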