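"""Group and brain-behaviour statistics.

Between-group comparisons use the pooled-variance (Student) two-sample
t-test — the design the cohort's printed df = n1 + n2 - 2 = 44 implies —
either from raw samples or directly from printed summary statistics
(mean, SD, n).  Categorical contrasts use Fisher's exact test.  Multiple
comparisons are controlled by a Bonferroni threshold (alpha / m) or
Benjamini-Hochberg step-up FDR.  Brain-behaviour associations are
ordinary least squares of a per-subject metric on the memory score with
gender, age and motion as covariates of no interest.

Implementation rides on scipy.stats and statsmodels; the module surface
and conventions (two-tailed p, ML/OLS denominators, degenerate-input
handling) are fixed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import SingularDesignError

__all__ = [
    "SummaryStats",
    "GroupTestResult",
    "AssociationResult",
    "ttest_from_summary",
    "ttest_two_sample",
    "fisher_exact",
    "bonferroni_threshold",
    "bh_fdr",
    "adjusted_association",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryStats:
    """Printed group summary: mean, SD and sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass
class GroupTestResult:
    statistic: float
    df: float
    p_two_tailed: float
    corrected_significant: bool = False
    correction: str = "none"
    degenerate: bool = False


@dataclass
class AssociationResult:
    coefficient: float
    t_statistic: float
    df: int
    p: float
    covariates: list[str] = field(default_factory=list)
    n_dropped: int = 0


def ttest_from_summary(a: SummaryStats, b: SummaryStats) -> GroupTestResult:
    """Pooled-variance two-sample t-test from summary statistics.

    df = n1 + n2 - 2; two-tailed p.  A zero pooled variance gives p = 1
    for equal means and a degenerate flag otherwise.
    """
    df = a.n + b.n - 2
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return GroupTestResult(0.0, df, 1.0)
        return GroupTestResult(float("inf"), df, 0.0, degenerate=True)
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return GroupTestResult(float(t), float(df), float(p))


def ttest_two_sample(x, y) -> GroupTestResult:
    """Pooled-variance two-sample t-test on raw samples.

    Exactly consistent with :func:`ttest_from_summary` applied to the
    groups' (mean, ddof=1 SD, n) summaries.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        logger.info("constant groups in t-test; applying degenerate convention")
        return ttest_from_summary(
            SummaryStats(float(x.mean()), 0.0, x.size),
            SummaryStats(float(y.mean()), 0.0, y.size),
        )
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return GroupTestResult(float(t), float(x.size + y.size - 2), float(p))


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of non-negative counts.

    Two-sidedness follows the probability-summation convention (all
    tables with hypergeometric probability <= the observed one).  A zero
    margin gives p = 1.
    """
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or np.any(tab < 0):
        raise ValueError("table must be 2x2 with non-negative integers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        return 1.0
    return float(sps.fisher_exact(tab, alternative="two-sided")[1])


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


def bh_fdr(pvals, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def _name_dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns linearly dependent on their predecessors (incremental rank)."""
    bad = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            bad.append(names[j])
        rank = r
    return bad


def adjusted_association(
    outcome,
    predictor,
    covariates: pd.DataFrame | None = None,
) -> AssociationResult:
    """OLS of a per-subject metric on the memory score plus covariates.

    Incomplete cases are dropped listwise (count logged and reported).
    Returns the t statistic, residual df and two-tailed p for the
    predictor's coefficient.  A rank-deficient design raises
    :class:`SingularDesignError` naming the offending columns.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if covariates is None:
        covariates = pd.DataFrame(index=range(y.size))
    cov = covariates.reset_index(drop=True).astype(float)
    frame = pd.DataFrame({"_outcome": y, "_predictor": x}).join(cov)
    complete = frame.dropna()
    n_dropped = len(frame) - len(complete)
    if n_dropped:
        logger.info("adjusted_association: dropped %d incomplete cases", n_dropped)
    n = len(complete)
    k = 2 + cov.shape[1]  # intercept + predictor + covariates
    if n <= k:
        raise ValueError(f"need n > {k} complete cases, have {n}")
    design = sm.add_constant(
        complete[["_predictor", *cov.columns]], has_constant="add"
    )
    if np.linalg.matrix_rank(design.values) < design.shape[1]:
        bad = _name_dependent_columns(design.values, list(design.columns))
        raise SingularDesignError(f"collinear design columns: {bad}")
    fit = sm.OLS(complete["_outcome"], design).fit()
    return AssociationResult(
        coefficient=float(fit.params["_predictor"]),
        t_statistic=float(fit.tvalues["_predictor"]),
        df=int(fit.df_resid),
        p=float(fit.pvalues["_predictor"]),
        covariates=list(cov.columns),
        n_dropped=n_dropped,
    )
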