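"""Cross-modality correlation with multiple-testing correction.

Regional imaging metrics (mean/axial/radial diffusivity and kurtosis, FA,
KFA) are paired by ROI with histological heterogeneity metrics (feature-
vector kurtosis and SD).  Each metric pair is tested with Pearson's
product-moment correlation (two-sided p from the t statistic with n-2
degrees of freedom, as implemented in SciPy) and the family of all pairs
run in one invocation is corrected with the Benjamini-Hochberg step-up
procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "UndefinedCorrelationError",
    "pearson",
    "bh_adjust",
    "build_paired_table",
    "correlate_modalities",
    "results_to_frame",
]

log = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Correlation undefined: fewer than 3 points or zero variance."""


@dataclass
class CorrelationResult:
    """One metric pair: r, two-sided p, BH-adjusted p, sample size."""

    dkti_metric: str
    histo_metric: str
    n: int
    r: float
    p: float
    p_adj: float = float("nan")


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson's r and two-sided p-value (t distribution, n-2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the inputs")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up).

    q(i) = min_{j >= i} p(j) * m / j on the ascending-sorted p-values,
    capped at 1 and mapped back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def build_paired_table(
    dkti: pd.DataFrame, histo: pd.DataFrame, on: str = "roi"
) -> pd.DataFrame:
    """Inner-join regional imaging and histology tables on ROI label.

    ``dkti`` must be wide (one row per ROI, one column per metric);
    ``histo`` likewise.  Rows dropped by the join are logged.
    """
    merged = dkti.merge(histo, on=on, how="inner", suffixes=("_dkti", "_histo"))
    dropped = set(dkti[on]).symmetric_difference(set(histo[on]))
    if dropped:
        log.info("ROIs without both modalities dropped from pairing: %s", sorted(dropped))
    return merged


def correlate_modalities(
    table: pd.DataFrame,
    dkti_metrics: list[str],
    histo_metrics: list[str],
) -> list[CorrelationResult]:
    """Correlate every (imaging, histology) metric pair across ROIs.

    The BH family is the full set of pairs tested in this invocation.
    Pairs with fewer than 3 complete rows or zero variance are skipped
    with a log entry.
    """
    results: list[CorrelationResult] = []
    for dm in dkti_metrics:
        for hm in histo_metrics:
            sub = table[[dm, hm]].dropna()
            if len(sub) < 3:
                log.warning("pair (%s, %s) skipped: only %d complete rows", dm, hm, len(sub))
                continue
            x, y = sub[dm].to_numpy(), sub[hm].to_numpy()
            if np.var(x) == 0 or np.var(y) == 0:
                log.warning("pair (%s, %s) skipped: zero variance", dm, hm)
                continue
            r, p = pearson(x, y)
            results.append(CorrelationResult(dm, hm, n=len(sub), r=r, p=p))
    if results:
        adj = bh_adjust(np.array([res.p for res in results]))
        for res, a in zip(results, adj):
            res.p_adj = float(a)
    log.info("BH family: %d metric-pair tests corrected together", len(results))
    return results


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Correlation results as a tidy table (pair, n, r, p, p_adj)."""
    return pd.DataFrame(
        [
            {
                "dkti_metric": res.dkti_metric,
                "histo_metric": res.histo_metric,
                "n": res.n,
                "r": res.r,
                "p": res.p,
                "p_adj": res.p_adj,
            }
            for res in results
        ]
    )
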