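"""Stress-, pathogen- and hormone-responsive gene calling.

Replicated log2 fold-change profiles from comparable experiments are combined
per condition (arithmetic mean), and each gene/condition is tested with a
one-sample, one-tailed t-test against 0.  A gene is called responsive when
the direction-matched one-tailed p-value is below alpha AND the combined
|log2 fold-change| exceeds a threshold (default 1.0, i.e. two-fold); sign
separates induced from repressed.  Raw p-values are used by default;
Benjamini-Hochberg correction is available but off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ResponseConfig",
    "combine_fold_changes",
    "one_sample_t_test",
    "call_responsive",
    "StressResponseCaller",
]


@dataclass(frozen=True)
class ResponseConfig:
    alpha: float = 0.05
    log2fc_threshold: float = 1.0
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.log2fc_threshold <= 0:
            raise ValueError("log2fc_threshold must be > 0")


def combine_fold_changes(
    fc: pd.DataFrame,
    condition_groups: Mapping[str, str],
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Average log2 fold-changes of experiments sharing a condition.

    ``condition_groups`` maps experiment (column) -> condition label; every
    condition needs >= 2 experiments so the t-test is possible.  Returns the
    genes-by-conditions matrix of combined values and, per condition, the
    retained replicate columns.
    """
    missing = [c for c in fc.columns if c not in condition_groups]
    if missing:
        raise ValueError(f"experiments without a condition label: {missing}")
    by_cond: dict[str, list[str]] = {}
    for exp, cond in condition_groups.items():
        if exp in fc.columns:
            by_cond.setdefault(cond, []).append(exp)
    too_small = [c for c, exps in by_cond.items() if len(exps) < 2]
    if too_small:
        raise ValueError(
            f"conditions with < 2 experiments (t-test impossible): {sorted(too_small)}"
        )
    combined = pd.DataFrame(
        {cond: fc[exps].mean(axis=1) for cond, exps in by_cond.items()}
    )
    replicates = {cond: fc[exps] for cond, exps in by_cond.items()}
    return combined, replicates


def one_sample_t_test(
    values: Sequence[float] | np.ndarray,
    mu0: float = 0.0,
    tail: str = "greater",
) -> tuple[float, float]:
    """One-sample Student t-test of mean(values) against mu0.

    t = (mean - mu0) / (sd / sqrt(n)) with n-1 degrees of freedom; the
    p-value is taken on the requested tail ('greater', 'less' or
    'two_sided').
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicates")
    if v.std(ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    alternative = {"greater": "greater", "less": "less", "two_sided": "two-sided"}[tail]
    res = stats.ttest_1samp(v, popmean=mu0, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_responsive(
    fc: pd.DataFrame,
    condition_groups: Mapping[str, str],
    config: ResponseConfig | None = None,
) -> pd.DataFrame:
    """Call induced/repressed genes per condition.

    For each gene and condition the replicate log2 fold-changes are averaged
    and tested against 0 on the tail matching the sign of the mean.  A gene
    is responsive when that one-tailed p < alpha and |mean log2FC| exceeds
    the threshold.  Zero-variance genes are reported untestable (p = NaN),
    never silently dropped.

    Returns a long-format frame with columns locus_id, condition,
    mean_log2fc, t_stat, p_value, direction, responsive, untestable.
    """
    config = config or ResponseConfig()
    combined, replicates = combine_fold_changes(fc, condition_groups)
    rows = []
    for cond, reps in replicates.items():
        arr = reps.to_numpy(dtype=float)
        means = arr.mean(axis=1)
        sds = arr.std(axis=1, ddof=1)
        n = arr.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(sds > 0, (means - 0.0) / (sds / np.sqrt(n)), np.nan)
        # one-tailed p on the side the observed mean favours
        p_up = stats.t.sf(tstat, df=n - 1)
        p_matched = np.where(means >= 0, p_up, 1.0 - p_up)
        p_matched = np.where(np.isnan(tstat), np.nan, p_matched)
        if config.bh_correct:
            ok = ~np.isnan(p_matched)
            adj = p_matched.copy()
            adj[ok] = _bh_adjust(p_matched[ok])
            p_matched = adj
        direction = np.where(means >= 0, "induced", "repressed")
        responsive = (
            (p_matched < config.alpha)
            & (np.abs(means) > config.log2fc_threshold)
            & ~np.isnan(p_matched)
        )
        for i, locus in enumerate(reps.index):
            rows.append(
                {
                    "locus_id": locus,
                    "condition": cond,
                    "mean_log2fc": float(means[i]),
                    "t_stat": float(tstat[i]) if not np.isnan(tstat[i]) else np.nan,
                    "p_value": float(p_matched[i]) if not np.isnan(p_matched[i]) else np.nan,
                    "direction": str(direction[i]),
                    "responsive": bool(responsive[i]),
                    "untestable": bool(np.isnan(p_matched[i])),
                }
            )
    return pd.DataFrame(rows)


class StressResponseCaller(BaseEstimator):
    """Responsive-gene caller over a log2 fold-change matrix.

    Parameters
    ----------
    alpha : float
        Raw one-tailed significance level (default 0.05).
    log2fc_threshold : float
        Minimum |combined log2 fold-change| (default 1.0 = two-fold).
    bh_correct : bool
        Apply Benjamini-Hochberg across genes within a condition.

    Attributes
    ----------
    calls_ : pandas.DataFrame   long-format per-gene/condition calls
    responsive_ : pandas.DataFrame   the responsive subset of ``calls_``
    """

    def __init__(
        self,
        alpha: float = 0.05,
        log2fc_threshold: float = 1.0,
        bh_correct: bool = False,
    ) -> None:
        self.alpha = alpha
        self.log2fc_threshold = log2fc_threshold
        self.bh_correct = bh_correct

    def fit(self, X: pd.DataFrame, y=None, *, condition_groups: Mapping[str, str]):
        config = ResponseConfig(
            alpha=self.alpha,
            log2fc_threshold=self.log2fc_threshold,
            bh_correct=self.bh_correct,
        )
        self.calls_ = call_responsive(X, condition_groups, config)
        self.responsive_ = self.calls_[self.calls_["responsive"]].reset_index(drop=True)
        return self
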