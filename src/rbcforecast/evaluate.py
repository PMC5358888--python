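"""Prediction scoring and train/test divergence diagnostics.

The error metric is the symmetric mean absolute percentage error over a
profile's time points,

    SMAPE = (1/n) * sum_t |y_t - yhat_t| / (y_t + yhat_t),

i.e. the per-point denominator is the plain sum of the two non-negative
values (no factor 1/2, no x100), so the score lives in [0, 1]: 0 for a
perfect prediction, 1 when prediction and measurement never overlap (e.g. a
zero forecast of a positive profile). Percentages are display formatting
only. A small epsilon guards the denominator so an exactly-zero pair
contributes 0, not 0/0.

Divergence between training and testing replicates is screened per
(metabolite, time point) with Welch two-sample t-tests, Benjamini–Hochberg
FDR adjustment over all tests jointly, and a practical-relevance gate on the
percent difference of the group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import MetabolomicsDataset, SplitAssignment
from .exceptions import AlignmentError, DomainError, InsufficientDataError

DEFAULT_EPSILON = 1e-12


def smape(measured, predicted, epsilon: float = DEFAULT_EPSILON) -> float:
    """Symmetric mean absolute percentage error on the [0, 1] scale.

    Accepts arrays or TimeSeries; both profiles must be non-negative and of
    equal length. Symmetric in its arguments and invariant to a common
    positive rescaling (away from the epsilon guard).
    """
    y = np.asarray(getattr(measured, "values", measured), dtype=float)
    yh = np.asarray(getattr(predicted, "values", predicted), dtype=float)
    if y.shape != yh.shape or y.ndim != 1 or len(y) < 1:
        raise AlignmentError(
            f"profiles must be equal-length 1-d arrays, got {y.shape} and {yh.shape}"
        )
    if (y < 0).any() or (yh < 0).any():
        raise DomainError("SMAPE is defined for non-negative profiles only")
    denom = np.maximum(y + yh, epsilon)
    return float(np.mean(np.abs(y - yh) / denom))


@dataclass(frozen=True)
class EvaluationSummary:
    """Per-metabolite mean SMAPEs and their global median/dispersion.

    ``per_metabolite`` columns: metabolite_id, mean_smape, sd_smape,
    n_replicates. The global statistic is the median of per-metabolite mean
    SMAPEs, with the sample standard deviation of those means as the
    dispersion (one convention among several; it is labelled as sd wherever
    reported).
    """

    per_metabolite: pd.DataFrame
    distributions: dict[str, np.ndarray]
    global_median: float
    global_sd: float
    n_timepoints: int


def summarize(results: Sequence, n_timepoints: int | None = None) -> EvaluationSummary:
    """Aggregate PredictionResults: per-target mean SMAPE, global median ± sd."""
    if len(results) == 0:
        raise InsufficientDataError("summarize requires at least one result")
    rows = []
    dists: dict[str, np.ndarray] = {}
    for res in results:
        scores = np.array(
            [res.smape_by_replicate[r] for r in res.replicate_ids], dtype=float
        )
        dists[res.target_id] = scores
        rows.append(
            {
                "metabolite_id": res.target_id,
                "mean_smape": float(scores.mean()),
                "sd_smape": float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
                "n_replicates": len(scores),
            }
        )
    per_met = pd.DataFrame(rows)
    means = per_met["mean_smape"].to_numpy()
    if n_timepoints is None:
        first = results[0]
        n_timepoints = len(first.consensus[first.replicate_ids[0]])
    return EvaluationSummary(
        per_metabolite=per_met,
        distributions=dists,
        global_median=float(np.median(means)),
        global_sd=float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        n_timepoints=int(n_timepoints),
    )


@dataclass(frozen=True)
class DivergenceReport:
    """Per-(metabolite, time) train-vs-test comparison.

    ``table`` columns: metabolite_id, time_days, pct_diff, p_raw, p_adj,
    flagged. A cell is flagged iff its FDR-adjusted p-value is below alpha
    *and* the percent difference of means exceeds the threshold.
    ``flagged_fraction`` is the share of all cells flagged.
    """

    table: pd.DataFrame
    alpha: float
    mean_diff_threshold: float

    @property
    def flagged_fraction(self) -> float:
        return float(self.table["flagged"].mean())


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        # degenerate: both sides constant; identical means are perfectly
        # consistent with the null, differing means reject it outright
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def compare_train_test(
    ds: MetabolomicsDataset,
    split: SplitAssignment,
    alpha: float = 0.05,
    mean_diff_threshold: float = 0.20,
) -> DivergenceReport:
    """Screen every (metabolite, time) cell for train/test divergence.

    Welch t-test per cell, Benjamini–Hochberg adjustment over all cells
    jointly; the percent difference of means is relative to the pooled mean,
    ``|m_tr - m_te| / ((m_tr + m_te)/2)``. Flags require both statistical
    (adjusted p < alpha) and practical (pct_diff > threshold) divergence.
    """
    tr_idx = [ds.replicate_index(r) for r in split.training_replicates]
    te_idx = [ds.replicate_index(r) for r in split.testing_replicates]
    if min(len(tr_idx), len(te_idx)) < 2:
        raise InsufficientDataError("need >= 2 replicates on each side")
    rows = []
    for i, mid in enumerate(ds.metabolite_ids):
        for t, day in enumerate(ds.time_days):
            a = ds.concentrations[i, tr_idx, t]
            b = ds.concentrations[i, te_idx, t]
            centre = (a.mean() + b.mean()) / 2.0
            pct = abs(a.mean() - b.mean()) / centre if centre > 0 else 0.0
            rows.append(
                {
                    "metabolite_id": mid,
                    "time_days": float(day),
                    "pct_diff": pct,
                    "p_raw": _welch_p(a, b),
                }
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")[1]
    if np.isfinite(mean_diff_threshold):
        practical = table["pct_diff"].to_numpy() > mean_diff_threshold
    else:
        practical = np.zeros(len(table), dtype=bool)
    table["flagged"] = (table["p_adj"].to_numpy() < alpha) & practical
    return DivergenceReport(table=table, alpha=alpha, mean_diff_threshold=mean_diff_threshold)
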