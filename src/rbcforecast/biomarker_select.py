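"""Exhaustive biomarker-subset selection by leave-one-replicate-out CV.

Every size-k subset of the candidate biomarkers is scored by cross-validation
over the *training* replicates only: each fold holds out one whole replicate,
trains per-replicate ensembles on the remaining replicates with the subset as
model inputs, predicts the held-out replicate's target metabolites from its
biomarkers alone, and scores the consensus by SMAPE. Holding out whole
replicates keeps each time series intact — splitting within a profile would
leak temporal information across folds. The subset score averages uniformly
over folds and target metabolites.

Candidate biomarkers outside the subset under evaluation are excluded from
the target pool: they are competing inputs, not forecasting targets, and
scoring them would let subsets be rewarded for predicting their rivals.

The fitting in each fold uses the batched FIR solve (one regressor matrix per
held-in replicate serves every target), which is numerically identical to
fitting each target separately.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import MetabolomicsDataset
from .exceptions import InsufficientDataError, UsageError
from .oe_sysid import OEModelSpec, design_matrix, fit_oe_multi

from dataclasses import dataclass


@dataclass(frozen=True)
class SubsetCVResult:
    """Cross-validation outcome for one candidate subset."""

    subset: tuple[str, ...]
    mean_smape: float
    fold_scores: tuple[float, ...]  # mean over targets, one per fold
    rank: int | None = None


@dataclass(frozen=True)
class SelectionResult:
    """Chosen subset plus the full ranked score table.

    ``within_tolerance`` lists every subset whose mean SMAPE is within the
    absolute tolerance of the best, supporting "within 1 percentage point of
    the top performer" style reasoning.
    """

    chosen: tuple[str, ...]
    table: pd.DataFrame
    within_tolerance: tuple[tuple[str, ...], ...]


def enumerate_subsets(candidates: Sequence[str], k: int) -> list[tuple[str, ...]]:
    """All size-k subsets of the candidates, lexicographic, no duplicates."""
    cands = sorted(candidates)
    if len(set(cands)) != len(cands):
        raise UsageError("candidate ids must be unique")
    if not 1 <= k <= len(cands):
        raise UsageError(f"k={k} out of range for {len(cands)} candidates")
    return list(combinations(cands, k))


def _fold_score(
    ds: MetabolomicsDataset,
    held_in: Sequence[str],
    held_out: str,
    subset: Sequence[str],
    target_ids: Sequence[str],
    spec: OEModelSpec,
    epsilon: float = 1e-12,
) -> np.ndarray:
    """Per-target SMAPE of the consensus prediction for one held-out replicate."""
    t_idx = [ds.metabolite_index(t) for t in target_ids]
    preds = []
    for rep in held_in:
        inputs = ds.biomarker_series(rep, subset)
        r_idx = ds.replicate_index(rep)
        Y = ds.concentrations[t_idx, r_idx, :].T  # (T, n_targets)
        B, intercepts = fit_oe_multi(spec, inputs, Y)
        X_out = design_matrix(spec, ds.biomarker_series(held_out, subset))
        if spec.include_intercept:
            yhat = X_out[:, :-1] @ B.T + intercepts[None, :]
        else:
            yhat = X_out @ B.T
        preds.append(yhat)  # (T, n_targets)
    consensus = np.clip(np.median(np.stack(preds), axis=0), 0.0, None)
    ho_idx = ds.replicate_index(held_out)
    measured = ds.concentrations[t_idx, ho_idx, :].T
    term = np.abs(measured - consensus) / np.maximum(measured + consensus, epsilon)
    return term.mean(axis=0)  # per-target SMAPE


def cross_validate_subset(
    ds: MetabolomicsDataset,
    training_replicates: Sequence[str],
    subset: Sequence[str],
    spec: OEModelSpec,
    candidates: Sequence[str] | None = None,
) -> SubsetCVResult:
    """Leave-one-replicate-out CV score of one biomarker subset.

    ``candidates`` defaults to the dataset's designated biomarkers; all
    candidates (in or out of the subset) are excluded from the target pool.
    """
    if len(training_replicates) < 2:
        raise InsufficientDataError("cross-validation requires >= 2 training replicates")
    cand = set(ds.biomarker_ids if candidates is None else candidates) | set(subset)
    target_ids = [m for m in ds.metabolite_ids if m not in cand]
    if not target_ids:
        raise UsageError("no target metabolites remain outside the candidate set")
    subset = tuple(subset)
    per_target_scores = []
    for held_out in training_replicates:
        held_in = [r for r in training_replicates if r != held_out]
        per_target_scores.append(
            _fold_score(ds, held_in, held_out, subset, target_ids, spec)
        )
    folds = np.stack(per_target_scores)  # (n_folds, n_targets)
    return SubsetCVResult(
        subset=subset,
        mean_smape=float(folds.mean()),
        fold_scores=tuple(float(s) for s in folds.mean(axis=1)),
    )


def select_biomarkers(
    ds: MetabolomicsDataset,
    training_replicates: Sequence[str],
    candidates: Sequence[str],
    k: int,
    spec: OEModelSpec,
    tolerance: float = 0.01,
) -> SelectionResult:
    """Exhaustively score every size-k subset and pick the best.

    Ties break lexicographically. ``tolerance`` is absolute on the [0, 1]
    SMAPE scale; the result also carries every subset scoring within
    tolerance of the winner.
    """
    subsets = enumerate_subsets(candidates, k)
    results = [
        cross_validate_subset(ds, training_replicates, s, spec, candidates=candidates)
        for s in subsets
    ]
    order = sorted(range(len(results)), key=lambda i: (results[i].mean_smape, subsets[i]))
    best_score = results[order[0]].mean_smape
    rows = []
    within: list[tuple[str, ...]] = []
    for rank, i in enumerate(order, start=1):
        in_tol = results[i].mean_smape <= best_score + tolerance
        if in_tol:
            within.append(subsets[i])
        rows.append(
            {
                "subset_members": ";".join(subsets[i]),
                "mean_smape": results[i].mean_smape,
                "rank": rank,
                "within_tolerance": in_tol,
            }
        )
    return SelectionResult(
        chosen=subsets[order[0]],
        table=pd.DataFrame(rows),
        within_tolerance=tuple(within),
    )
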