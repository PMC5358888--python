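"""Per-replicate model ensembles with median-consensus prediction.

For each target metabolite, one OE model is fitted per *training* replicate
(biomarkers of that replicate as inputs, the target's profile as output). At
prediction time every member is run on a test replicate's biomarker profiles
and the per-time-point median of the member outputs is the consensus
prediction. The median (even member count: mean of the two central values)
captures between-bag biological variability while remaining robust to
individual unstable members.

Prediction sees biomarkers only; measured target profiles enter solely
through scoring, so test-set information cannot leak into the forecast.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import MetabolomicsDataset, SplitAssignment
from .evaluate import smape
from .exceptions import AlignmentError, RBCForecastError, UsageError
from .oe_sysid import OEModel, OEModelSpec, TimeSeries, fit_oe, load_model, save_model


@dataclass(frozen=True)
class EnsembleModel:
    """One fitted OE model per training replicate for a single target."""

    target_id: str
    members: tuple[tuple[str, OEModel], ...]  # (replicate_id, model), training order
    spec: OEModelSpec
    biomarker_ids: tuple[str, ...]

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PredictionResult:
    """Consensus predictions for one target over a set of test replicates.

    ``member_predictions[rep]`` stacks each member's simulated profile
    (n_members, T); ``consensus[rep]`` is their per-time-point median.
    ``smape_by_replicate`` scores the consensus against each replicate's
    measurement when measurements were supplied; ``summary_smape`` is their
    mean over replicates.
    """

    target_id: str
    replicate_ids: tuple[str, ...]
    member_predictions: Mapping[str, np.ndarray]
    consensus: Mapping[str, TimeSeries]
    measured: Mapping[str, TimeSeries] | None = None
    smape_by_replicate: Mapping[str, float] | None = None
    summary_smape: float | None = None


def train_ensemble(
    ds: MetabolomicsDataset,
    split: SplitAssignment,
    target_id: str,
    spec: OEModelSpec,
    biomarker_ids: Sequence[str] | None = None,
) -> EnsembleModel:
    """Fit one OE model per training replicate for ``target_id``.

    Inputs default to the dataset's designated biomarker panel; member order
    follows the training-replicate order of the split. Fit failures are
    re-raised naming the offending replicate.
    """
    input_ids = tuple(ds.biomarker_ids if biomarker_ids is None else biomarker_ids)
    if target_id in input_ids:
        raise UsageError(
            f"{target_id!r} is a model input (biomarker); it cannot be an "
            "ensemble target"
        )
    members = []
    for rep in split.training_replicates:
        inputs = ds.biomarker_series(rep, input_ids)
        output = ds.series(target_id, rep)
        try:
            model = fit_oe(spec, inputs, output, input_ids=input_ids)
        except RBCForecastError as exc:
            raise type(exc)(
                f"fitting target {target_id!r} on replicate {rep!r}: {exc}"
            ) from exc
        members.append((rep, model))
    return EnsembleModel(
        target_id=target_id,
        members=tuple(members),
        spec=spec,
        biomarker_ids=input_ids,
    )


def predict_consensus(
    em: EnsembleModel,
    test_biomarkers: Mapping[str, Sequence[TimeSeries]],
    measured: Mapping[str, TimeSeries] | None = None,
) -> PredictionResult:
    """Median-consensus prediction for each test replicate's biomarkers.

    ``test_biomarkers`` maps replicate id -> one input TimeSeries per
    biomarker (in the ensemble's input order). When ``measured`` profiles are
    supplied they are attached and the consensus is scored by SMAPE against
    each replicate's measurement.
    """
    from .oe_sysid import simulate

    member_predictions: dict[str, np.ndarray] = {}
    consensus: dict[str, TimeSeries] = {}
    scores: dict[str, float] = {}
    rep_ids = tuple(test_biomarkers)
    for rep in rep_ids:
        inputs = test_biomarkers[rep]
        preds = np.stack(
            [simulate(model, inputs).values for _, model in em.members]
        )
        grid = inputs[0].times
        member_predictions[rep] = preds
        cons = TimeSeries(grid, np.median(preds, axis=0))
        consensus[rep] = cons
        if measured is not None:
            meas = measured[rep]
            if not np.array_equal(meas.times, grid):
                raise AlignmentError(
                    f"measured grid for replicate {rep!r} does not match inputs"
                )
            # SMAPE is defined for non-negative profiles; the consensus of a
            # non-negativity-agnostic linear model is clipped for scoring only
            scores[rep] = smape(meas.values, np.clip(cons.values, 0.0, None))
    return PredictionResult(
        target_id=em.target_id,
        replicate_ids=rep_ids,
        member_predictions=member_predictions,
        consensus=consensus,
        measured=dict(measured) if measured is not None else None,
        smape_by_replicate=scores if measured is not None else None,
        summary_smape=float(np.mean(list(scores.values()))) if scores else None,
    )


def predict_for_split(
    em: EnsembleModel, ds: MetabolomicsDataset, replicate_ids: Sequence[str]
) -> PredictionResult:
    """Convenience: predict and score against a dataset's test replicates."""
    biomarkers = {r: ds.biomarker_series(r, em.biomarker_ids) for r in replicate_ids}
    measured = {r: ds.series(em.target_id, r) for r in replicate_ids}
    return predict_consensus(em, biomarkers, measured)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_ensemble(em: EnsembleModel, directory: str | Path) -> None:
    """One model file per member in a directory named after the target."""
    d = Path(directory) / em.target_id
    d.mkdir(parents=True, exist_ok=True)
    for idx, (rep, model) in enumerate(em.members):
        save_model(model, d / f"member_{idx:02d}_{rep}.json")


def predictions_to_frame(results: Sequence[PredictionResult]) -> pd.DataFrame:
    """Tidy export: target_id, replicate_id, time_days, consensus, measured,
    smape_of_replicate."""
    rows = []
    for res in results:
        for rep in res.replicate_ids:
            cons = res.consensus[rep]
            meas = res.measured[rep].values if res.measured else np.full(len(cons), np.nan)
            sc = res.smape_by_replicate.get(rep) if res.smape_by_replicate else np.nan
            for t, c, m in zip(cons.times, cons.values, meas):
                rows.append(
                    {
                        "target_id": res.target_id,
                        "replicate_id": rep,
                        "time_days": t,
                        "consensus": c,
                        "measured": m,
                        "smape_of_replicate": sc,
                    }
                )
    return pd.DataFrame(rows)
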