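"""Output-Error (OE) model representation, simulation, and estimation.

An OE model expresses an output signal as a sum of rational transfer functions
of measured inputs plus an output-equation disturbance:

    y(t) = sum_i [B_i(q) / F_i(q)] u_i(t - nk) + e(t)

with polynomials in the backward shift operator ``q`` (``(q^-1 x)(t) = x(t-1)``,
acting on *sample index*, not clock time):

    B(q) = b_1 + b_2 q^-1 + ... + b_nb q^-(nb-1)
    F(q) = 1 + f_1 q^-1 + ... + f_nf q^-nf

With ``nf = 0`` every F polynomial is identically 1 and the model reduces to a
finite-impulse-response (FIR) form, linear in its coefficients, so least-squares
estimation has a closed form: ordinary linear regression of the output on
lagged inputs. Simulation supports ``nf > 0``; estimation deliberately does not
(iterative prediction-error minimisation is out of scope — the pipeline's
selected configuration is ``nb=1, nf=0, nk=0``, i.e. static linear mixing).

Pre-sample values of inputs and outputs are taken as zero (zero initial
conditions), both in simulation and in the regression rows built for fitting,
so the two are mutually consistent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import (
    AlignmentError,
    InsufficientDataError,
    UnsupportedSpecError,
    UsageError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeSeries:
    """A sampled signal: strictly increasing times (days) and matching values."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise AlignmentError("times and values must be one-dimensional")
        if len(self.times) != len(self.values):
            raise AlignmentError(
                f"times (n={len(self.times)}) and values (n={len(self.values)}) "
                "differ in length"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise AlignmentError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class OEModelSpec:
    """Model orders for an OE model with ``n_inputs`` inputs.

    Parameters
    ----------
    n_inputs:
        Number of measured input signals (biomarkers).
    nb:
        Order of each B polynomial (number of numerator coefficients per input).
    nf:
        Order of each F polynomial (0 gives the FIR family).
    nk:
        Input delay in samples, shared by all inputs.
    include_intercept:
        Add a constant term to the model. The canonical OE form has none;
        the flag exists because a no-lag, no-delay FIR model without intercept
        is exactly multiple linear regression through the origin, and the
        intercept variant is the natural "simple linear regression" comparator.
    """

    n_inputs: int
    nb: int = 1
    nf: int = 0
    nk: int = 0
    include_intercept: bool = False

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise UsageError("n_inputs must be >= 1")
        if self.nb < 1:
            raise UsageError("nb must be >= 1")
        if self.nf < 0 or self.nk < 0:
            raise UsageError("nf and nk must be >= 0")

    @property
    def n_free_coefficients(self) -> int:
        return self.n_inputs * (self.nb + self.nf) + int(self.include_intercept)


@dataclass(frozen=True)
class OEModel:
    """A fitted/specified OE model.

    ``b`` has shape (n_inputs, nb); ``f`` has shape (n_inputs, nf) and is empty
    when nf = 0 (each F polynomial identically 1). ``input_ids`` fixes the
    input ordering the coefficient rows refer to.
    """

    spec: OEModelSpec
    b: np.ndarray
    f: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    intercept: float = 0.0
    input_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        b = np.atleast_2d(np.asarray(self.b, dtype=float))
        object.__setattr__(self, "b", b)
        f = np.asarray(self.f, dtype=float).reshape(self.spec.n_inputs, self.spec.nf)
        object.__setattr__(self, "f", f)
        if b.shape != (self.spec.n_inputs, self.spec.nb):
            raise UsageError(
                f"b has shape {b.shape}, spec requires "
                f"({self.spec.n_inputs}, {self.spec.nb})"
            )
        if self.input_ids and len(self.input_ids) != self.spec.n_inputs:
            raise UsageError("input_ids length must equal n_inputs")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _check_common_grid(inputs: Sequence[TimeSeries]) -> np.ndarray:
    grid = inputs[0].times
    for ts in inputs[1:]:
        if not np.array_equal(ts.times, grid):
            raise AlignmentError("all input series must share one time grid")
    return grid


def simulate(model: OEModel, inputs: Sequence[TimeSeries]) -> TimeSeries:
    """Noise-free simulation of the OE model on the inputs' shared grid.

    Computes ``yhat(t) = sum_i [B_i(q)/F_i(q)] u_i(t - nk) + intercept``
    recursively by sample index, with pre-sample input and output values
    taken as zero.
    """
    spec = model.spec
    if len(inputs) != spec.n_inputs:
        raise AlignmentError(
            f"model expects {spec.n_inputs} inputs, got {len(inputs)}"
        )
    grid = _check_common_grid(inputs)
    T = len(grid)
    if T <= max(spec.nk + spec.nb - 1, spec.nf):
        raise InsufficientDataError(
            f"grid of length {T} too short for orders "
            f"(nb={spec.nb}, nf={spec.nf}, nk={spec.nk})"
        )

    yhat = np.full(T, model.intercept, dtype=float)
    for i, ts in enumerate(inputs):
        u = ts.values
        # FIR part: x_i(t) = sum_j b_ij u_i(t - nk - j + 1), zeros pre-sample
        x = np.zeros(T)
        for j in range(spec.nb):
            lag = spec.nk + j
            if lag < T:
                x[lag:] += model.b[i, j] * u[: T - lag]
        if spec.nf == 0:
            yhat += x
        else:
            # y_i(t) = x_i(t) - sum_k f_ik y_i(t-k), zero initial conditions
            yi = np.zeros(T)
            for t in range(T):
                acc = x[t]
                for k in range(1, spec.nf + 1):
                    if t - k >= 0:
                        acc -= model.f[i, k - 1] * yi[t - k]
                yi[t] = acc
            yhat += yi
    return TimeSeries(grid, yhat)


# ---------------------------------------------------------------------------
# Estimation (FIR family, nf = 0)
# ---------------------------------------------------------------------------

def design_matrix(spec: OEModelSpec, inputs: Sequence[TimeSeries]) -> np.ndarray:
    """Lagged-input regressor matrix for the FIR (nf = 0) family.

    Column order: input-major, lag-minor — (u_1 lag 0 .. lag nb-1, u_2 ...),
    then the intercept column when enabled. Rows touching pre-sample lags use
    zeros, matching :func:`simulate`'s zero initial conditions. The matrix
    depends only on the inputs, never on the output, so one matrix serves any
    number of outputs measured on the same grid.
    """
    if spec.nf != 0:
        raise UnsupportedSpecError("design matrix defined only for nf = 0")
    grid = _check_common_grid(inputs)
    T = len(grid)
    cols = []
    for ts in inputs:
        u = ts.values
        for j in range(spec.nb):
            lag = spec.nk + j
            col = np.zeros(T)
            if lag < T:
                col[lag:] = u[: T - lag]
            cols.append(col)
    if spec.include_intercept:
        cols.append(np.ones(T))
    return np.column_stack(cols)


def _solve_lstsq(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Minimum-norm least squares; warns once on rank deficiency."""
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        logger.warning(
            "rank-deficient regression (rank %d < %d columns); "
            "returning the minimum-norm solution",
            rank,
            X.shape[1],
        )
    return coef


def fit_oe(
    spec: OEModelSpec,
    inputs: Sequence[TimeSeries],
    output: TimeSeries,
    input_ids: Sequence[str] = (),
) -> OEModel:
    """Least-squares estimate of an FIR-family (nf = 0) OE model.

    Minimises ``sum_t (y(t) - yhat(t))^2`` where ``yhat`` is exactly what
    :func:`simulate` produces; solved in closed form by regressing the output
    on lagged inputs. Rank-deficient problems return the minimum-norm solution
    with a logged warning rather than erroring: collinear biomarkers are
    plausible and the downstream ensemble median damps unstable members.
    """
    if spec.nf != 0:
        raise UnsupportedSpecError(
            "least-squares fitting supports only nf = 0 (FIR family); "
            "simulation supports nf > 0"
        )
    if len(inputs) != spec.n_inputs:
        raise AlignmentError(
            f"spec expects {spec.n_inputs} inputs, got {len(inputs)}"
        )
    grid = _check_common_grid(inputs)
    if not np.array_equal(output.times, grid):
        raise AlignmentError("output grid does not match input grid")
    if len(grid) < spec.n_free_coefficients:
        raise InsufficientDataError(
            f"{len(grid)} samples < {spec.n_free_coefficients} free coefficients"
        )
    X = design_matrix(spec, inputs)
    coef = _solve_lstsq(X, output.values)
    if spec.include_intercept:
        b, intercept = coef[:-1], float(coef[-1])
    else:
        b, intercept = coef, 0.0
    return OEModel(
        spec=spec,
        b=b.reshape(spec.n_inputs, spec.nb),
        f=np.empty((spec.n_inputs, 0)),
        intercept=intercept,
        input_ids=tuple(input_ids),
    )


def fit_oe_multi(
    spec: OEModelSpec, inputs: Sequence[TimeSeries], outputs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fit many outputs sharing one input set in a single batched solve.

    ``outputs`` has shape (T, n_outputs). Because the regressor matrix depends
    only on the inputs, solving all outputs jointly is numerically identical to
    calling :func:`fit_oe` per output. Returns ``(B, intercepts)`` with ``B``
    of shape (n_outputs, n_inputs * nb).
    """
    if spec.nf != 0:
        raise UnsupportedSpecError("batched fitting supports only nf = 0")
    X = design_matrix(spec, inputs)
    if X.shape[0] < spec.n_free_coefficients:
        raise InsufficientDataError(
            f"{X.shape[0]} samples < {spec.n_free_coefficients} free coefficients"
        )
    coef = _solve_lstsq(X, np.asarray(outputs, dtype=float))
    if spec.include_intercept:
        return coef[:-1].T, coef[-1].copy()
    return coef.T, np.zeros(coef.shape[1])


# ---------------------------------------------------------------------------
# Model-order selection
# ---------------------------------------------------------------------------

def select_model_order(
    candidate_specs: Sequence[OEModelSpec],
    ds,
    training_replicates: Sequence[str],
    target_ids: Sequence[str] | None = None,
):
    """Pick the model order with the lowest leave-one-replicate-out CV SMAPE.

    Each candidate spec is evaluated by the same cross-validation scheme used
    for biomarker-subset selection: for each held-out training replicate,
    per-replicate ensembles are fitted on the remaining replicates and their
    median-consensus predictions scored against the held-out measurements.
    Ties break toward fewer free coefficients, then candidate order.

    Returns ``(best_spec, table)`` where ``table`` is a DataFrame with one row
    per candidate (spec fields, mean_smape, rank).
    """
    import pandas as pd

    from .biomarker_select import cross_validate_subset  # local: avoid cycle

    if len(candidate_specs) < 1:
        raise UsageError("need at least one candidate spec")
    rows = []
    for pos, spec in enumerate(candidate_specs):
        res = cross_validate_subset(
            ds, training_replicates, ds.biomarker_ids, spec,
            candidates=ds.biomarker_ids,
        )
        rows.append(
            {
                "nb": spec.nb,
                "nf": spec.nf,
                "nk": spec.nk,
                "include_intercept": spec.include_intercept,
                "n_free_coefficients": spec.n_free_coefficients,
                "mean_smape": res.mean_smape,
                "_pos": pos,
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["mean_smape", "n_free_coefficients", "_pos"], kind="mergesort"
    ).index
    table["rank"] = 0
    table.loc[order, "rank"] = np.arange(1, len(table) + 1)
    best = candidate_specs[int(table.loc[order[0], "_pos"])]
    return best, table.drop(columns="_pos")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: OEModel, path: str | Path) -> None:
    """Write a model to a plain-text JSON file at full float precision."""
    doc = {
        "spec": {
            "n_inputs": model.spec.n_inputs,
            "nb": model.spec.nb,
            "nf": model.spec.nf,
            "nk": model.spec.nk,
            "include_intercept": model.spec.include_intercept,
        },
        "input_ids": list(model.input_ids),
        "b": model.b.tolist(),
        "f": model.f.tolist(),
        "intercept": model.intercept,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_model(path: str | Path) -> OEModel:
    """Read a model written by :func:`save_model`; round-trip is exact."""
    doc = json.loads(Path(path).read_text())
    spec = OEModelSpec(**doc["spec"])
    return OEModel(
        spec=spec,
        b=np.array(doc["b"], dtype=float).reshape(spec.n_inputs, spec.nb),
        f=np.array(doc["f"], dtype=float).reshape(spec.n_inputs, spec.nf),
        intercept=float(doc["intercept"]),
        input_ids=tuple(doc["input_ids"]),
    )
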