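"""Replicate-resolved metabolite concentration time courses.

The dataset is a complete cube of concentrations indexed by
(metabolite, replicate, time) on a single shared time grid, with a subset of
metabolites designated as biomarkers (the model inputs). Missing cells are a
hard load error, never imputed: every downstream statistic assumes a complete
grid, and the shift operator of the dynamic model indexes by sample, so all
replicates must share the grid exactly.

Metabolites are uniquely keyed by (metabolite_id, compartment); the same
compound measured intracellularly and extracellularly is two entries. Lookups
by bare metabolite_id raise if the id is ambiguous across compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataFormatError,
    DomainError,
    IncompleteDataError,
    InsufficientDataError,
    UnknownIdentifierError,
)
from .oe_sysid import TimeSeries

CSV_COLUMNS = ["metabolite_id", "compartment", "replicate_id", "time_days", "concentration"]
COMPARTMENTS = ("intracellular", "extracellular")

INTRACELLULAR = "intracellular"
EXTRACELLULAR = "extracellular"


@dataclass(frozen=True)
class MetabolomicsDataset:
    """Complete concentration cube with biomarker designations.

    ``concentrations`` has shape (n_metabolites, n_replicates, n_times) and is
    aligned with ``metabolite_ids``/``compartments``, ``replicate_ids`` and
    ``time_days``. Concentration units are opaque to the pipeline. Target
    metabolites are all metabolites not designated as biomarkers.
    """

    metabolite_ids: tuple[str, ...]
    compartments: tuple[str, ...]
    replicate_ids: tuple[str, ...]
    time_days: np.ndarray
    concentrations: np.ndarray
    biomarker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        object.__setattr__(self, "compartments", tuple(self.compartments))
        object.__setattr__(self, "replicate_ids", tuple(self.replicate_ids))
        object.__setattr__(self, "biomarker_ids", tuple(self.biomarker_ids))
        object.__setattr__(self, "time_days", np.asarray(self.time_days, dtype=float))
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )
        n_m, n_r, n_t = (
            len(self.metabolite_ids),
            len(self.replicate_ids),
            len(self.time_days),
        )
        if len(self.compartments) != n_m:
            raise DataFormatError("one compartment label required per metabolite")
        bad = set(self.compartments) - set(COMPARTMENTS)
        if bad:
            raise DataFormatError(f"unknown compartment labels: {sorted(bad)}")
        if self.concentrations.shape != (n_m, n_r, n_t):
            raise IncompleteDataError(
                f"concentration cube shape {self.concentrations.shape} does not "
                f"match ({n_m}, {n_r}, {n_t})"
            )
        if np.isnan(self.concentrations).any():
            raise IncompleteDataError("concentration cube contains missing values")
        if len(self.time_days) > 1 and not np.all(np.diff(self.time_days) > 0):
            raise DataFormatError("time_days must be strictly increasing")
        if (self.concentrations < 0).any():
            raise DomainError("concentrations must be non-negative")
        keys = list(zip(self.metabolite_ids, self.compartments))
        if len(set(keys)) != len(keys):
            raise DataFormatError("(metabolite_id, compartment) keys must be unique")
        if len(set(self.replicate_ids)) != len(self.replicate_ids):
            raise DataFormatError("replicate ids must be unique")
        for bid in self.biomarker_ids:
            self.metabolite_index(bid)  # raises if absent or ambiguous

    # -- lookups -----------------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    @property
    def n_timepoints(self) -> int:
        return len(self.time_days)

    @property
    def target_ids(self) -> tuple[str, ...]:
        """Metabolites that are prediction targets (non-biomarkers), in order."""
        bm = set(self.biomarker_ids)
        return tuple(m for m in self.metabolite_ids if m not in bm)

    def metabolite_index(self, metabolite_id: str) -> int:
        hits = [i for i, m in enumerate(self.metabolite_ids) if m == metabolite_id]
        if not hits:
            raise UnknownIdentifierError(f"unknown metabolite id {metabolite_id!r}")
        if len(hits) > 1:
            raise UnknownIdentifierError(
                f"metabolite id {metabolite_id!r} is ambiguous across compartments"
            )
        return hits[0]

    def replicate_index(self, replicate_id: str) -> int:
        try:
            return self.replicate_ids.index(replicate_id)
        except ValueError:
            raise UnknownIdentifierError(
                f"unknown replicate id {replicate_id!r}"
            ) from None

    def profile(self, metabolite_id: str, replicate_id: str) -> np.ndarray:
        return self.concentrations[
            self.metabolite_index(metabolite_id), self.replicate_index(replicate_id)
        ]

    def series(self, metabolite_id: str, replicate_id: str) -> TimeSeries:
        return TimeSeries(self.time_days, self.profile(metabolite_id, replicate_id))

    def biomarker_series(
        self, replicate_id: str, biomarker_ids: Sequence[str] | None = None
    ) -> list[TimeSeries]:
        """One input TimeSeries per biomarker, in panel order."""
        ids = self.biomarker_ids if biomarker_ids is None else biomarker_ids
        return [self.series(b, replicate_id) for b in ids]

    def with_biomarkers(self, biomarker_ids: Sequence[str]) -> "MetabolomicsDataset":
        return replace(self, biomarker_ids=tuple(biomarker_ids))


@dataclass(frozen=True)
class SplitAssignment:
    """A seeded random partition of replicates into training and testing sets."""

    training_replicates: tuple[str, ...]
    testing_replicates: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "training_replicates", tuple(self.training_replicates)
        )
        object.__setattr__(self, "testing_replicates", tuple(self.testing_replicates))
        if set(self.training_replicates) & set(self.testing_replicates):
            raise DataFormatError("training and testing sets must be disjoint")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_dataset(path: str | Path, biomarker_ids: Sequence[str]) -> MetabolomicsDataset:
    """Load a tidy concentration CSV into a complete dataset.

    Expects columns metabolite_id, compartment, replicate_id, time_days,
    concentration; row order is irrelevant. Raises on missing columns,
    missing or duplicate (metabolite, replicate, time) cells, negative
    concentrations, and biomarker ids absent from the data.
    """
    path = Path(path)
    # round_trip parsing: written values must reload to the identical float64
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    if df["concentration"].isna().any():
        raise IncompleteDataError(f"{path}: empty concentration cells")
    if (df["concentration"] < 0).any():
        raise DomainError(f"{path}: negative concentrations present")

    met_keys = df[["metabolite_id", "compartment"]].drop_duplicates()
    mets = [tuple(r) for r in met_keys.itertuples(index=False)]
    reps = sorted(df["replicate_id"].astype(str).unique())
    times = np.array(sorted(df["time_days"].unique()), dtype=float)

    cube = df.pivot_table(
        index=["metabolite_id", "compartment"],
        columns=["replicate_id", "time_days"],
        values="concentration",
        aggfunc="count",
    )
    if (cube != 1).any().any() or cube.isna().any().any():
        raise IncompleteDataError(
            f"{path}: (metabolite, replicate, time) grid is incomplete or has "
            "duplicate cells"
        )

    wide = df.set_index(["metabolite_id", "compartment", "replicate_id", "time_days"])[
        "concentration"
    ].sort_index()
    conc = np.empty((len(mets), len(reps), len(times)))
    for i, (mid, comp) in enumerate(mets):
        block = wide.loc[(mid, comp)].unstack("time_days")
        block = block.loc[[r for r in reps], list(times)]
        conc[i] = block.to_numpy()
    return MetabolomicsDataset(
        metabolite_ids=tuple(m for m, _ in mets),
        compartments=tuple(c for _, c in mets),
        replicate_ids=tuple(str(r) for r in reps),
        time_days=times,
        concentrations=conc,
        biomarker_ids=tuple(biomarker_ids),
    )


def write_dataset(ds: MetabolomicsDataset, path: str | Path) -> None:
    """Write the dataset as a tidy CSV; concentrations at float64 round-trip
    precision (17 significant digits)."""
    rows = {
        "metabolite_id": np.repeat(ds.metabolite_ids, ds.n_replicates * ds.n_timepoints),
        "compartment": np.repeat(ds.compartments, ds.n_replicates * ds.n_timepoints),
        "replicate_id": np.tile(
            np.repeat(ds.replicate_ids, ds.n_timepoints), ds.n_metabolites
        ),
        "time_days": np.tile(ds.time_days, ds.n_metabolites * ds.n_replicates),
        "concentration": ds.concentrations.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Quality control and splitting
# ---------------------------------------------------------------------------

def exclude_timepoints(
    ds: MetabolomicsDataset, excluded_days: Sequence[float]
) -> MetabolomicsDataset:
    """Drop the listed sampling days from the grid (exact match required).

    All other cells are unchanged. This is the explicit, user-driven path for
    removing a suspect time point (e.g. a storage-day with an acquisition
    artifact) flagged by :func:`flag_anomalous_timepoints`.
    """
    if len(excluded_days) == 0:
        return ds
    grid = list(ds.time_days)
    for day in excluded_days:
        if float(day) not in grid:
            raise UnknownIdentifierError(
                f"excluded day {day!r} is not on the sampling grid {grid}"
            )
    keep = np.array([t not in [float(d) for d in excluded_days] for t in grid])
    return replace(
        ds,
        time_days=ds.time_days[keep],
        concentrations=ds.concentrations[:, :, keep],
    )


def flag_anomalous_timepoints(
    ds: MetabolomicsDataset, cv_ratio_threshold: float = 3.0
) -> list[tuple[float, str]]:
    """Advisory screen for time points with outlying across-replicate spread.

    For each *extracellular* metabolite and time point the across-replicate
    coefficient of variation (CV) is computed; a time point is flagged when its
    CV exceeds ``cv_ratio_threshold`` times the median CV of that metabolite
    over all other time points. This is a heuristic reconstruction of manual
    artifact screening: it flags, it never excludes.

    Returns a list of (time_day, metabolite_id) flags.
    """
    if ds.n_replicates < 2:
        raise InsufficientDataError("anomaly flagging requires >= 2 replicates")
    flags: list[tuple[float, str]] = []
    for i, (mid, comp) in enumerate(zip(ds.metabolite_ids, ds.compartments)):
        if comp != EXTRACELLULAR:
            continue
        block = ds.concentrations[i]  # (n_rep, n_time)
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), 0.0)
        for t in range(ds.n_timepoints):
            others = np.delete(cv, t)
            ref = float(np.median(others)) if len(others) else 0.0
            # absolute floor guards numerically-zero CVs (identical replicates)
            if cv[t] > max(cv_ratio_threshold * ref, 1e-9):
                flags.append((float(ds.time_days[t]), mid))
    return flags


def split_replicates(ds: MetabolomicsDataset, seed: int) -> SplitAssignment:
    """Uniform random partition of replicates into equal halves.

    With an odd replicate count, training receives the extra replicate.
    Deterministic given the seed; the generator is dedicated to the split so
    other stochastic stages never perturb it.
    """
    if ds.n_replicates < 2:
        raise InsufficientDataError("splitting requires >= 2 replicates")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n_replicates)
    n_train = (ds.n_replicates + 1) // 2
    train = tuple(ds.replicate_ids[i] for i in sorted(perm[:n_train]))
    test = tuple(ds.replicate_ids[i] for i in sorted(perm[n_train:]))
    return SplitAssignment(train, test, seed)
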