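"""Synthetic stored-RBC metabolomics datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes, at the
dimensions of a typical storage study: 20 blood-bag replicates sampled on a
14-day nominal grid spanning 45 days of storage, ~96 metabolites of which 5
are designated extracellular biomarkers.

Biomarkers follow deterministic three-phase piecewise-linear templates in time
(the storage lesion's characteristic multi-phase decay/accumulation), with two
interior breakpoints per biomarker drawn once from the interior of the grid.
Each replicate ("blood bag") scales every profile by a multiplicative
lognormal bag factor, and measurements carry additive Gaussian noise
proportional to profile scale, truncated at zero.

Signal targets are static linear mixtures of the biomarker profiles — the
generative truth matches the pipeline's final model form (FIR with nb=1,
nf=0, nk=0), so parameter recovery is well-posed; an optional one-step lag
exercises input-delay handling. Noise targets are trend-free positive noise
around a constant and carry no biomarker information. An optional Day-31
artifact inflates the across-replicate dispersion of all extracellular
measurements at day 31 tenfold, mimicking a mid-storage acquisition artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .dataset import EXTRACELLULAR, INTRACELLULAR, MetabolomicsDataset
from .exceptions import SpecError

NOMINAL_DAYS = (0.0, 3.0, 7.0, 10.0, 14.0, 17.0, 21.0, 24.0, 28.0, 31.0, 35.0, 38.0, 42.0, 45.0)

ARTIFACT_DAY = 31.0
ARTIFACT_DISPERSION = 10.0


@dataclass(frozen=True)
class SynthSpec:
    """Generator configuration; defaults emulate the reference study's shape."""

    n_replicates: int = 20
    time_days: tuple[float, ...] = NOMINAL_DAYS
    n_biomarkers: int = 5
    n_signal_targets: int = 85
    n_noise_targets: int = 6
    coeff_range: tuple[float, float] = (0.2, 1.0)
    noise_sd: float = 0.05
    bag_sd: float = 0.1
    lag_mixing: bool = False  # one-step-lagged mixing (nk = 1) instead of static
    day31_artifact: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_replicates, self.n_biomarkers) < 1:
            raise SpecError("replicate and biomarker counts must be positive")
        if self.n_signal_targets < 0 or self.n_noise_targets < 0:
            raise SpecError("target counts must be non-negative")
        if self.noise_sd < 0 or self.bag_sd < 0:
            raise SpecError("noise_sd and bag_sd must be >= 0")
        t = np.asarray(self.time_days, dtype=float)
        if len(t) < 4 or not np.all(np.diff(t) > 0):
            raise SpecError("time grid must be strictly increasing with >= 4 points")
        lo, hi = self.coeff_range
        if lo > hi:
            raise SpecError("coeff_range must be (low, high) with low <= high")
        if max(abs(lo), abs(hi)) == 0:
            raise SpecError("coeff_range (0, 0) would generate all-zero targets")

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.time_days, dtype=float)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery oracles.

    ``coefficients`` maps each signal-target id to its true mixing weights
    (keyed by biomarker id); ``kinds`` labels every target "signal" or
    "noise"; ``bag_factors`` holds the per-replicate multiplicative effects;
    ``artifact_cells`` lists (time_day, metabolite_id) pairs carrying the
    planted dispersion artifact; ``breakpoints`` gives each biomarker
    template's two interior breakpoint days.
    """

    kinds: Mapping[str, str]
    coefficients: Mapping[str, Mapping[str, float]]
    bag_factors: Mapping[str, float]
    artifact_cells: tuple[tuple[float, str], ...] = ()
    breakpoints: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    templates: Mapping[str, np.ndarray] = field(default_factory=dict)


def biomarker_id(i: int) -> str:
    return f"BM{i + 1:02d}"


def _replicate_ids(n: int) -> tuple[str, ...]:
    return tuple(f"R{i + 1:02d}" for i in range(n))


# ---------------------------------------------------------------------------
# Biomarker templates and profiles
# ---------------------------------------------------------------------------

def _three_phase_template(
    grid: np.ndarray, rng: np.random.Generator, idx: int, n_biomarkers: int
) -> tuple[np.ndarray, tuple[float, float]]:
    """One monotone three-phase piecewise-linear template on the grid.

    Breakpoints sit on interior grid points, so a grid-knot change-point fit
    can localise them exactly on noiseless output. Each biomarker's first
    breakpoint is drawn from a window staggered across the storage period
    (different biomarkers transition in different phases of the lesion, which
    also keeps the panel's profiles mutually identifiable rather than
    collinear), and most of the total change is concentrated in one rotating
    phase, giving decay-then-plateau, plateau-then-decay, etc. shapes.
    Adjacent-phase slopes are re-drawn until they differ by >= 10% so all
    three phases are genuinely present.
    """
    T = len(grid)
    if T >= 10:
        start = 1 + (idx * (T - 6)) // max(1, n_biomarkers - 1)
        k1 = min(int(start + rng.integers(0, 2)), T - 4)
        k2 = int(rng.integers(k1 + 2, min(k1 + 7, T - 1)))
    else:
        k1 = int(rng.integers(1, max(2, T - 2)))
        k2 = int(rng.integers(k1 + 1, T - 1))
    decay = idx % 3 == 0
    scale = float(rng.uniform(5.0, 15.0))
    lo = scale * float(rng.uniform(0.05, 0.2))
    nodes_t = np.array([grid[0], grid[k1], grid[k2], grid[-1]])
    for _ in range(200):
        fracs = np.full(3, 0.075)
        fracs[idx % 3] = 0.85
        fracs = fracs + rng.uniform(-0.03, 0.03, size=3)
        fracs = fracs / fracs.sum()
        cum = np.concatenate([[0.0], np.cumsum(fracs)]) * (scale - lo)
        levels = scale - cum if decay else lo + cum
        slopes = np.diff(levels) / np.diff(nodes_t)
        ok = all(
            abs(abs(slopes[a]) - abs(slopes[b]))
            >= 0.10 * max(abs(slopes[a]), abs(slopes[b]))
            for a, b in ((0, 1), (1, 2))
        )
        if ok:
            break
    template = np.interp(grid, nodes_t, levels)
    return template, (float(grid[k1]), float(grid[k2]))


def generate_biomarkers(
    spec: SynthSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, tuple[float, float]], np.ndarray]:
    """Generate biomarker templates and per-replicate measured profiles.

    Returns ``(profiles, templates, bag_factors, breakpoints, grid)`` with
    ``profiles`` of shape (n_biomarkers, n_replicates, T) — template x
    lognormal bag factor plus truncated Gaussian noise at ``noise_sd`` x
    template scale — ``templates`` of shape (n_biomarkers, T), and one bag
    factor per replicate, shared by every profile of that bag.
    """
    grid = spec.grid
    T = len(grid)
    rng_t = np.random.default_rng(derive_seed(spec.seed, "biomarker-templates"))
    rng_n = np.random.default_rng(derive_seed(spec.seed, "biomarker-noise"))
    rng_b = np.random.default_rng(derive_seed(spec.seed, "bag-factors"))

    templates = np.empty((spec.n_biomarkers, T))
    breakpoints: dict[str, tuple[float, float]] = {}
    for i in range(spec.n_biomarkers):
        templates[i], breakpoints[biomarker_id(i)] = _three_phase_template(
            grid, rng_t, i, spec.n_biomarkers
        )

    bag_factors = rng_b.lognormal(mean=0.0, sigma=spec.bag_sd, size=spec.n_replicates)
    scales = templates.mean(axis=1)
    noise = rng_n.normal(
        0.0, 1.0, size=(spec.n_biomarkers, spec.n_replicates, T)
    ) * (spec.noise_sd * scales)[:, None, None]
    profiles = templates[:, None, :] * bag_factors[None, :, None] + noise
    return np.clip(profiles, 0.0, None), templates, bag_factors, breakpoints, grid


# ---------------------------------------------------------------------------
# Targets and dataset assembly
# ---------------------------------------------------------------------------

def generate_targets(
    spec: SynthSpec,
    biomarkers: tuple[np.ndarray, np.ndarray, np.ndarray, dict, np.ndarray] | None = None,
) -> tuple[MetabolomicsDataset, GroundTruth]:
    """Assemble the full synthetic dataset and its ground truth.

    Signal targets obey, per replicate r,
    ``y_r(t) = sum_i b*_i u_{i,r}(t - lag) + e_r(t)`` with ``b*`` drawn once
    per target from ``coeff_range`` (lag = 1 sample only when ``lag_mixing``),
    noise targets are positive noise around a bag-scaled constant, and all
    values are truncated at zero. Biomarkers are labelled extracellular;
    targets alternate deterministically between compartments.
    """
    if biomarkers is None:
        biomarkers = generate_biomarkers(spec)
    profiles, templates, bag_factors, breakpoints, grid = biomarkers
    T = len(grid)
    n_rep = spec.n_replicates

    rng_c = np.random.default_rng(derive_seed(spec.seed, "target-coefficients"))
    rng_e = np.random.default_rng(derive_seed(spec.seed, "target-noise"))
    rng_l = np.random.default_rng(derive_seed(spec.seed, "noise-target-levels"))

    bm_ids = [biomarker_id(i) for i in range(spec.n_biomarkers)]
    met_ids: list[str] = list(bm_ids)
    compartments: list[str] = [EXTRACELLULAR] * spec.n_biomarkers
    cube = [profiles]  # list of (n, n_rep, T) blocks

    # inputs used for mixing: contemporaneous, or one-sample lag with
    # zero pre-sample values (matching the FIR model's convention)
    if spec.lag_mixing:
        mixed_inputs = np.zeros_like(profiles)
        mixed_inputs[:, :, 1:] = profiles[:, :, :-1]
    else:
        mixed_inputs = profiles

    kinds: dict[str, str] = {}
    coefficients: dict[str, dict[str, float]] = {}

    lo, hi = spec.coeff_range
    sig_block = np.empty((spec.n_signal_targets, n_rep, T))
    for j in range(spec.n_signal_targets):
        tid = f"SIG{j + 1:02d}"
        b_true = rng_c.uniform(lo, hi, size=spec.n_biomarkers)
        clean = np.einsum("i,irt->rt", b_true, mixed_inputs)
        scale = max(float(np.abs(clean).mean()), 1e-12)
        noisy = clean + rng_e.normal(0.0, spec.noise_sd * scale, size=(n_rep, T))
        sig_block[j] = np.clip(noisy, 0.0, None)
        met_ids.append(tid)
        compartments.append(INTRACELLULAR if j % 2 == 0 else EXTRACELLULAR)
        kinds[tid] = "signal"
        coefficients[tid] = dict(zip(bm_ids, map(float, b_true)))
    cube.append(sig_block)

    # noise targets draw their own per-replicate level factors: sharing the
    # biomarkers' bag factor would couple their level to the biomarkers and
    # make them (weakly) predictable, violating their planted independence
    noi_block = np.empty((spec.n_noise_targets, n_rep, T))
    for j in range(spec.n_noise_targets):
        tid = f"NOI{j + 1:02d}"
        level = float(rng_l.uniform(1.0, 10.0))
        own_factors = rng_l.lognormal(mean=0.0, sigma=spec.bag_sd, size=n_rep)
        base = level * own_factors[:, None] * np.ones((n_rep, T))
        noisy = base + rng_e.normal(0.0, spec.noise_sd * level, size=(n_rep, T))
        noi_block[j] = np.clip(noisy, 0.0, None)
        met_ids.append(tid)
        compartments.append(INTRACELLULAR if j % 2 == 0 else EXTRACELLULAR)
        kinds[tid] = "noise"
    cube.append(noi_block)

    conc = np.concatenate(cube, axis=0)

    artifact_cells: list[tuple[float, str]] = []
    if spec.day31_artifact and ARTIFACT_DAY in grid:
        t_idx = int(np.flatnonzero(grid == ARTIFACT_DAY)[0])
        rng_a = np.random.default_rng(derive_seed(spec.seed, "day31-artifact"))
        for i, comp in enumerate(compartments):
            if comp != EXTRACELLULAR:
                continue
            col = conc[i, :, t_idx]
            centre = col.mean()
            spread = col - centre
            if np.allclose(spread, 0.0):
                # degenerate noiseless column: synthesize dispersion at the
                # artifact's scale so the spike is still present
                spread = rng_a.normal(0.0, 0.05 * max(abs(centre), 1.0), size=n_rep)
            conc[i, :, t_idx] = np.clip(centre + ARTIFACT_DISPERSION * spread, 0.0, None)
            artifact_cells.append((ARTIFACT_DAY, met_ids[i]))

    ds = MetabolomicsDataset(
        metabolite_ids=tuple(met_ids),
        compartments=tuple(compartments),
        replicate_ids=_replicate_ids(n_rep),
        time_days=grid,
        concentrations=conc,
        biomarker_ids=tuple(bm_ids),
    )
    truth = GroundTruth(
        kinds=kinds,
        coefficients=coefficients,
        bag_factors=dict(zip(ds.replicate_ids, map(float, bag_factors))),
        artifact_cells=tuple(artifact_cells),
        breakpoints=breakpoints,
        templates={bm_ids[i]: templates[i] for i in range(spec.n_biomarkers)},
    )
    return ds, truth


def generate_dataset(spec: SynthSpec) -> tuple[MetabolomicsDataset, GroundTruth]:
    """Convenience wrapper: biomarkers then targets, one call."""
    return generate_targets(spec, generate_biomarkers(spec))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the ground-truth sidecar CSV (coefficients and bag factors).

    Long format with a ``record`` discriminator column: ``coefficient`` rows
    carry target_id/kind/biomarker_id/value, ``bag`` rows carry
    replicate_id/value.
    """
    rows = []
    for tid, kind in truth.kinds.items():
        if kind == "signal":
            for bid, c in truth.coefficients[tid].items():
                rows.append(
                    {"record": "coefficient", "target_id": tid, "kind": kind,
                     "biomarker_id": bid, "replicate_id": "", "value": c}
                )
        else:
            rows.append(
                {"record": "coefficient", "target_id": tid, "kind": kind,
                 "biomarker_id": "", "replicate_id": "", "value": np.nan}
            )
    for rid, f in truth.bag_factors.items():
        rows.append(
            {"record": "bag", "target_id": "", "kind": "", "biomarker_id": "",
             "replicate_id": rid, "value": f}
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
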