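"""Naive-random-walk benchmark and empirical per-metabolite significance.

The null model for a metabolite's dynamics is a random walk whose increments
are zero-mean Gaussian with a metabolite-specific step standard deviation
estimated from the testing replicates' observed per-sample changes, started
from a value drawn uniformly from the pool of measured first-time-point
values of the testing replicates. Walks take one step per grid interval
(unscaled by interval length — the step sigma is estimated on the same grid,
so the conventions cancel) and are clipped at zero to stay in SMAPE's domain.

Each walk is scored like the model: mean SMAPE against every testing
replicate's measured profile. The empirical p-value is the fraction of walks
that strictly outperform (score lower than) the model's mean SMAPE; a
metabolite's prediction is significant when fewer than 5% of walks do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .dataset import MetabolomicsDataset
from .evaluate import DEFAULT_EPSILON
from .exceptions import InsufficientDataError, SpecError

DEFAULT_N_WALKS = 10_000
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class RandomWalkSpec:
    """Null-walk parameters for one metabolite."""

    sigma: float
    start_pool: np.ndarray
    n_walks: int = DEFAULT_N_WALKS
    seed: int = 0
    clip_at_zero: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "start_pool", np.asarray(self.start_pool, dtype=float)
        )
        if self.sigma < 0:
            raise SpecError("sigma must be >= 0")
        if self.start_pool.size < 1:
            raise SpecError("start_pool must be non-empty")
        if self.n_walks < 1:
            raise SpecError("n_walks must be >= 1")


@dataclass(frozen=True)
class BenchmarkResult:
    """Null-walk comparison for one metabolite."""

    metabolite_id: str
    model_score: float
    walk_scores: np.ndarray
    p_empirical: float
    significant: bool
    sigma: float
    n_walks: int


def estimate_step_sigma(
    ds: MetabolomicsDataset,
    testing_replicates: Sequence[str],
    metabolite_id: str,
) -> float:
    """Step standard deviation from pooled per-sample changes.

    Pools consecutive differences ``y_r(t+1) - y_r(t)`` over all testing
    replicates and steps and returns their root mean square — the sample
    standard deviation about an assumed zero mean. Replicate order is
    irrelevant.
    """
    if ds.n_timepoints < 2:
        raise InsufficientDataError("sigma estimation requires >= 2 time points")
    diffs = [
        np.diff(ds.profile(metabolite_id, rep)) for rep in testing_replicates
    ]
    pooled = np.sort(np.concatenate(diffs) ** 2)  # sorted: order-exact pooling
    return float(np.sqrt(np.mean(pooled)))


def simulate_walks(spec: RandomWalkSpec, time_grid: Sequence[float]) -> np.ndarray:
    """Simulate ``n_walks`` random-walk profiles on the grid.

    Returns an array of shape (n_walks, len(time_grid)). Clipping at zero is
    applied step-by-step (a clipped walk continues from zero), keeping every
    profile in the non-negative domain.
    """
    grid = np.asarray(time_grid, dtype=float)
    T = len(grid)
    rng = np.random.default_rng(spec.seed)
    walks = np.empty((spec.n_walks, T))
    walks[:, 0] = rng.choice(spec.start_pool, size=spec.n_walks, replace=True)
    if spec.clip_at_zero:
        walks[:, 0] = np.clip(walks[:, 0], 0.0, None)
    for t in range(1, T):
        step = rng.normal(0.0, spec.sigma, size=spec.n_walks) if spec.sigma > 0 else 0.0
        walks[:, t] = walks[:, t - 1] + step
        if spec.clip_at_zero:
            walks[:, t] = np.clip(walks[:, t], 0.0, None)
    return walks


def score_walks(
    walks: np.ndarray, measured_profiles: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Mean SMAPE of each walk against every measured testing profile.

    Vectorised over (walks x replicates x time); exactly equivalent to
    averaging :func:`rbcforecast.evaluate.smape` over replicates per walk.
    """
    w = np.clip(np.asarray(walks, dtype=float), 0.0, None)[:, None, :]
    m = np.asarray(measured_profiles, dtype=float)[None, :, :]
    term = np.abs(w - m) / np.maximum(w + m, epsilon)
    return term.mean(axis=2).mean(axis=1)


def benchmark_metabolite(
    walks: np.ndarray,
    measured_profiles: np.ndarray,
    model_score: float,
    metabolite_id: str = "",
    sigma: float = float("nan"),
    alpha: float = DEFAULT_ALPHA,
) -> BenchmarkResult:
    """Empirical significance of a model score against the walk ensemble.

    ``p_empirical`` is the fraction of walks whose mean SMAPE is *strictly*
    lower than the model's (ties count as not outperforming); the model is
    significant when ``p_empirical < alpha``.
    """
    if len(walks) < 1:
        raise InsufficientDataError("need at least one walk")
    walk_scores = score_walks(walks, measured_profiles)
    p = float(np.count_nonzero(walk_scores < model_score)) / len(walk_scores)
    return BenchmarkResult(
        metabolite_id=metabolite_id,
        model_score=float(model_score),
        walk_scores=walk_scores,
        p_empirical=p,
        significant=p < alpha,
        sigma=float(sigma),
        n_walks=len(walk_scores),
    )


def benchmark_targets(
    ds: MetabolomicsDataset,
    testing_replicates: Sequence[str],
    model_scores: dict[str, float],
    n_walks: int = DEFAULT_N_WALKS,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> list[BenchmarkResult]:
    """Run the full null-walk benchmark for every target with a model score.

    Each metabolite's walk stream is seeded by (seed, metabolite index) so
    results do not depend on processing order.
    """
    results = []
    for mid, score in model_scores.items():
        m_idx = ds.metabolite_index(mid)
        sigma = estimate_step_sigma(ds, testing_replicates, mid)
        start_pool = np.array(
            [ds.profile(mid, rep)[0] for rep in testing_replicates]
        )
        spec = RandomWalkSpec(
            sigma=sigma,
            start_pool=start_pool,
            n_walks=n_walks,
            seed=derive_seed(seed, "nullwalk", m_idx),
        )
        walks = simulate_walks(spec, ds.time_days)
        measured = np.stack(
            [ds.profile(mid, rep) for rep in testing_replicates]
        )
        results.append(
            benchmark_metabolite(
                walks, measured, score, metabolite_id=mid, sigma=sigma, alpha=alpha
            )
        )
    return results


def benchmark_to_frame(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    """Tidy export with walk-distribution summaries per metabolite."""
    rows = []
    for r in results:
        rows.append(
            {
                "metabolite_id": r.metabolite_id,
                "model_mean_smape": r.model_score,
                "walk_smape_q05": float(np.quantile(r.walk_scores, 0.05)),
                "walk_smape_median": float(np.median(r.walk_scores)),
                "p_empirical": r.p_empirical,
                "significant": r.significant,
                "n_walks": r.n_walks,
                "sigma": r.sigma,
            }
        )
    return pd.DataFrame(rows)
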