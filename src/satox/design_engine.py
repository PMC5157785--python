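"""Dose-escalation decision logic.

After each cohort the posterior median DLT surface drives three decisions:

- **early stop** if the posterior probability that the lowest combination is
  above the target toxicity level Gamma exceeds a threshold tau;
- **next combination**: the neighbour (including the current pair, and
  vertical/horizontal/diagonal moves of at most one level per drug) whose
  posterior median DLT probability is closest to Gamma.  Exact-distance ties
  (within ``tie_tolerance``) break toward the smallest dose of drug A, then
  of drug B, under the SA analysis; under NA a tied candidate is drawn with
  probability proportional to the inverse of the number of patients already
  treated there, and uniformly among untried candidates if any are untried;
- **MTD set** at the end of a completed trial: every combination experimented
  on whose posterior median is within epsilon of Gamma (possibly empty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes_inference import PosteriorSummary, TrialData
from .core_model import DoseGrid

__all__ = [
    "DesignConfig",
    "DecisionOutcome",
    "neighbourhood",
    "select_next",
    "should_stop",
    "recommend_mtd",
]


@dataclass(frozen=True)
class DesignConfig:
    """Design parameters with the reference defaults.

    Gamma: target toxicity level; tau: early-stop threshold on
    P(pi_T(a_1, b_1) > Gamma); epsilon: half-width of the MTD window;
    ``neighbourhood_constraint=False`` allows jumps anywhere on the grid.
    """

    Gamma: float = 0.25
    tau: float = 0.80
    epsilon: float = 0.025
    cohort_size: int = 2
    max_patients: int = 60
    tie_tolerance: float = 1e-6
    neighbourhood_constraint: bool = True

    def __post_init__(self):
        if not 0 < self.Gamma < 1:
            raise ValueError("Gamma must be in (0, 1)")
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.cohort_size < 1 or self.max_patients < 1:
            raise ValueError("cohort_size and max_patients must be positive")
        if self.max_patients % self.cohort_size != 0:
            raise ValueError("max_patients must be divisible by cohort_size")


@dataclass(frozen=True)
class DecisionOutcome:
    """A single escalation decision with per-candidate diagnostics."""

    action: str  # "continue" | "stop"
    next_combo: tuple | None
    candidates: tuple  # of (combo, median, |median - Gamma|)


def neighbourhood(grid: DoseGrid, combo: tuple) -> list:
    """All on-grid pairs within one level of ``combo`` in each coordinate,
    including ``combo`` itself (1-based indices, row-major order)."""
    j, k = combo
    if not (1 <= j <= grid.J and 1 <= k <= grid.K):
        raise ValueError(f"combo {combo} outside {grid.J}x{grid.K} grid")
    return [
        (jj, kk)
        for jj in range(max(1, j - 1), min(grid.J, j + 1) + 1)
        for kk in range(max(1, k - 1), min(grid.K, k + 1) + 1)
    ]


def select_next(
    summary: PosteriorSummary,
    prev_combo: tuple,
    config: DesignConfig,
    model: str,
    patient_counts: np.ndarray,
    rng: np.random.Generator | None = None,
) -> DecisionOutcome:
    """Choose the next cohort's combination from the neighbourhood of the last.

    SA tie-breaking is deterministic (smallest dose of A, then of B); NA ties
    use inverse-patient-count weighted randomization and therefore consume
    ``rng`` (only on ties).
    """
    grid_shape = summary.median_pi_T.shape
    if config.neighbourhood_constraint:
        cand = [
            (jj, kk)
            for jj in range(max(1, prev_combo[0] - 1), min(grid_shape[0], prev_combo[0] + 1) + 1)
            for kk in range(max(1, prev_combo[1] - 1), min(grid_shape[1], prev_combo[1] + 1) + 1)
        ]
    else:
        cand = [(jj, kk) for jj in range(1, grid_shape[0] + 1) for kk in range(1, grid_shape[1] + 1)]
    if not cand:
        raise ValueError("empty candidate set")

    meds = np.array([summary.median_pi_T[j - 1, k - 1] for j, k in cand])
    dist = np.abs(meds - config.Gamma)
    diagnostics = tuple(zip(cand, meds.tolist(), dist.tolist()))
    best = dist.min()
    tied = [c for c, d in zip(cand, dist) if d <= best + config.tie_tolerance]
    if len(tied) == 1:
        choice = tied[0]
    elif model == "SA":
        choice = min(tied)  # smallest dose of A, then of B
    else:
        if rng is None:
            raise ValueError("NA tie-breaking requires an rng")
        counts = np.array([patient_counts[j - 1, k - 1] for j, k in tied], dtype=float)
        if np.any(counts == 0):
            untried = [c for c, n in zip(tied, counts) if n == 0]
            choice = untried[rng.integers(len(untried))]
        else:
            weights = 1.0 / counts
            choice = tied[rng.choice(len(tied), p=weights / weights.sum())]
    return DecisionOutcome(action="continue", next_combo=choice, candidates=diagnostics)


def should_stop(summary: PosteriorSummary, config: DesignConfig) -> bool:
    """True iff P(pi_T(a_1, b_1) > Gamma) strictly exceeds tau."""
    return summary.exceedance_lowest > config.tau


def recommend_mtd(summary: PosteriorSummary, data: TrialData, config: DesignConfig) -> frozenset:
    """MTD set of a completed trial: experimented combinations whose posterior
    median DLT probability lies within [Gamma - epsilon, Gamma + epsilon]."""
    counts = data.per_combo_counts()
    J, K = counts.shape
    return frozenset(
        (j, k)
        for j in range(1, J + 1)
        for k in range(1, K + 1)
        if counts[j - 1, k - 1] > 0
        and abs(summary.median_pi_T[j - 1, k - 1] - config.Gamma) <= config.epsilon
    )
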