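"""Whole-trial simulation and operating characteristics.

A scenario supplies the *true* full-cycle DLT probability table and the true
pre-``t_B`` marginals; patient outcomes are trinary draws from those tables.
``run_trial`` executes the cohort-wise escalation algorithm under either the
SA or the NA analysis; ``run_batch`` replicates trials with per-trial derived
seeds; ``compute_oc`` reduces a batch to the standard operating
characteristics (experimentation and MTD-recommendation percentages by
true-toxicity bin, DLT rates, early stops, estimator bias/RMSE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .bayes_inference import (
    MCMCConfig,
    PatientRecord,
    PriorSpec,
    TrialData,
    sample_posterior,
    summarize,
)
from .core_model import DoseGrid, ModelParams, pi_T_surface
from .design_engine import DesignConfig, recommend_mtd, select_next, should_stop

__all__ = [
    "Scenario",
    "TrialResult",
    "OperatingCharacteristics",
    "PAPER_BINS",
    "sample_outcome",
    "run_trial",
    "run_batch",
    "compute_oc",
]

#: True-DLT-probability bins: [0, 0.2], (0.2, 0.225], (0.225, 0.275],
#: (0.275, 0.3], (0.3, 0.4], (0.4, 1].
PAPER_BINS = (0.0, 0.2, 0.225, 0.275, 0.3, 0.4, 1.0)


@dataclass
class Scenario:
    """True dose-toxicity tables driving outcome generation.

    ``true_pi_T[j-1, k-1]`` is the full-cycle DLT probability at (a_j, b_k);
    ``true_pre_tB[j-1]`` the probability of a DLT before drug B at dose a_j.
    ``lambda_TR`` is informational (the scalar attributable fraction that
    generated ``true_pre_tB``, if any); ``true_params`` enables bias/RMSE
    metrics for parameter-generated scenarios.
    """

    name: str
    grid: DoseGrid
    true_pi_T: np.ndarray
    true_pre_tB: np.ndarray
    lambda_TR: float | None = None
    true_params: ModelParams | None = None

    def __post_init__(self):
        self.true_pi_T = np.asarray(self.true_pi_T, dtype=float)
        self.true_pre_tB = np.asarray(self.true_pre_tB, dtype=float)
        J, K = self.grid.J, self.grid.K
        if self.true_pi_T.shape != (J, K):
            raise ValueError(f"true_pi_T must have shape ({J}, {K})")
        if self.true_pre_tB.shape != (J,):
            raise ValueError(f"true_pre_tB must have shape ({J},)")
        if np.any(self.true_pi_T < 0) or np.any(self.true_pi_T > 1):
            raise ValueError("true_pi_T entries must lie in [0, 1]")
        tol = 1e-12
        if np.any(np.diff(self.true_pi_T, axis=0) < -tol) or np.any(
            np.diff(self.true_pi_T, axis=1) < -tol
        ):
            raise ValueError("true_pi_T must be non-decreasing in each dose")
        if np.any(self.true_pre_tB < 0) or np.any(self.true_pre_tB >= 1):
            raise ValueError("true_pre_tB entries must lie in [0, 1)")
        if np.any(self.true_pre_tB > self.true_pi_T.min(axis=1) + tol):
            raise ValueError("true_pre_tB must not exceed any full-cycle probability")

    @classmethod
    def from_params(
        cls,
        name: str,
        grid: DoseGrid,
        params: ModelParams,
        lambda_TR: float | None = None,
    ) -> "Scenario":
        """Generate the truth tables from copula parameters.

        ``lambda_TR`` defaults to ``params.lam``; the pre-``t_B`` marginals are
        ``lambda_TR * p_j ** alpha``.
        """
        lam = params.lam if lambda_TR is None else lambda_TR
        surface = pi_T_surface(grid, params)
        pre = lam * np.asarray(grid.skeleton_p) ** params.alpha
        return cls(
            name=name,
            grid=grid,
            true_pi_T=surface,
            true_pre_tB=pre,
            lambda_TR=lam,
            true_params=params,
        )

    def outcome_probs(self, combo: tuple) -> np.ndarray:
        """True (P(Y=0), P(Y=1), P(Y=2)) at a combination."""
        j, k = combo
        full = self.true_pi_T[j - 1, k - 1]
        pre = self.true_pre_tB[j - 1]
        return np.array([1.0 - full, pre, full - pre])


def sample_outcome(scenario: Scenario, combo: tuple, rng: np.random.Generator) -> int:
    """Draw one trinary outcome; consumes exactly one uniform variate."""
    j, k = combo
    if not (1 <= j <= scenario.grid.J and 1 <= k <= scenario.grid.K):
        raise ValueError(f"combo {combo} outside grid")
    _, p1, p2 = scenario.outcome_probs(combo)
    u = rng.random()
    if u < p1:
        return 1
    if u < p1 + p2:
        return 2
    return 0


@dataclass
class TrialResult:
    """Trajectory and summaries of one simulated trial."""

    scenario_name: str
    design: str
    cohorts: list  # of (combo, outcomes tuple)
    stopped_early: bool
    mtd_set: frozenset
    counts: np.ndarray  # patients per combo (J, K)
    n_patients: int
    n_dlt: int
    n_dlt_pre_tB: int
    param_medians: dict
    decision_log: list = field(default_factory=list)

    @property
    def dlt_rate_pct(self) -> float:
        return 100.0 * self.n_dlt / self.n_patients

    @property
    def pre_tB_dlt_pct(self) -> float | None:
        """Percentage of this trial's DLTs occurring before t_B; None if no DLT."""
        if self.n_dlt == 0:
            return None
        return 100.0 * self.n_dlt_pre_tB / self.n_dlt


def _derived_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def run_trial(
    scenario: Scenario,
    design: str = "SA",
    config: DesignConfig = DesignConfig(),
    prior: PriorSpec = PriorSpec(),
    mcmc: MCMCConfig = MCMCConfig(),
    seed: int = 0,
) -> TrialResult:
    """Simulate one trial under the cohort-wise escalation algorithm.

    The first cohort is dosed at (a_1, b_1).  After each cohort the design's
    posterior is refit; the trial stops early when the lowest combination is
    deemed too toxic, otherwise the next cohort is dosed at the
    target-closest neighbour.  At the patient cap the MTD set is recommended.

    Outcome generation, NA tie-breaking and MCMC chains draw from separate
    seed-derived streams, so SA and NA analyses of the same seed see
    identical outcome randomness while their dose paths agree.
    """
    if design not in ("SA", "NA"):
        raise ValueError("design must be 'SA' or 'NA'")
    streams = _derived_seeds(seed, 3)
    outcome_rng = np.random.default_rng(int(streams[0]))
    tie_rng = np.random.default_rng(int(streams[1]))
    n_cohorts = config.max_patients // config.cohort_size
    mcmc_seeds = _derived_seeds(int(streams[2]), n_cohorts)

    data = TrialData(grid=scenario.grid, timing=prior.timing)
    combo = (1, 1)
    cohorts = []
    decision_log = []
    stopped = False
    summary = None
    for c in range(n_cohorts):
        outcomes = []
        for _ in range(config.cohort_size):
            y = sample_outcome(scenario, combo, outcome_rng)
            outcomes.append(y)
            data.add(
                PatientRecord(
                    a_idx=combo[0], b_idx=combo[1], b_administered=(y != 1), outcome=y
                )
            )
        cohorts.append((combo, tuple(outcomes)))
        draws = sample_posterior(data, prior, model=design, mcmc=mcmc, seed=int(mcmc_seeds[c]))
        summary = summarize(draws, scenario.grid, gamma_target=config.Gamma)
        record = {
            "cohort": c + 1,
            "combo": combo,
            "outcomes": tuple(outcomes),
            "exceedance": summary.exceedance_lowest,
        }
        if should_stop(summary, config):
            stopped = True
            record["action"] = "stop"
            decision_log.append(record)
            break
        if c + 1 < n_cohorts:
            decision = select_next(
                summary, combo, config, design, data.per_combo_counts(), rng=tie_rng
            )
            combo = decision.next_combo
            record["action"] = "continue"
            record["next_combo"] = combo
        else:
            record["action"] = "complete"
        decision_log.append(record)

    mtd = frozenset()
    if not stopped:
        mtd = recommend_mtd(summary, data, config)
    outcomes_all = [r.outcome for r in data.records]
    return TrialResult(
        scenario_name=scenario.name,
        design=design,
        cohorts=cohorts,
        stopped_early=stopped,
        mtd_set=mtd,
        counts=data.per_combo_counts(),
        n_patients=len(data),
        n_dlt=sum(1 for y in outcomes_all if y != 0),
        n_dlt_pre_tB=sum(1 for y in outcomes_all if y == 1),
        param_medians=summary.param_medians,
        decision_log=decision_log,
    )


def run_batch(
    scenario: Scenario,
    design: str = "SA",
    config: DesignConfig = DesignConfig(),
    prior: PriorSpec = PriorSpec(),
    mcmc: MCMCConfig = MCMCConfig(),
    n_trials: int = 1000,
    base_seed: int = 0,
    n_jobs: int = 1,
) -> list:
    """Replicate ``run_trial`` with per-trial seeds derived from ``base_seed``.

    Results are identical regardless of ``n_jobs`` (each trial's seed depends
    only on its index).
    """
    seeds = _derived_seeds(base_seed, max(n_trials, 1))[:n_trials]
    if n_trials == 0:
        return []
    if n_jobs == 1:
        return [
            run_trial(scenario, design, config, prior, mcmc, seed=int(s)) for s in seeds
        ]
    return Parallel(n_jobs=n_jobs)(
        delayed(run_trial)(scenario, design, config, prior, mcmc, seed=int(s))
        for s in seeds
    )


def _bin_index(p: float, bins: tuple) -> int:
    """Bin a probability: first bin is closed, the rest are left-open."""
    for i in range(1, len(bins)):
        if p <= bins[i] + 1e-12:
            return i - 1
    return len(bins) - 2


@dataclass
class OperatingCharacteristics:
    """Batch-level summaries of a set of simulated trials."""

    n_trials: int
    bins: tuple
    experimentation_pct: np.ndarray  # % of all patients per true-toxicity bin
    dlt_rate_mean: float
    dlt_rate_sd: float
    pre_tB_pct_mean: float | None  # over trials with >= 1 DLT
    pre_tB_pct_sd: float | None
    mtd_pct: np.ndarray  # % of pooled MTD recommendations per bin
    early_stop_count: int
    no_mtd_count: int  # completed trials with an empty MTD set
    mean_n_mtd: float | None  # mean MTD-set size over completed trials
    bias: dict | None
    rmse: dict | None

    def to_frame(self) -> pd.DataFrame:
        labels = [
            f"[{self.bins[0]},{self.bins[1]}]"
            if i == 0
            else f"({self.bins[i]},{self.bins[i + 1]}]"
            for i in range(len(self.bins) - 1)
        ]
        row = {f"exp_pct {lab}": v for lab, v in zip(labels, self.experimentation_pct)}
        row.update({f"mtd_pct {lab}": v for lab, v in zip(labels, self.mtd_pct)})
        row.update(
            {
                "dlt_rate_mean": self.dlt_rate_mean,
                "dlt_rate_sd": self.dlt_rate_sd,
                "pre_tB_pct_mean": self.pre_tB_pct_mean,
                "pre_tB_pct_sd": self.pre_tB_pct_sd,
                "early_stop_count": self.early_stop_count,
                "no_mtd_count": self.no_mtd_count,
                "mean_n_mtd": self.mean_n_mtd,
                "n_trials": self.n_trials,
            }
        )
        if self.bias is not None:
            for p, v in self.bias.items():
                row[f"bias_{p}"] = v
            for p, v in self.rmse.items():
                row[f"rmse_{p}"] = v
        return pd.DataFrame([row])


def compute_oc(
    results: list,
    scenario: Scenario,
    config: DesignConfig = DesignConfig(),
    bins: tuple = PAPER_BINS,
) -> OperatingCharacteristics:
    """Operating characteristics of a batch of trials.

    Experimentation percentages pool patients across all trials (including
    early-stopped ones); DLT-rate mean/SD are across per-trial rates; the
    pre-``t_B`` DLT percentage averages only trials with at least one DLT;
    MTD metrics use completed trials only; bias and RMSE of (alpha, beta,
    gamma) are computed over completed trials when the scenario carries its
    generating parameters.
    """
    if not results:
        raise ValueError("results must be non-empty")
    n_bins = len(bins) - 1
    combo_bin = np.array(
        [
            [_bin_index(scenario.true_pi_T[j, k], bins) for k in range(scenario.grid.K)]
            for j in range(scenario.grid.J)
        ]
    )

    patients_per_bin = np.zeros(n_bins)
    for r in results:
        for b in range(n_bins):
            patients_per_bin[b] += r.counts[combo_bin == b].sum()
    experimentation_pct = 100.0 * patients_per_bin / patients_per_bin.sum()

    dlt_rates = np.array([r.dlt_rate_pct for r in results])
    pre_pcts = np.array([p for r in results if (p := r.pre_tB_dlt_pct) is not None])

    completed = [r for r in results if not r.stopped_early]
    mtd_per_bin = np.zeros(n_bins)
    for r in completed:
        for j, k in r.mtd_set:
            mtd_per_bin[combo_bin[j - 1, k - 1]] += 1
    total_mtd = mtd_per_bin.sum()
    mtd_pct = 100.0 * mtd_per_bin / total_mtd if total_mtd > 0 else np.zeros(n_bins)

    bias = rmse = None
    if scenario.true_params is not None and completed:
        truth = {
            "alpha": scenario.true_params.alpha,
            "beta": scenario.true_params.beta,
            "gamma": scenario.true_params.gamma,
        }
        errs = {
            p: np.array([r.param_medians[p] - v for r in completed])
            for p, v in truth.items()
        }
        bias = {p: float(e.mean()) for p, e in errs.items()}
        rmse = {p: float(np.sqrt((e**2).mean())) for p, e in errs.items()}

    return OperatingCharacteristics(
        n_trials=len(results),
        bins=tuple(bins),
        experimentation_pct=experimentation_pct,
        dlt_rate_mean=float(dlt_rates.mean()),
        dlt_rate_sd=float(dlt_rates.std(ddof=1)) if len(dlt_rates) > 1 else 0.0,
        pre_tB_pct_mean=float(pre_pcts.mean()) if len(pre_pcts) else None,
        pre_tB_pct_sd=float(pre_pcts.std(ddof=1)) if len(pre_pcts) > 1 else None,
        mtd_pct=mtd_pct,
        early_stop_count=sum(r.stopped_early for r in results),
        no_mtd_count=sum(1 for r in completed if not r.mtd_set),
        mean_n_mtd=float(np.mean([len(r.mtd_set) for r in completed])) if completed else None,
        bias=bias,
        rmse=rmse,
    )
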