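"""Priors, likelihoods and posterior computation for the dose-toxicity model.

Two analyses of the same trial data are supported:

- **SA (semi-attributable)**: the trinary outcome is modelled directly, with
  per-patient likelihood factors ``1 - pi_T`` (Y=0), ``lambda * pi_T(a, 0)``
  (Y=1, DLT before drug B) and ``pi_T - lambda * pi_T(a, 0)`` (Y=2).
- **NA (non-attributable)**: only the binary DLT indicator over the full cycle
  is used, with factors ``1 - pi_T`` and ``pi_T`` at the planned dose pair;
  lambda plays no role.

Priors follow the reference design: alpha, beta ~ Uniform[0, 2], gamma ~
Normal(0, variance 10), and lambda ~ Beta(t_B/(T - t_B), 1) when
t_B >= T - t_B, else Beta(1, (T - t_B)/t_B), so that the prior mean of lambda
is t_B / T.  Posterior sampling uses an adaptive random-walk Metropolis
kernel; a dense-grid quadrature over the parameter space is provided as an
independent cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _mcmc
from .core_model import (
    CycleTiming,
    DoseGrid,
    ModelParams,
    pi_T,
    pi_T_surfaces_from_draws,
    pi_tB,
)

__all__ = [
    "PatientRecord",
    "TrialData",
    "PriorSpec",
    "MCMCConfig",
    "REDUCED_MCMC",
    "PosteriorDraws",
    "PosteriorSummary",
    "log_likelihood_sa",
    "log_likelihood_na",
    "log_prior",
    "sample_posterior",
    "quadrature_posterior",
    "summarize",
]

DEFAULT_TIMING = CycleTiming(t_B=4.0, T=7.0)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: dose indices (1-based), whether drug B was given, outcome.

    ``b_idx`` is the planned dose of drug B and is recorded even when a
    pre-``t_B`` DLT (outcome 1) prevented its administration.
    """

    a_idx: int
    b_idx: int
    b_administered: bool
    outcome: int

    def __post_init__(self):
        if self.outcome not in (0, 1, 2):
            raise ValueError("outcome must be 0, 1 or 2")
        if (self.outcome == 1) == self.b_administered:
            raise ValueError(
                "outcome 1 (DLT before t_B) must coincide with drug B being withheld"
            )


@dataclass
class TrialData:
    """Ordered per-patient records, tied to a dose grid and cycle timing."""

    grid: DoseGrid
    timing: CycleTiming = DEFAULT_TIMING
    records: list = field(default_factory=list)

    def __post_init__(self):
        for r in self.records:
            self._check(r)

    def _check(self, r: PatientRecord):
        if not (1 <= r.a_idx <= self.grid.J and 1 <= r.b_idx <= self.grid.K):
            raise ValueError(f"record {r} outside grid {self.grid.J}x{self.grid.K}")

    def add(self, record: PatientRecord):
        self._check(record)
        self.records.append(record)

    def __len__(self):
        return len(self.records)

    def counts_sa(self):
        """(n0[J,K], n1[J], n2[J,K]) outcome counts for the SA likelihood."""
        J, K = self.grid.J, self.grid.K
        n0 = np.zeros((J, K))
        n1 = np.zeros(J)
        n2 = np.zeros((J, K))
        for r in self.records:
            if r.outcome == 0:
                n0[r.a_idx - 1, r.b_idx - 1] += 1
            elif r.outcome == 1:
                n1[r.a_idx - 1] += 1
            else:
                n2[r.a_idx - 1, r.b_idx - 1] += 1
        return n0, n1, n2

    def counts_na(self):
        """(n0[J,K], n_dlt[J,K]) binary DLT counts at the planned dose pairs."""
        J, K = self.grid.J, self.grid.K
        n0 = np.zeros((J, K))
        nd = np.zeros((J, K))
        for r in self.records:
            tgt = n0 if r.outcome == 0 else nd
            tgt[r.a_idx - 1, r.b_idx - 1] += 1
        return n0, nd

    def per_combo_counts(self) -> np.ndarray:
        """Patients per planned dose pair, shape (J, K)."""
        counts = np.zeros((self.grid.J, self.grid.K), dtype=int)
        for r in self.records:
            counts[r.a_idx - 1, r.b_idx - 1] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient": np.arange(1, len(self.records) + 1),
                "a_idx": [r.a_idx for r in self.records],
                "b_idx": [r.b_idx for r in self.records],
                "b_administered": [int(r.b_administered) for r in self.records],
                "outcome": [r.outcome for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grid: DoseGrid, timing: CycleTiming = DEFAULT_TIMING):
        records = [
            PatientRecord(
                a_idx=int(row.a_idx),
                b_idx=int(row.b_idx),
                b_administered=bool(row.b_administered),
                outcome=int(row.outcome),
            )
            for row in df.itertuples()
        ]
        return cls(grid=grid, timing=timing, records=records)


@dataclass(frozen=True)
class PriorSpec:
    """Prior specification for (alpha, beta, gamma, lambda)."""

    alpha_range: tuple = (0.0, 2.0)
    beta_range: tuple = (0.0, 2.0)
    gamma_mean: float = 0.0
    gamma_var: float = 10.0
    lambda_mode: str = "estimated"  # "estimated" | "fixed"
    lambda_fixed_value: float | None = None
    timing: CycleTiming = DEFAULT_TIMING

    def __post_init__(self):
        if self.lambda_mode not in ("estimated", "fixed"):
            raise ValueError("lambda_mode must be 'estimated' or 'fixed'")
        if self.lambda_mode == "fixed" and self.lambda_fixed_value is None:
            # default fixed value t_B / T
            object.__setattr__(
                self, "lambda_fixed_value", self.timing.t_B / self.timing.T
            )

    @property
    def lambda_beta_shapes(self) -> tuple:
        """Beta prior shapes for lambda, chosen so E(lambda) = t_B / T."""
        t_B, T = self.timing.t_B, self.timing.T
        if t_B >= T - t_B:
            return (t_B / (T - t_B), 1.0)
        return (1.0, (T - t_B) / t_B)


@dataclass(frozen=True)
class MCMCConfig:
    """Metropolis settings; ``keep`` is the number of retained draws per chain."""

    chains: int = 2
    burn_in: int = 500
    keep: int = 4000
    thin: int = 2


#: Scaled-down settings used for batch simulation.
REDUCED_MCMC = MCMCConfig(chains=1, burn_in=250, keep=1000, thin=2)


@dataclass
class PosteriorDraws:
    """Retained posterior draws with chain labels and sampler diagnostics."""

    params: np.ndarray  # (n, 4): alpha, beta, gamma, lambda
    chain: np.ndarray
    model: str
    acceptance: np.ndarray
    rhat: dict
    grid: DoseGrid

    names = ("alpha", "beta", "gamma", "lam")

    @property
    def alpha(self):
        return self.params[:, 0]

    @property
    def beta(self):
        return self.params[:, 1]

    @property
    def gamma(self):
        return self.params[:, 2]

    @property
    def lam(self):
        return self.params[:, 3]

    def __len__(self):
        return self.params.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """One row per retained draw, including pi_T at the lowest combination."""
        surf = pi_T_surfaces_from_draws(self.grid, self.alpha, self.beta, self.gamma)
        df = pd.DataFrame(self.params, columns=list(self.names))
        df.insert(0, "iter", np.arange(len(df)))
        df.insert(0, "chain", self.chain)
        df["pi_T_a1_b1"] = surf[:, 0, 0]
        return df


@dataclass
class PosteriorSummary:
    """Posterior medians of pi_T over the grid plus decision quantities."""

    median_pi_T: np.ndarray  # (J, K)
    param_medians: dict
    exceedance_lowest: float  # P(pi_T(a_1, b_1) > Gamma)
    gamma_target: float


def log_likelihood_sa(data: TrialData, params: ModelParams) -> float:
    """Trinary-outcome log-likelihood; -inf if any outcome has zero probability."""
    ll = 0.0
    for r in data.records:
        if r.outcome == 0:
            f = 1.0 - pi_T(data.grid, params, r.a_idx, r.b_idx)
        elif r.outcome == 1:
            f = pi_tB(data.grid, params, r.a_idx)
        else:
            f = pi_T(data.grid, params, r.a_idx, r.b_idx) - pi_tB(data.grid, params, r.a_idx)
        if f <= 0.0:
            return -np.inf
        ll += np.log(f)
    return ll


def log_likelihood_na(data: TrialData, params: ModelParams) -> float:
    """Binary DLT log-likelihood at the planned dose pairs; lambda unused."""
    ll = 0.0
    for r in data.records:
        p = pi_T(data.grid, params, r.a_idx, r.b_idx)
        f = 1.0 - p if r.outcome == 0 else p
        if f <= 0.0:
            return -np.inf
        ll += np.log(f)
    return ll


def log_prior(params: ModelParams, prior: PriorSpec, model: str = "SA") -> float:
    """Log prior density on the natural scale; -inf outside support.

    The lambda term enters only for the SA model with lambda estimated.
    """
    (a_lo, a_hi), (b_lo, b_hi) = prior.alpha_range, prior.beta_range
    if not (a_lo <= params.alpha <= a_hi and b_lo <= params.beta <= b_hi):
        return -np.inf
    lp = -np.log(a_hi - a_lo) - np.log(b_hi - b_lo)
    lp += stats.norm.logpdf(params.gamma, prior.gamma_mean, np.sqrt(prior.gamma_var))
    if model == "SA" and prior.lambda_mode == "estimated":
        a, b = prior.lambda_beta_shapes
        lp += stats.beta.logpdf(params.lam, a, b)
        if not np.isfinite(lp):
            return -np.inf
    return float(lp)


def _counts_for(data: TrialData, model: str):
    if model == "SA":
        return data.counts_sa()
    n0, nd = data.counts_na()
    return n0, np.zeros(data.grid.J), nd


def _split_rhat(x: np.ndarray, chain: np.ndarray) -> float:
    """Split-chain potential scale reduction factor."""
    halves = []
    for c in np.unique(chain):
        xc = x[chain == c]
        h = len(xc) // 2
        if h >= 2:
            halves.append(xc[:h])
            halves.append(xc[h : 2 * h])
    if len(halves) < 2:
        return np.nan
    n = min(len(h) for h in halves)
    seqs = np.array([h[:n] for h in halves])
    W = seqs.var(axis=1, ddof=1).mean()
    B = n * seqs.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def sample_posterior(
    data: TrialData,
    prior: PriorSpec,
    model: str = "SA",
    mcmc: MCMCConfig = MCMCConfig(),
    seed: int = 0,
) -> PosteriorDraws:
    """Draw from the posterior of (alpha, beta, gamma[, lambda]) by adaptive RWM.

    With empty data the draws target the prior.  Chains initialize at the
    prior medians (transformed scale) with seed-controlled jitter; a chain
    whose initial log-posterior is non-finite is re-jittered up to 20 times.
    Split-chain R-hat above 1.1 triggers a warning, not an error.
    """
    if model not in ("SA", "NA"):
        raise ValueError("model must be 'SA' or 'NA'")
    n0, n1, n2 = _counts_for(data, model)
    grid = data.grid
    p_skel = np.asarray(grid.skeleton_p)
    q_skel = np.asarray(grid.skeleton_q)

    est_lam = model == "SA" and prior.lambda_mode == "estimated"
    lam_a, lam_b = prior.lambda_beta_shapes
    lam_fixed = float(prior.lambda_fixed_value or 0.0)
    model_code = _mcmc.MODEL_SA if model == "SA" else _mcmc.MODEL_NA
    (a_lo, a_hi), (b_lo, b_hi) = prior.alpha_range, prior.beta_range

    rng = np.random.default_rng(seed)
    chain_seeds = rng.integers(0, 2**31 - 1, size=mcmc.chains)
    lam_median = stats.beta.median(lam_a, lam_b)
    z_center = np.array([0.0, 0.0, prior.gamma_mean, np.log(lam_median / (1 - lam_median))])
    scale_init = np.array([0.6, 0.6, 1.0, 0.6])

    kernel_args = (
        p_skel, q_skel, n0, n1, n2, model_code,
        a_lo, a_hi, b_lo, b_hi, prior.gamma_mean, prior.gamma_var,
        est_lam, lam_fixed, lam_a, lam_b,
    )
    all_draws, all_chain, all_rates = [], [], []
    for c in range(mcmc.chains):
        z0 = None
        for _ in range(20):
            cand = z_center + 0.25 * rng.standard_normal(4)
            if np.isfinite(_mcmc.log_post_value(cand, *kernel_args)):
                z0 = cand
                break
        if z0 is None:
            raise RuntimeError("could not find a finite-posterior initial point")
        draws, rates = _mcmc.run_chain(
            int(chain_seeds[c]),
            mcmc.burn_in,
            mcmc.keep * mcmc.thin,
            mcmc.thin,
            z0,
            scale_init,
            *kernel_args,
        )
        all_draws.append(draws)
        all_chain.append(np.full(len(draws), c))
        all_rates.append(rates)

    params = np.vstack(all_draws)
    chain = np.concatenate(all_chain)
    n_dim = 4 if est_lam else 3
    rhat = {
        PosteriorDraws.names[d]: _split_rhat(params[:, d], chain) for d in range(n_dim)
    }
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > 1.1}
    if bad:
        warnings.warn(f"split-chain R-hat above 1.1: {bad}", stacklevel=2)
    return PosteriorDraws(
        params=params,
        chain=chain,
        model=model,
        acceptance=np.mean(all_rates, axis=0),
        rhat=rhat,
        grid=grid,
    )


def summarize(draws: PosteriorDraws, grid: DoseGrid, gamma_target: float = 0.25) -> PosteriorSummary:
    """Posterior medians of pi_T per combination and the lowest-combo exceedance.

    Each draw is transformed to its pi_T surface before taking entrywise
    medians; the exceedance probability is the fraction of draws with
    pi_T(a_1, b_1) strictly above the target.
    """
    surf = pi_T_surfaces_from_draws(grid, draws.alpha, draws.beta, draws.gamma)
    medians = {
        name: float(np.median(draws.params[:, i]))
        for i, name in enumerate(PosteriorDraws.names)
    }
    if draws.model == "NA":
        medians.pop("lam")
    return PosteriorSummary(
        median_pi_T=np.median(surf, axis=0),
        param_medians=medians,
        exceedance_lowest=float(np.mean(surf[:, 0, 0] > gamma_target)),
        gamma_target=gamma_target,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with mid-mass interpolation (exact for symmetric grids)."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5 * w.sum(), cw, v))


def quadrature_posterior(
    data: TrialData,
    prior: PriorSpec,
    model: str = "SA",
    n_points: int = 60,
    gamma_halfwidth_sd: float = 6.0,
    gamma_target: float = 0.25,
) -> PosteriorSummary:
    """Posterior summaries by brute-force quadrature on a dense tensor grid.

    Midpoint rule with ``n_points`` per dimension over the prior support
    (gamma truncated at +/- ``gamma_halfwidth_sd`` prior SD).  Intended as an
    independent oracle for small datasets; cost grows as n_points^3 (NA) or
    n_points^4 (SA with lambda estimated).
    """
    if n_points < 10:
        raise ValueError("n_points must be at least 10")
    if model not in ("SA", "NA"):
        raise ValueError("model must be 'SA' or 'NA'")
    grid = data.grid
    J, K = grid.J, grid.K
    p_skel = np.asarray(grid.skeleton_p)
    q_skel = np.asarray(grid.skeleton_q)

    def midgrid(lo, hi):
        h = (hi - lo) / n_points
        return lo + (np.arange(n_points) + 0.5) * h

    (a_lo, a_hi), (b_lo, b_hi) = prior.alpha_range, prior.beta_range
    A = midgrid(a_lo, a_hi)
    B = midgrid(b_lo, b_hi)
    g_sd = np.sqrt(prior.gamma_var)
    G = midgrid(prior.gamma_mean - gamma_halfwidth_sd * g_sd, prior.gamma_mean + gamma_halfwidth_sd * g_sd)
    wg = stats.norm.pdf(G, prior.gamma_mean, g_sd)

    est_lam = model == "SA" and prior.lambda_mode == "estimated"
    if model == "SA":
        if est_lam:
            L = midgrid(0.0, 1.0)
            la, lb = prior.lambda_beta_shapes
            wl = stats.beta.pdf(L, la, lb)
        else:
            L = np.array([float(prior.lambda_fixed_value)])
            wl = np.array([1.0])
    else:
        L = np.array([0.0])
        wl = np.array([1.0])

    ua = p_skel[:, None] ** A[None, :]  # (J, Na)
    vb = q_skel[:, None] ** B[None, :]  # (K, Nb)
    t = np.tanh(G / 2.0)  # (Ng,)

    n0, n1, n2 = _counts_for(data, model)
    shape4 = (len(A), len(B), len(G), len(L))
    ll = np.zeros(shape4)

    def pi_jk(j, k):
        u = ua[j][:, None, None]
        v = vb[k][None, :, None]
        return 1.0 - (1.0 - u) * (1.0 - v) + u * (1.0 - u) * v * (1.0 - v) * t[None, None, :]

    pre = ua[:, :, None] * L[None, None, :]  # (J, Na, Nl)
    for j in range(J):
        if model == "SA" and n1[j] > 0:
            with np.errstate(divide="ignore"):
                ll += n1[j] * np.where(pre[j] > 0, np.log(pre[j]), -np.inf)[:, None, None, :]
        for k in range(K):
            if n0[j, k] == 0 and n2[j, k] == 0:
                continue
            pi = pi_jk(j, k)
            with np.errstate(divide="ignore"):
                if n0[j, k] > 0:
                    ll += n0[j, k] * np.where(pi < 1, np.log1p(-np.clip(pi, None, 1.0)), -np.inf)[..., None]
                if n2[j, k] > 0:
                    if model == "SA":
                        cell = pi[..., None] - pre[j][:, None, None, :]
                    else:
                        cell = pi[..., None]
                    ll += n2[j, k] * np.where(cell > 0, np.log(np.clip(cell, 1e-300, None)), -np.inf)

    logw = (
        ll
        + np.log(wg)[None, None, :, None]
        + np.log(wl)[None, None, None, :]
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()

    w_theta = w.sum(axis=3)  # marginal over lambda, shape (Na, Nb, Ng)
    median_pi = np.empty((J, K))
    for j in range(J):
        for k in range(K):
            median_pi[j, k] = _weighted_median(pi_jk(j, k).ravel(), w_theta.ravel())
    exceed = float(w_theta.ravel()[pi_jk(0, 0).ravel() > gamma_target].sum())

    medians = {
        "alpha": _weighted_median(A, w.sum(axis=(1, 2, 3))),
        "beta": _weighted_median(B, w.sum(axis=(0, 2, 3))),
        "gamma": _weighted_median(G, w.sum(axis=(0, 1, 3))),
    }
    if est_lam:
        medians["lam"] = _weighted_median(L, w.sum(axis=(0, 1, 2)))
    elif model == "SA":
        medians["lam"] = float(L[0])
    return PosteriorSummary(
        median_pi_T=median_pi,
        param_medians=medians,
        exceedance_lowest=exceed,
        gamma_target=gamma_target,
    )
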