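"""Dose-toxicity probability surface for dual-agent trials with staged dosing.

Drug A is given at the start of the cycle; drug B at a pre-planned time ``t_B``
within the cycle ``[0, T]``, and only if no dose-limiting toxicity (DLT) has
occurred before ``t_B``.  The full-cycle DLT probability at a dose pair
``(a_j, b_k)`` is modelled with a Farlie-Gumbel-Morgenstern (FGM) copula on
power-transformed skeleton probabilities,

    pi_T(a_j, b_k) = 1 - (1 - p_j^alpha)(1 - q_k^beta)
                     + p_j^alpha (1 - p_j^alpha) q_k^beta (1 - q_k^beta) tanh(gamma / 2),

where ``tanh(gamma/2) = (e^gamma - 1)/(e^gamma + 1)`` is the bounded interaction
term (antagonism for gamma < 0, synergy for gamma > 0, independence at 0).
The pre-``t_B`` marginal is linked linearly: ``pi_tB(a_j) = lambda * pi_T(a_j, 0)
= lambda * p_j^alpha`` with ``0 <= lambda < 1``.

The per-patient outcome is trinary: 0 = no DLT in ``[0, T]``; 1 = DLT before
``t_B`` (attributable to drug A alone, drug B withheld); 2 = DLT after ``t_B``
(non-attributable).  Dose index ``k = 0`` denotes "drug B absent" (``q = 0``),
so ``pi_T(a_j, 0)`` is an ordinary grid evaluation rather than a special case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np

__all__ = [
    "DoseGrid",
    "ModelParams",
    "CycleTiming",
    "OutcomeProbs",
    "pi_T",
    "pi_tB",
    "outcome_probs",
    "pi_T_surface",
    "pi_T_surfaces_from_draws",
    "check_conditions",
    "round_half_even",
]


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties going to the even digit.

    Operates on the decimal value (cleaned of float representation noise at
    10 decimals), so exact decimal midpoints such as 0.325 round to 0.32 and
    0.295 to 0.30 — the convention of R's ``round`` used for printed tables.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(round(float(x), 10))).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class DoseGrid:
    """Dose levels of drugs A and B with monotone skeleton DLT probabilities.

    ``skeleton_p[j-1]`` / ``skeleton_q[k-1]`` are the prior guesses of the
    single-agent DLT probabilities at the j-th dose of A and k-th dose of B,
    strictly increasing and in (0, 1).  ``levels_a`` / ``levels_b`` are
    optional dose labels (defaults: 1..J, 1..K).
    """

    skeleton_p: tuple
    skeleton_q: tuple
    levels_a: tuple | None = None
    levels_b: tuple | None = None
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "skeleton_p", tuple(float(p) for p in self.skeleton_p))
        object.__setattr__(self, "skeleton_q", tuple(float(q) for q in self.skeleton_q))
        if self.levels_a is not None:
            object.__setattr__(self, "levels_a", tuple(self.levels_a))
        if self.levels_b is not None:
            object.__setattr__(self, "levels_b", tuple(self.levels_b))
        if self.J < 1 or self.K < 1:
            raise ValueError("grid must have at least one dose level per drug")
        for name, skel in (("skeleton_p", self.skeleton_p), ("skeleton_q", self.skeleton_q)):
            if not all(0.0 < s < 1.0 for s in skel):
                raise ValueError(f"{name} values must lie in (0, 1)")
            if self.validate and not all(a < b for a, b in zip(skel, skel[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.levels_a is not None and len(self.levels_a) != self.J:
            raise ValueError("levels_a length must match skeleton_p")
        if self.levels_b is not None and len(self.levels_b) != self.K:
            raise ValueError("levels_b length must match skeleton_q")

    @property
    def J(self) -> int:
        return len(self.skeleton_p)

    @property
    def K(self) -> int:
        return len(self.skeleton_q)

    def label_a(self, j: int):
        return self.levels_a[j - 1] if self.levels_a else j

    def label_b(self, k: int):
        return self.levels_b[k - 1] if self.levels_b else k


@dataclass(frozen=True)
class ModelParams:
    """Copula parameters psi = (alpha, beta, gamma, lambda).

    alpha, beta >= 0 are the marginal skeleton powers, gamma the interaction,
    and ``lam`` in [0, 1) the fraction of drug A's full-cycle toxicity realized
    before drug B is given.
    """

    alpha: float
    beta: float
    gamma: float
    lam: float = 0.0

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "lam"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if not 0.0 <= self.lam < 1.0:
            raise ValueError("lam must lie in [0, 1)")


@dataclass(frozen=True)
class CycleTiming:
    """Administration time of drug B (``t_B``) and cycle length ``T``, 0 < t_B < T."""

    t_B: float
    T: float

    def __post_init__(self):
        if not 0.0 < self.t_B < self.T:
            raise ValueError("need 0 < t_B < T")


@dataclass(frozen=True)
class OutcomeProbs:
    """Probabilities of the trinary outcome (Y=0, Y=1, Y=2) at one combination."""

    p0: float
    p1: float
    p2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2])


def _marginal_a(grid: DoseGrid, params: ModelParams, j: int) -> float:
    if not 1 <= j <= grid.J:
        raise IndexError(f"dose index j={j} outside 1..{grid.J}")
    return grid.skeleton_p[j - 1] ** params.alpha


def _marginal_b(grid: DoseGrid, params: ModelParams, k: int) -> float:
    if k == 0:  # drug B absent
        return 0.0
    if not 1 <= k <= grid.K:
        raise IndexError(f"dose index k={k} outside 0..{grid.K}")
    return grid.skeleton_q[k - 1] ** params.beta


def pi_T(grid: DoseGrid, params: ModelParams, j: int, k: int) -> float:
    """Full-cycle DLT probability at combination (a_j, b_k) under the FGM copula.

    ``k = 0`` denotes drug B absent, reducing to the marginal ``p_j ** alpha``.
    """
    u = _marginal_a(grid, params, j)
    v = _marginal_b(grid, params, k)
    t = np.tanh(params.gamma / 2.0)  # == (e^g - 1)/(e^g + 1), overflow-safe
    return float(1.0 - (1.0 - u) * (1.0 - v) + u * (1.0 - u) * v * (1.0 - v) * t)


def pi_tB(grid: DoseGrid, params: ModelParams, j: int) -> float:
    """Probability of a DLT before drug B is given: ``lambda * p_j ** alpha``."""
    return float(params.lam * _marginal_a(grid, params, j))


def outcome_probs(grid: DoseGrid, params: ModelParams, j: int, k: int) -> OutcomeProbs:
    """Trinary outcome probabilities at (a_j, b_k).

    p1 = lambda * pi_T(a_j, 0) does not depend on k: a pre-``t_B`` DLT occurs
    before drug B could be given.  p2 = pi_T - p1 is non-negative because
    lambda < 1 and pi_T(a_j, b_k) >= pi_T(a_j, 0).
    """
    full = pi_T(grid, params, j, k)
    pre = pi_tB(grid, params, j)
    return OutcomeProbs(p0=1.0 - full, p1=pre, p2=full - pre)


def pi_T_surface(grid: DoseGrid, params: ModelParams, include_absent: bool = False) -> np.ndarray:
    """The J x K matrix of pi_T over the grid (optionally with a k=0 column first)."""
    u = np.asarray(grid.skeleton_p) ** params.alpha
    q = np.asarray(grid.skeleton_q)
    if include_absent:
        q = np.concatenate([[0.0], q])
    v = np.where(q > 0, q, 1.0) ** params.beta * (q > 0)
    t = np.tanh(params.gamma / 2.0)
    U, V = u[:, None], v[None, :]
    return 1.0 - (1.0 - U) * (1.0 - V) + U * (1.0 - U) * V * (1.0 - V) * t


def pi_T_surfaces_from_draws(
    grid: DoseGrid, alpha: np.ndarray, beta: np.ndarray, gamma: np.ndarray
) -> np.ndarray:
    """Vectorized pi_T surfaces, shape (n_draws, J, K), for posterior summaries."""
    p = np.asarray(grid.skeleton_p)
    q = np.asarray(grid.skeleton_q)
    u = p[None, :] ** np.asarray(alpha)[:, None]  # (n, J)
    v = q[None, :] ** np.asarray(beta)[:, None]  # (n, K)
    t = np.tanh(np.asarray(gamma) / 2.0)[:, None, None]
    U = u[:, :, None]
    V = v[:, None, :]
    return 1.0 - (1.0 - U) * (1.0 - V) + U * (1.0 - U) * V * (1.0 - V) * t


def check_conditions(grid: DoseGrid, params: ModelParams, tol: float = 1e-12) -> dict:
    """Numerically verify the model's structural conditions over the grid.

    Returns a report with one boolean per condition:

    - ``pi_tB_zero_at_zero_dose``: pi_tB vanishes when drug A is absent;
    - ``pi_tB_monotone_in_a``: pi_tB non-decreasing in the dose of A;
    - ``pi_T_zero_at_zero_dose``: pi_T(0, 0) = 0;
    - ``pi_T_dominates_pi_tB``: pi_T(a_j, b_k) >= pi_tB(a_j) for every k >= 0;
    - ``pi_T_monotone_in_a`` / ``pi_T_monotone_in_b``: monotone surface.

    A failure is reported, not raised: with monotone skeletons the FGM family
    satisfies all conditions, so a failure flags a misconfigured grid.
    """
    # 0**alpha == 0 only for alpha > 0; evaluate the zero-dose marginals directly.
    zero_a = 0.0 ** params.alpha if params.alpha > 0 else 1.0
    surface = pi_T_surface(grid, params, include_absent=True)  # (J, K+1), col 0 = B absent
    pre = params.lam * surface[:, 0]
    report = {
        "pi_tB_zero_at_zero_dose": params.lam * zero_a <= tol,
        "pi_tB_monotone_in_a": bool(np.all(np.diff(pre) >= -tol)),
        "pi_T_zero_at_zero_dose": zero_a <= tol,  # pi_T(0, 0) reduces to 0**alpha
        "pi_T_dominates_pi_tB": bool(np.all(surface >= pre[:, None] - tol)),
        "pi_T_monotone_in_a": bool(np.all(np.diff(surface, axis=0) >= -tol)),
        "pi_T_monotone_in_b": bool(np.all(np.diff(surface, axis=1) >= -tol)),
    }
    report["all_pass"] = all(report.values())
    return report
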