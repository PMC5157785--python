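"""Adaptive random-walk Metropolis kernel (numba-compiled).

The posterior over (alpha, beta, gamma[, lambda]) is sampled on an
unconstrained scale: alpha and beta via a scaled logit over their uniform
prior support, lambda via a logit, gamma untransformed.  Log-Jacobians are
included so the chain targets the posterior of the natural parameters.
Component scales adapt toward ~44% acceptance during burn-in only, leaving
the post-burn-in chain a valid fixed-kernel Metropolis sampler.

The likelihood is evaluated from per-cell outcome counts rather than
per-patient records: n0[j,k] patients with no DLT at (a_j, b_k), n1[j] with a
pre-t_B DLT at a_j (drug B withheld), n2[j,k] with a post-t_B DLT.  Under the
non-attributable (NA) analysis n1 is folded into n2 at the planned dose pair
and lambda is not a model parameter.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODEL_SA = 0
MODEL_NA = 1


@njit(cache=True)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _log_post(
    z,
    p_skel,
    q_skel,
    n0,
    n1,
    n2,
    model,
    a_lo,
    a_hi,
    b_lo,
    b_hi,
    gamma_mean,
    gamma_var,
    est_lam,
    lam_fixed,
    lam_shape_a,
    lam_shape_b,
):
    J = p_skel.shape[0]
    K = q_skel.shape[0]

    # --- transforms and log prior (incl. Jacobians; additive constants dropped)
    sa_ = _sigmoid(z[0])
    sb_ = _sigmoid(z[1])
    alpha = a_lo + (a_hi - a_lo) * sa_
    beta = b_lo + (b_hi - b_lo) * sb_
    gamma = z[2]
    lp = np.log(sa_ * (1.0 - sa_)) + np.log(sb_ * (1.0 - sb_))
    lp += -0.5 * (gamma - gamma_mean) ** 2 / gamma_var

    lam = 0.0
    if model == MODEL_SA:
        if est_lam:
            sl = _sigmoid(z[3])
            lam = sl
            if lam <= 0.0 or lam >= 1.0:
                return -np.inf
            # Beta(a, b) density plus logit Jacobian lam * (1 - lam)
            lp += lam_shape_a * np.log(lam) + lam_shape_b * np.log(1.0 - lam)
        else:
            lam = lam_fixed

    # --- likelihood from counts
    t = np.tanh(gamma / 2.0)
    ll = 0.0
    for j in range(J):
        u = p_skel[j] ** alpha
        pre = lam * u
        if model == MODEL_SA and n1[j] > 0:
            if pre <= 0.0:
                return -np.inf
            ll += n1[j] * np.log(pre)
        for k in range(K):
            if n0[j, k] == 0 and n2[j, k] == 0:
                continue
            v = q_skel[k] ** beta
            pi = 1.0 - (1.0 - u) * (1.0 - v) + u * (1.0 - u) * v * (1.0 - v) * t
            if n0[j, k] > 0:
                if pi >= 1.0:
                    return -np.inf
                ll += n0[j, k] * np.log(1.0 - pi)
            if n2[j, k] > 0:
                if model == MODEL_SA:
                    cell = pi - pre
                else:
                    cell = pi
                if cell <= 0.0:
                    return -np.inf
                ll += n2[j, k] * np.log(cell)
    return lp + ll


@njit(cache=True)
def run_chain(
    seed,
    n_burn,
    n_iter,
    thin,
    z_init,
    scale_init,
    p_skel,
    q_skel,
    n0,
    n1,
    n2,
    model,
    a_lo,
    a_hi,
    b_lo,
    b_hi,
    gamma_mean,
    gamma_var,
    est_lam,
    lam_fixed,
    lam_shape_a,
    lam_shape_b,
):
    """One Metropolis chain; returns (draws on the natural scale, acceptance rates).

    ``draws`` has shape (n_iter // thin, 4): columns alpha, beta, gamma, lambda
    (lambda = lam_fixed or 0 when not estimated).  Scales adapt every 25
    burn-in sweeps toward 44% component acceptance and are then frozen.
    """
    np.random.seed(seed)
    dims = 4 if (model == MODEL_SA and est_lam) else 3
    z = z_init.copy()
    scales = scale_init.copy()
    lp = _log_post(
        z, p_skel, q_skel, n0, n1, n2, model,
        a_lo, a_hi, b_lo, b_hi, gamma_mean, gamma_var,
        est_lam, lam_fixed, lam_shape_a, lam_shape_b,
    )
    n_keep = n_iter // thin
    draws = np.empty((n_keep, 4))
    acc = np.zeros(4)
    tries = np.zeros(4)
    adapt_acc = np.zeros(4)
    adapt_try = np.zeros(4)
    kept = 0
    for it in range(n_burn + n_iter):
        for d in range(dims):
            old = z[d]
            z[d] = old + scales[d] * np.random.normal()
            lp_new = _log_post(
                z, p_skel, q_skel, n0, n1, n2, model,
                a_lo, a_hi, b_lo, b_hi, gamma_mean, gamma_var,
                est_lam, lam_fixed, lam_shape_a, lam_shape_b,
            )
            accept = lp_new > -np.inf and np.log(np.random.random()) < lp_new - lp
            if accept:
                lp = lp_new
            else:
                z[d] = old
            if it < n_burn:
                adapt_try[d] += 1.0
                if accept:
                    adapt_acc[d] += 1.0
            else:
                tries[d] += 1.0
                if accept:
                    acc[d] += 1.0
        if it < n_burn:
            if (it + 1) % 25 == 0:
                for d in range(dims):
                    if adapt_try[d] > 0:
                        rate = adapt_acc[d] / adapt_try[d]
                        scales[d] *= np.exp(1.5 * (rate - 0.44))
                        if scales[d] < 1e-3:
                            scales[d] = 1e-3
                        elif scales[d] > 50.0:
                            scales[d] = 50.0
                    adapt_acc[d] = 0.0
                    adapt_try[d] = 0.0
        else:
            if (it - n_burn) % thin == thin - 1:
                draws[kept, 0] = a_lo + (a_hi - a_lo) * _sigmoid(z[0])
                draws[kept, 1] = b_lo + (b_hi - b_lo) * _sigmoid(z[1])
                draws[kept, 2] = z[2]
                if model == MODEL_SA and est_lam:
                    draws[kept, 3] = _sigmoid(z[3])
                elif model == MODEL_SA:
                    draws[kept, 3] = lam_fixed
                else:
                    draws[kept, 3] = 0.0
                kept += 1
    rates = np.zeros(4)
    for d in range(dims):
        if tries[d] > 0:
            rates[d] = acc[d] / tries[d]
    return draws[:kept], rates


@njit(cache=True)
def log_post_value(
    z, p_skel, q_skel, n0, n1, n2, model,
    a_lo, a_hi, b_lo, b_hi, gamma_mean, gamma_var,
    est_lam, lam_fixed, lam_shape_a, lam_shape_b,
):
    """Expose the kernel's log-posterior for initialization checks."""
    return _log_post(
        z, p_skel, q_skel, n0, n1, n2, model,
        a_lo, a_hi, b_lo, b_hi, gamma_mean, gamma_var,
        est_lam, lam_fixed, lam_shape_a, lam_shape_b,
    )
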