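"""Packaged true dose-toxicity scenarios for the 4x4 simulation grid.

Six full-cycle DLT probability tables over the reference 4x4 grid, each
paired with pre-``t_B`` marginal DLT probabilities for true attributable
fractions lambda_TR in {2/14, 8/14, 13/14}, plus a sensitivity scenario in
which lambda_TR increases with the dose of drug A.  The printed 2-dp table
values are treated as exact truth; scenario 1 is additionally
parameter-generated (alpha = beta = 1, gamma = 0, the prior centre).
"""

from __future__ import annotations

import numpy as np

from .core_model import DoseGrid, ModelParams

__all__ = ["PAPER_GRID", "load_packaged_scenarios", "packaged_scenario_names"]

#: Reference grid: skeleton DLT probabilities for four doses of each drug.
PAPER_GRID = DoseGrid(
    skeleton_p=(0.10, 0.15, 0.20, 0.25),
    skeleton_q=(0.06, 0.12, 0.18, 0.25),
)

# Full-cycle DLT probability tables, printed layout: one row per dose of drug B
# from b_4 (top) to b_1 (bottom), columns a_1..a_4.
_PI_T_PRINTED = {
    1: [
        [0.32, 0.36, 0.40, 0.44],
        [0.26, 0.30, 0.34, 0.38],
        [0.21, 0.25, 0.30, 0.34],
        [0.15, 0.20, 0.25, 0.30],
    ],
    2: [
        [0.17, 0.19, 0.22, 0.25],
        [0.12, 0.15, 0.17, 0.21],
        [0.08, 0.11, 0.14, 0.18],
        [0.06, 0.08, 0.12, 0.15],
    ],
    3: [
        [0.18, 0.22, 0.25, 0.29],
        [0.13, 0.17, 0.21, 0.25],
        [0.10, 0.14, 0.18, 0.22],
        [0.08, 0.11, 0.16, 0.20],
    ],
    4: [
        [0.27, 0.32, 0.36, 0.41],
        [0.23, 0.28, 0.33, 0.38],
        [0.20, 0.25, 0.31, 0.36],
        [0.17, 0.23, 0.29, 0.34],
    ],
    5: [
        [0.33, 0.39, 0.44, 0.48],
        [0.29, 0.34, 0.40, 0.45],
        [0.25, 0.31, 0.37, 0.42],
        [0.22, 0.28, 0.34, 0.39],
    ],
    6: [
        [0.46, 0.48, 0.51, 0.53],
        [0.39, 0.41, 0.43, 0.46],
        [0.31, 0.34, 0.36, 0.40],
        [0.22, 0.25, 0.28, 0.31],
    ],
}

# Pre-t_B marginal DLT probabilities, printed layout: one row per dose of drug A
# from a_4 (top) to a_1 (bottom), columns lambda_TR = 2/14, 8/14, 13/14.
_PRE_TB_PRINTED = {
    1: [[0.04, 0.14, 0.23], [0.03, 0.11, 0.19], [0.02, 0.09, 0.14], [0.01, 0.06, 0.09]],
    2: [[0.02, 0.08, 0.13], [0.01, 0.06, 0.09], [0.01, 0.04, 0.06], [0.01, 0.02, 0.04]],
    3: [[0.03, 0.11, 0.17], [0.02, 0.08, 0.13], [0.01, 0.06, 0.09], [0.01, 0.04, 0.06]],
    4: [[0.05, 0.19, 0.31], [0.04, 0.16, 0.26], [0.03, 0.13, 0.20], [0.02, 0.09, 0.15]],
    5: [[0.05, 0.22, 0.35], [0.05, 0.19, 0.30], [0.04, 0.15, 0.25], [0.03, 0.11, 0.19]],
    6: [[0.02, 0.08, 0.13], [0.02, 0.06, 0.10], [0.01, 0.04, 0.07], [0.01, 0.02, 0.04]],
}

_LAMBDA_TR = {"lam2": 2 / 14, "lam8": 8 / 14, "lam13": 13 / 14}
_LAMBDA_COL = {"lam2": 0, "lam8": 1, "lam13": 2}

#: Dose-dependent attributable fractions of the sensitivity scenario
#: (lambda_TR(a_j) = 1/14, 3/14, 5/14, 8/14), giving these pre-t_B marginals.
SENSITIVITY_PRE_TB = (0.01, 0.06, 0.12, 0.22)


def _pi_t_matrix(scenario_number: int) -> np.ndarray:
    """(J, K) matrix indexed [j-1, k-1] from the printed (B-descending) layout."""
    printed = np.asarray(_PI_T_PRINTED[scenario_number])
    return printed[::-1].T.copy()


def _pre_tb_vector(scenario_number: int, lam_key: str) -> np.ndarray:
    printed = np.asarray(_PRE_TB_PRINTED[scenario_number])
    return printed[::-1, _LAMBDA_COL[lam_key]].copy()


def packaged_scenario_names() -> list:
    names = [f"scenario{s}-{key}" for s in range(1, 7) for key in ("lam2", "lam8", "lam13")]
    names.append("scenario5-sensitivity")
    return names


def load_packaged_scenarios() -> dict:
    """All 19 packaged scenarios, keyed by name (e.g. ``scenario2-lam8``)."""
    from .trial_sim import Scenario  # deferred: trial_sim imports this module's grid

    out = {}
    for s in range(1, 7):
        for key, lam_tr in _LAMBDA_TR.items():
            out[f"scenario{s}-{key}"] = Scenario(
                name=f"scenario{s}-{key}",
                grid=PAPER_GRID,
                true_pi_T=_pi_t_matrix(s),
                true_pre_tB=_pre_tb_vector(s, key),
                lambda_TR=lam_tr,
                true_params=ModelParams(1.0, 1.0, 0.0, lam_tr) if s == 1 else None,
            )
    out["scenario5-sensitivity"] = Scenario(
        name="scenario5-sensitivity",
        grid=PAPER_GRID,
        true_pi_T=_pi_t_matrix(5),
        true_pre_tB=np.asarray(SENSITIVITY_PRE_TB),
        lambda_TR=None,
    )
    return out
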