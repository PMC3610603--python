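"""Independent steady-state oracle for the noise-free networks.

Solves the algebraic fixed-point equations of the normalization dynamics by
damped fixed-point iteration on the rates themselves — no Euler integration,
no time axis — so it is an independent check on the ODE integrator.
"""

from __future__ import annotations

import numpy as np

from rivalnorm.params import ModelParams, mono_weight_matrix, sum_weight_matrix


def steady_state(
    model: str,
    c: np.ndarray,
    params: ModelParams,
    max_iter: int = 20000,
    tol: float = 1e-14,
    mixing: float = 0.5,
) -> dict[str, np.ndarray]:
    """Noise-free fixed point reached from zero rates.

    Iterates R <- (1-m) R + m * |E(R)|^2 / (sigma^2 + W |E(R)|^2) until
    convergence.  Starting from zero and with symmetric inputs this tracks
    the same (symmetric) attractor the integrator converges to.
    """
    c = np.asarray(c, dtype=float)
    W_m = mono_weight_matrix(params.weights)
    W_s = sum_weight_matrix(params.weights)
    w_ff = params.weights.w_ff
    sig_m = params.sigma**params.sigma_exponent
    sig_o = params.sigma_opp**params.sigma_exponent
    opponency = model == "opponency"

    r_m = np.zeros(4)
    r_s = np.zeros(2)
    r_o = np.zeros(4)
    for _ in range(max_iter):
        if opponency:
            inh = np.array([r_o[0] + r_o[1]] * 2 + [r_o[2] + r_o[3]] * 2)
        else:
            inh = 0.0
        e_m = np.maximum(c - inh, 0.0) ** 2
        r_m_new = e_m / (sig_m + W_m @ e_m)
        e_s = np.maximum(w_ff * (r_m[0:2] + r_m[2:4]), 0.0) ** 2
        r_s_new = e_s / (sig_m + W_s @ e_s)
        if opponency:
            d = np.array(
                [r_m[2] - r_m[0], r_m[3] - r_m[1], r_m[0] - r_m[2], r_m[1] - r_m[3]]
            )
            e_o = np.maximum(d, 0.0) ** 2
            den = sig_o + np.array(
                [e_o[0] + e_o[1]] * 2 + [e_o[2] + e_o[3]] * 2
            )
            r_o_new = e_o / den
        else:
            r_o_new = r_o
        delta = max(
            np.max(np.abs(r_m_new - r_m)),
            np.max(np.abs(r_s_new - r_s)),
            np.max(np.abs(r_o_new - r_o)),
        )
        r_m = (1 - mixing) * r_m + mixing * r_m_new
        r_s = (1 - mixing) * r_s + mixing * r_s_new
        r_o = (1 - mixing) * r_o + mixing * r_o_new
        if delta < tol:
            break
    return {"r_mono": r_m, "r_sum": r_s, "r_opp": r_o}
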