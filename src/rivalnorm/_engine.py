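"""Batched forward-Euler integrator for the rivalry/normalization networks.

The integrator advances a batch of independent networks in lockstep: the
batch axis carries replicates (same parameters, different noise) or
grid-search parameterizations (per-batch weight matrices).  All updates are
explicit Euler from the previous step's state, including the opponency
feedback loop.

Neuron order within layers: mono = (LA, LB, RA, RB), sum = (A, B),
opp = (RL_A, RL_B, LR_A, LR_B).  Noise channel order: mono(4), sum(2),
then opp(4) for the opponency model.
"""

from __future__ import annotations

import numpy as np

N_MONO = 4
N_SUM = 2
N_OPP = 4


class SimulationBlowupError(RuntimeError):
    """Numerical blow-up: a non-finite state value during integration."""

    def __init__(self, step: int, t_ms: float):
        self.step = step
        self.t_ms = t_ms
        super().__init__(
            f"non-finite network state at step {step} (t = {t_ms:g} ms); "
            "check parameter magnitudes and the time step"
        )


def n_noise_channels(model: str) -> int:
    return N_MONO + N_SUM + (N_OPP if model == "opponency" else 0)


def integrate(
    model: str,
    contrasts: np.ndarray,
    noise: np.ndarray,
    *,
    W_mono: np.ndarray,
    W_sum: np.ndarray,
    w_ff,
    sigma: float,
    sigma_opp: float,
    tau_ms: float,
    dt_ms: float,
    adapt_enabled: bool = False,
    tau_adapt_s: float = 80.0,
    adapt_scale: float = 0.5,
    noise_on_opponency: bool = True,
    noise_on_summation: bool = False,
    sigma_exponent: int = 2,
    record: tuple[str, ...] = ("mono", "sum", "opp", "adapt"),
    record_from: int = 0,
    init_state: dict[str, np.ndarray] | None = None,
    check_every: int = 500,
    on_blowup: str = "raise",
) -> dict[str, np.ndarray]:
    """Integrate a batch of networks.

    Parameters
    ----------
    contrasts : (n_steps, 4) stimulus contrast per step (shared by batch).
    noise : (B, C, n_steps) pre-generated noise, C = 6 or 10 per model.
    W_mono, W_sum : pool weight matrices, (4,4)/(2,2) or batched (B,4,4)/(B,2,2).
    w_ff : scalar or (B,) feedforward weight.
    record : subset of {"mono","sum","opp","adapt"} to store as traces.
    record_from : first step index stored in the trace arrays.
    init_state : optional {"r_mono","r_sum","r_opp","a_mono","a_sum","a_opp"}
        arrays to resume from (each (B, n)); zeros otherwise.
    on_blowup : "raise" aborts with :class:`SimulationBlowupError`;
        "mask" runs to completion and returns a per-batch ``blown`` flag.

    Returns
    -------
    dict with final-state arrays, requested trace arrays of shape
    (B, n_recorded, n), and a ``blown`` boolean mask.
    """
    opponency = model == "opponency"
    n_steps = contrasts.shape[0]
    B = noise.shape[0]
    expected_c = n_noise_channels(model)
    if noise.shape[1] != expected_c or noise.shape[2] != n_steps:
        raise ValueError(
            f"noise must have shape (B, {expected_c}, {n_steps}), got {noise.shape}"
        )

    W_mono = np.asarray(W_mono, dtype=float)
    W_sum = np.asarray(W_sum, dtype=float)
    batched_w = W_mono.ndim == 3
    if not batched_w:
        Wm_T = W_mono.T.copy()
        Ws_T = W_sum.T.copy()
    w_ff = np.asarray(w_ff, dtype=float)
    if w_ff.ndim == 1:
        w_ff = w_ff[:, None]

    k_ad = adapt_scale if adapt_enabled else 0.0
    dt_tau = dt_ms / tau_ms
    dt_tau_a = dt_ms / (tau_adapt_s * 1000.0)
    sig_m = sigma**sigma_exponent
    sig_o = sigma_opp**sigma_exponent

    def _init(key, n):
        if init_state is not None and key in init_state:
            return np.array(init_state[key], dtype=float).reshape(B, n).copy()
        return np.zeros((B, n))

    r_m = _init("r_mono", N_MONO)
    r_s = _init("r_sum", N_SUM)
    r_o = _init("r_opp", N_OPP) if opponency else np.zeros((B, 0))
    a_m = _init("a_mono", N_MONO)
    a_s = _init("a_sum", N_SUM)
    a_o = _init("a_opp", N_OPP) if opponency else np.zeros((B, 0))

    n_rec = max(0, n_steps - record_from)
    traces: dict[str, np.ndarray] = {}
    if "mono" in record:
        traces["mono"] = np.empty((B, n_rec, N_MONO))
    if "sum" in record:
        traces["sum"] = np.empty((B, n_rec, N_SUM))
    if "opp" in record and opponency:
        traces["opp"] = np.empty((B, n_rec, N_OPP))
    if "adapt" in record and adapt_enabled:
        traces["adapt_mono"] = np.empty((B, n_rec, N_MONO))
        traces["adapt_sum"] = np.empty((B, n_rec, N_SUM))
        if opponency:
            traces["adapt_opp"] = np.empty((B, n_rec, N_OPP))

    def _check(step: int) -> bool:
        ok = np.isfinite(r_m).all() and np.isfinite(r_s).all()
        if opponency:
            ok = ok and np.isfinite(r_o).all()
        if not ok and on_blowup == "raise":
            raise SimulationBlowupError(step, step * dt_ms)
        return bool(ok)

    blown_at = -1
    for k in range(n_steps):
        c = contrasts[k]

        # Drives from the previous step's state.
        E_m = c + noise[:, 0:N_MONO, k] - k_ad * a_m
        if opponency:
            inh_left = r_o[:, 0] + r_o[:, 1]  # RL neurons inhibit left eye
            inh_right = r_o[:, 2] + r_o[:, 3]  # LR neurons inhibit right eye
            E_m[:, 0] -= inh_left
            E_m[:, 1] -= inh_left
            E_m[:, 2] -= inh_right
            E_m[:, 3] -= inh_right
        E_s = w_ff * (r_m[:, 0:2] + r_m[:, 2:4]) - k_ad * a_s
        if noise_on_summation:
            E_s = E_s + noise[:, N_MONO : N_MONO + N_SUM, k]
        if opponency:
            d_a = r_m[:, 2] - r_m[:, 0]  # right minus left, orientation A
            d_b = r_m[:, 3] - r_m[:, 1]
            E_o = np.stack((d_a, d_b, -d_a, -d_b), axis=1)
            if noise_on_opponency:
                E_o += noise[:, N_MONO + N_SUM :, k]
            E_o -= k_ad * a_o

        # Normalization updates (half-squared drives, pooled denominators).
        Em2 = np.square(np.maximum(E_m, 0.0))
        Es2 = np.square(np.maximum(E_s, 0.0))
        if batched_w:
            den_m = sig_m + np.einsum("bij,bj->bi", W_mono, Em2)
            den_s = sig_m + np.einsum("bij,bj->bi", W_sum, Es2)
        else:
            den_m = sig_m + Em2 @ Wm_T
            den_s = sig_m + Es2 @ Ws_T
        r_m_new = r_m + dt_tau * (Em2 / den_m - r_m)
        r_s_new = r_s + dt_tau * (Es2 / den_s - r_s)
        if opponency:
            Eo2 = np.square(np.maximum(E_o, 0.0))
            pool_rl = Eo2[:, 0:2].sum(axis=1, keepdims=True)
            pool_lr = Eo2[:, 2:4].sum(axis=1, keepdims=True)
            den_o = sig_o + np.concatenate(
                (pool_rl, pool_rl, pool_lr, pool_lr), axis=1
            )
            r_o_new = r_o + dt_tau * (Eo2 / den_o - r_o)

        if adapt_enabled:
            a_m = a_m + dt_tau_a * (r_m - a_m)
            a_s = a_s + dt_tau_a * (r_s - a_s)
            if opponency:
                a_o = a_o + dt_tau_a * (r_o - a_o)

        r_m, r_s = r_m_new, r_s_new
        if opponency:
            r_o = r_o_new

        if k >= record_from:
            i = k - record_from
            if "mono" in traces:
                traces["mono"][:, i] = r_m
            if "sum" in traces:
                traces["sum"][:, i] = r_s
            if "opp" in traces:
                traces["opp"][:, i] = r_o
            if "adapt_mono" in traces:
                traces["adapt_mono"][:, i] = a_m
                traces["adapt_sum"][:, i] = a_s
                if opponency:
                    traces["adapt_opp"][:, i] = a_o

        if check_every and (k + 1) % check_every == 0:
            if not _check(k) and blown_at < 0:
                blown_at = k

    if not _check(n_steps - 1) and blown_at < 0:
        blown_at = n_steps - 1

    blown = np.zeros(B, dtype=bool)
    if blown_at >= 0:

        def _bad(x):
            return ~np.isfinite(x).all(axis=tuple(range(1, x.ndim)))

        blown = _bad(r_m) | _bad(r_s)
        if opponency:
            blown |= _bad(r_o)
        for arr in traces.values():
            blown |= _bad(arr)

    out = {
        "r_mono": r_m,
        "r_sum": r_s,
        "r_opp": r_o,
        "a_mono": a_m,
        "a_sum": a_s,
        "a_opp": a_o,
        "blown": blown,
    }
    out.update(traces)
    return out
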