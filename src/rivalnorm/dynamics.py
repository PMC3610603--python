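"""Firing-rate dynamics of the conventional and opponency models.

Both models are networks of rate units obeying a dynamical variant of
divisive normalization:

    tau dR_i/dt = -R_i + |E_i|_+^2 / (sigma^2 + sum_j w_ij |E_j|_+^2)

where |x|_+ = max(x, 0) is halfwave rectification, E_i is the neuron's
unnormalized drive, and j ranges over the neuron's normalization pool.
The conventional model pools all four monocular neurons together and the
two summation neurons together.  The opponency model adds four ocular
opponency neurons (rectified right-minus-left and left-minus-right
differences per orientation, pooled RL-with-RL and LR-with-LR under
sigma_opp) whose output is subtracted from the monocular drives of the eye
they receive inhibition from.

Long-term adaptation, when enabled, is a per-neuron first-order lowpass of
the rate, da/dt = (R - a)/tau_a, scaled and subtracted from the drive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import noise as noise_mod
from ._engine import (
    N_MONO,
    N_OPP,
    N_SUM,
    SimulationBlowupError,
    integrate,
    n_noise_channels,
)
from .params import (
    MODELS,
    MONO_NEURONS,
    OPP_NEURONS,
    SUM_NEURONS,
    ModelParams,
    mono_weight_matrix,
    sum_weight_matrix,
)
from .stimuli import StimulusSpec

__all__ = [
    "NetworkState",
    "SimulationResult",
    "drive_conventional",
    "drive_opponency_model",
    "normalization_rhs",
    "adaptation_rhs",
    "simulate",
    "SimulationBlowupError",
]

#: Integration steps the simulations were designed around (ms).
STANDARD_DT_MS = (2.0, 10.0)


@dataclass
class NetworkState:
    """Instantaneous rates and adaptation variables of one network.

    ``r_opp`` is empty for the conventional model.  ``a`` concatenates the
    per-neuron adaptation variables in layer order (mono, sum, opp).
    """

    r_mono: np.ndarray = field(default_factory=lambda: np.zeros(N_MONO))
    r_sum: np.ndarray = field(default_factory=lambda: np.zeros(N_SUM))
    r_opp: np.ndarray = field(default_factory=lambda: np.zeros(0))
    a: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.r_mono) + len(self.r_sum) + len(self.r_opp)
        if self.a is None:
            self.a = np.zeros(n)
        if len(self.a) != n:
            raise ValueError(f"adaptation vector must have length {n}")


def drive_conventional(
    state: NetworkState, c: np.ndarray, n: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Unnormalized drives of the 6 conventional-model neurons.

    Monocular drive: stimulus contrast plus noise (minus scaled adaptation
    when enabled).  Summation drive: feedforward-weighted sum of the two
    iso-oriented monocular rates (plus direct noise only when
    ``params.noise_on_summation``).

    Parameters
    ----------
    c : 4-vector of contrasts (LA, LB, RA, RB).
    n : 6-vector of per-neuron noise values (mono then sum).

    Returns the drives ordered (mono LA, LB, RA, RB, sum A, B).
    """
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    k = params.adapt_scale if params.adapt_enabled else 0.0
    e_mono = c + n[:N_MONO] - k * state.a[:N_MONO]
    w_ff = params.weights.w_ff
    r = state.r_mono
    e_sum = (
        w_ff * np.array([r[0] + r[2], r[1] + r[3]])
        - k * state.a[N_MONO : N_MONO + N_SUM]
    )
    if params.noise_on_summation:
        e_sum = e_sum + n[N_MONO : N_MONO + N_SUM]
    return np.concatenate([e_mono, e_sum])


def drive_opponency_model(
    state: NetworkState, c: np.ndarray, n: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Unnormalized drives of the 10 opponency-model neurons.

    Opponency drive (RL, orientation theta) = R_right,theta - R_left,theta;
    LR is the mirror difference.  Through feedback, the RL pair inhibits
    both left-eye monocular neurons and the LR pair both right-eye ones.
    All connection weights are 1 in this model.

    ``n`` is a 10-vector (mono, sum, opp); opponency noise is applied only
    when ``params.noise_on_opponency``.

    Returns drives ordered (mono LA..RB, sum A, B, opp RL_A, RL_B, LR_A, LR_B).
    """
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    k = params.adapt_scale if params.adapt_enabled else 0.0
    r = state.r_mono
    o = state.r_opp if len(state.r_opp) == N_OPP else np.zeros(N_OPP)
    a = state.a if len(state.a) == N_MONO + N_SUM + N_OPP else np.zeros(10)

    inh_left = o[0] + o[1]
    inh_right = o[2] + o[3]
    e_mono = c + n[:N_MONO] - k * a[:N_MONO]
    e_mono -= np.array([inh_left, inh_left, inh_right, inh_right])
    e_sum = np.array([r[0] + r[2], r[1] + r[3]]) - k * a[N_MONO : N_MONO + N_SUM]
    if params.noise_on_summation:
        e_sum = e_sum + n[N_MONO : N_MONO + N_SUM]
    d_a = r[2] - r[0]
    d_b = r[3] - r[1]
    e_opp = np.array([d_a, d_b, -d_a, -d_b])
    if params.noise_on_opponency:
        e_opp = e_opp + n[N_MONO + N_SUM :]
    e_opp = e_opp - k * a[N_MONO + N_SUM :]
    return np.concatenate([e_mono, e_sum, e_opp])


def normalization_rhs(
    E: np.ndarray,
    R: np.ndarray,
    pool_weights: np.ndarray,
    sigma_pool: float,
    tau_ms: float,
    sigma_exponent: int = 2,
) -> np.ndarray:
    """dR/dt (per ms) for one normalization pool.

    dR_i/dt = (1/tau) * (-R_i + |E_i|_+^2 / (sigma^p + sum_j w_ij |E_j|_+^2)).
    """
    if sigma_pool <= 0:
        raise ValueError("sigma_pool must be > 0")
    e2 = np.square(np.maximum(np.asarray(E, dtype=float), 0.0))
    den = sigma_pool**sigma_exponent + np.asarray(pool_weights) @ e2
    return (-np.asarray(R, dtype=float) + e2 / den) / tau_ms


def adaptation_rhs(R: np.ndarray, a: np.ndarray, tau_adapt_s: float) -> np.ndarray:
    """da/dt (per second): first-order lowpass of the rate, (R - a)/tau_a."""
    if tau_adapt_s <= 0:
        raise ValueError("tau_adapt_s must be > 0")
    return (np.asarray(R, dtype=float) - np.asarray(a, dtype=float)) / tau_adapt_s


@dataclass
class SimulationResult:
    """Full trace record of one simulation run.

    ``traces`` maps canonical neuron names (mono_LA, ..., sum_A, sum_B,
    opp_RL_A, ..., plus adapt_* when adaptation is enabled) to 1-D arrays
    sampled once per Euler step, starting at t = dt.
    """

    t_ms: np.ndarray
    traces: dict[str, np.ndarray]
    params: ModelParams
    model: str
    stimulus_label: str
    dt_ms: float
    seed: int

    @property
    def r_mono(self) -> np.ndarray:
        return np.stack([self.traces[k] for k in MONO_NEURONS], axis=1)

    @property
    def r_sum(self) -> np.ndarray:
        return np.stack([self.traces[k] for k in SUM_NEURONS], axis=1)

    @property
    def r_opp(self) -> np.ndarray:
        if self.model != "opponency":
            return np.zeros((len(self.t_ms), 0))
        return np.stack([self.traces[k] for k in OPP_NEURONS], axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Traces as a DataFrame with a leading time_ms column."""
        data = {"time_ms": self.t_ms}
        data.update(self.traces)
        return pd.DataFrame(data)


def _neuron_names(model: str, adapt_enabled: bool) -> list[str]:
    names = list(MONO_NEURONS) + list(SUM_NEURONS)
    if model == "opponency":
        names += list(OPP_NEURONS)
    if adapt_enabled:
        names += [f"adapt_{n}" for n in names[: len(names)]]
    return names


def simulate(
    model: str,
    stimulus: StimulusSpec,
    params: ModelParams,
    dt_ms: float = 2.0,
    seed: int | None = None,
    noise_matrix: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate one model/stimulus pair with forward Euler from zero state.

    Noise is pre-generated for every neuron over the full duration from
    ``seed`` (default: ``params.noise.seed``); passing ``noise_matrix``
    (shape (n_channels, n_steps)) overrides generation, which the symmetry
    tests use to permute noise channels explicitly.

    Deterministic given (model, stimulus, params, dt, seed).  Raises
    :class:`SimulationBlowupError` naming the step on numerical blow-up.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if dt_ms <= 0:
        raise ValueError(f"dt_ms must be > 0, got {dt_ms}")
    if float(dt_ms) not in STANDARD_DT_MS:
        warnings.warn(
            f"dt_ms = {dt_ms} differs from the standard steps {STANDARD_DT_MS}; "
            "results may not be directly comparable",
            stacklevel=2,
        )
    if seed is None:
        seed = params.noise.seed

    n_steps = int(round(stimulus.duration_s * 1000.0 / dt_ms))
    if n_steps <= 0:
        raise ValueError("stimulus too short for this time step")
    t_s = np.arange(n_steps) * (dt_ms / 1000.0)  # left edge of each step
    contrasts = stimulus.sample(t_s)
    if contrasts.min() < 0 or contrasts.max() > 1:
        raise ValueError("stimulus contrasts must lie in [0, 1]")

    n_ch = n_noise_channels(model)
    if noise_matrix is None:
        from dataclasses import replace

        noise_matrix = noise_mod.generate(
            n_steps, dt_ms, n_ch, replace(params.noise, seed=int(seed))
        )
    noise_matrix = np.asarray(noise_matrix, dtype=float)
    if noise_matrix.shape != (n_ch, n_steps):
        raise ValueError(
            f"noise_matrix must have shape ({n_ch}, {n_steps}), "
            f"got {noise_matrix.shape}"
        )

    out = integrate(
        model,
        contrasts,
        noise_matrix[None, :, :],
        W_mono=mono_weight_matrix(params.weights),
        W_sum=sum_weight_matrix(params.weights),
        w_ff=params.weights.w_ff,
        sigma=params.sigma,
        sigma_opp=params.sigma_opp,
        tau_ms=params.tau_ms,
        dt_ms=dt_ms,
        adapt_enabled=params.adapt_enabled,
        tau_adapt_s=params.tau_adapt_s,
        adapt_scale=params.adapt_scale,
        noise_on_opponency=params.noise_on_opponency,
        noise_on_summation=params.noise_on_summation,
        sigma_exponent=params.sigma_exponent,
        record=("mono", "sum", "opp", "adapt"),
    )

    traces: dict[str, np.ndarray] = {}
    for i, name in enumerate(MONO_NEURONS):
        traces[name] = out["mono"][0, :, i]
    for i, name in enumerate(SUM_NEURONS):
        traces[name] = out["sum"][0, :, i]
    if model == "opponency":
        for i, name in enumerate(OPP_NEURONS):
            traces[name] = out["opp"][0, :, i]
    if params.adapt_enabled:
        for i, name in enumerate(MONO_NEURONS):
            traces[f"adapt_{name}"] = out["adapt_mono"][0, :, i]
        for i, name in enumerate(SUM_NEURONS):
            traces[f"adapt_{name}"] = out["adapt_sum"][0, :, i]
        if model == "opponency":
            for i, name in enumerate(OPP_NEURONS):
                traces[f"adapt_{name}"] = out["adapt_opp"][0, :, i]

    t_ms = (np.arange(n_steps) + 1) * dt_ms
    return SimulationResult(
        t_ms=t_ms,
        traces=traces,
        params=params,
        model=model,
        stimulus_label=stimulus.label,
        dt_ms=float(dt_ms),
        seed=int(seed),
    )
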