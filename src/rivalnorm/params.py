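"""Model parameters for the rivalry/normalization network.

The network has three layers: four monocular neurons (left/right eye x
orientations A/B), two binocular summation neurons (A/B), and — in the
opponency model — four ocular opponency neurons (right-minus-left and
left-minus-right, per orientation).  Every parameter here is a property of
the network, not of a particular stimulus or run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace, asdict
from typing import Any

import numpy as np

#: Canonical neuron ordering used by every trace array in the package.
MONO_NEURONS = ("mono_LA", "mono_LB", "mono_RA", "mono_RB")
SUM_NEURONS = ("sum_A", "sum_B")
OPP_NEURONS = ("opp_RL_A", "opp_RL_B", "opp_LR_A", "opp_LR_B")

MODELS = ("conventional", "opponency")


@dataclass(frozen=True)
class NoiseParams:
    """Lowpass-filtered Gaussian noise added to each neuron's input.

    Parameters
    ----------
    amplitude : float
        Standard deviation of the stationary filtered noise process
        (dimensionless, in contrast units).  Default 0.05.
    smoothness_ms : float
        SD of the Gaussian temporal filter, in milliseconds.  Default 800.
    seed : int
        Master seed; per-channel sub-streams are derived from it.
    """

    amplitude: float = 0.05
    smoothness_ms: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"noise.amplitude must be >= 0, got {self.amplitude}")
        if self.smoothness_ms <= 0:
            raise ValueError(
                f"noise.smoothness_ms must be > 0, got {self.smoothness_ms}"
            )


@dataclass(frozen=True)
class Weights:
    """Connection weights of the conventional model.

    The four ``w_mono_*`` weights populate the monocular normalization pool
    (self, same eye / orthogonal orientation, opposite eye / same
    orientation, opposite eye / orthogonal orientation); ``w_sum_same`` and
    ``w_sum_orth`` populate the summation-layer pool; ``w_ff`` scales the
    feedforward drive from monocular to summation neurons.  The opponency
    model fixes all weights at 1.
    """

    w_mono_self: float = 1.0
    w_mono_same_eye_orth: float = 1.0
    w_mono_opp_eye_same: float = 1.0
    w_mono_opp_eye_orth: float = 1.0
    w_sum_same: float = 1.0
    w_sum_orth: float = 1.0
    w_ff: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"weights.{f.name} must be >= 0, got {v}")


#: Order of the free grid-search parameters (weights, then noise amplitude).
WEIGHT_FIELDS = (
    "w_mono_self",
    "w_mono_same_eye_orth",
    "w_mono_opp_eye_same",
    "w_mono_opp_eye_orth",
    "w_sum_same",
    "w_sum_orth",
    "w_ff",
)


@dataclass(frozen=True)
class ModelParams:
    """All constants of the rivalry/normalization models.

    Parameters
    ----------
    sigma : float
        Semisaturation constant for monocular and summation neurons (0.5).
    sigma_opp : float
        Semisaturation constant for opponency neurons (0.9).
    tau_ms : float
        Firing-rate time constant, ms (50).
    tau_adapt_s : float
        Long-term adaptation time constant, seconds (80).
    adapt_scale : float
        Factor multiplying the adaptation variable before it is subtracted
        from the unnormalized drive (0.5).
    adapt_enabled : bool
        Whether the long-term adaptation variables are integrated and
        subtracted from the drives.  Off by default (the five-condition
        simulations); on for the adaptation experiment.
    noise : NoiseParams
    weights : Weights
    noise_on_opponency : bool
        Add noise to opponency-neuron drives as well (default True).
    noise_on_summation : bool
        Add noise directly to summation-neuron drives.  Off by default:
        summation neurons already inherit noise through their monocular
        inputs, and direct summation noise washes out the dichoptic/plaid
        rivalry contrast the models are built to expose (see the methods
        note).  The flag exists for sensitivity checks.
    sigma_exponent : int
        Power of sigma in the normalization denominator.  2 is the standard
        normalization-model convention; 1 exists for sensitivity checks.
    """

    sigma: float = 0.5
    sigma_opp: float = 0.9
    tau_ms: float = 50.0
    tau_adapt_s: float = 80.0
    adapt_scale: float = 0.5
    adapt_enabled: bool = False
    noise: NoiseParams = field(default_factory=NoiseParams)
    weights: Weights = field(default_factory=Weights)
    noise_on_opponency: bool = True
    noise_on_summation: bool = False
    sigma_exponent: int = 2

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.sigma_opp <= 0:
            raise ValueError(f"sigma_opp must be > 0, got {self.sigma_opp}")
        if self.tau_ms <= 0:
            raise ValueError(f"tau_ms must be > 0, got {self.tau_ms}")
        if self.tau_adapt_s <= 0:
            raise ValueError(f"tau_adapt_s must be > 0, got {self.tau_adapt_s}")
        if self.adapt_scale < 0:
            raise ValueError(f"adapt_scale must be >= 0, got {self.adapt_scale}")
        if self.sigma_exponent not in (1, 2):
            raise ValueError(
                f"sigma_exponent must be 1 or 2, got {self.sigma_exponent}"
            )


def mono_weight_matrix(weights: Weights) -> np.ndarray:
    """4x4 normalization-pool weight matrix for the monocular layer.

    Row i, column j is the weight on neuron j's half-squared drive in the
    denominator of neuron i.  Neuron order: LA, LB, RA, RB.
    """
    s = weights.w_mono_self
    seo = weights.w_mono_same_eye_orth
    oes = weights.w_mono_opp_eye_same
    oeo = weights.w_mono_opp_eye_orth
    return np.array(
        [
            [s, seo, oes, oeo],
            [seo, s, oeo, oes],
            [oes, oeo, s, seo],
            [oeo, oes, seo, s],
        ]
    )


def sum_weight_matrix(weights: Weights) -> np.ndarray:
    """2x2 normalization-pool weight matrix for the summation layer."""
    return np.array(
        [
            [weights.w_sum_same, weights.w_sum_orth],
            [weights.w_sum_orth, weights.w_sum_same],
        ]
    )


def params_to_dict(params: ModelParams) -> dict[str, Any]:
    """Flatten a ModelParams into a JSON-serializable nested dict."""
    return asdict(params)


def params_from_dict(d: dict[str, Any]) -> ModelParams:
    """Inverse of :func:`params_to_dict`."""
    d = dict(d)
    noise = NoiseParams(**d.pop("noise", {}))
    weights = Weights(**d.pop("weights", {}))
    return ModelParams(noise=noise, weights=weights, **d)


def with_seed(params: ModelParams, seed: int) -> ModelParams:
    """Return a copy of ``params`` with the noise seed replaced."""
    return replace(params, noise=replace(params.noise, seed=int(seed)))
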