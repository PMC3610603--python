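"""Lowpass-filtered Gaussian noise for the neural inputs.

Each neuron receives an independent realization: Gaussian white noise
convolved in time with a Gaussian kernel (SD ``smoothness_ms``), then
rescaled so the stationary SD of the filtered process equals ``amplitude``.
The rescaling makes the noise magnitude independent of the integration
step, so 2 ms and 10 ms simulations see statistically identical noise.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .params import NoiseParams

#: Kernel truncation, in SDs of the Gaussian temporal filter.
KERNEL_TRUNCATE = 4.0


def gaussian_kernel(smoothness_ms: float, dt_ms: float) -> np.ndarray:
    """Unit-sum discretized Gaussian kernel, truncated at +/- 4 SD."""
    sd_steps = smoothness_ms / dt_ms
    half = int(np.ceil(KERNEL_TRUNCATE * sd_steps))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sd_steps) ** 2)
    return k / k.sum()


def _streams(seed: int, n_channels: int) -> list[np.random.SeedSequence]:
    # Spawn order depends only on the channel index, so adding channels
    # never reshuffles earlier ones.
    return np.random.SeedSequence(seed).spawn(n_channels)


def filtered_unit_noise(
    n_steps: int,
    dt_ms: float,
    smoothness_ms: float,
    streams: Sequence[np.random.SeedSequence],
) -> np.ndarray:
    """Filtered noise with unit stationary SD, one row per stream.

    White Gaussian steps are drawn with pre-roll padding of one kernel
    length, so the returned process is stationary from step 0, then
    convolved ('valid') with the unit-sum Gaussian kernel and rescaled by
    the kernel's theoretical SD gain sqrt(sum k^2).
    """
    kernel = gaussian_kernel(smoothness_ms, dt_ms)
    pad = len(kernel) - 1
    white = np.empty((len(streams), n_steps + pad))
    for i, ss in enumerate(streams):
        white[i] = np.random.default_rng(ss).standard_normal(n_steps + pad)
    filt = fftconvolve(white, kernel[None, :], mode="valid", axes=1)
    return filt / np.sqrt(np.sum(kernel**2))


def generate(
    n_steps: int,
    dt_ms: float,
    n_channels: int,
    params: NoiseParams,
    streams: Sequence[np.random.SeedSequence] | None = None,
) -> np.ndarray:
    """Noise matrix of shape (n_channels, n_steps).

    Channels are mutually independent sub-streams of ``params.seed``
    (or of ``streams`` when given explicitly).  Each channel's stationary
    SD equals ``params.amplitude``; ``amplitude == 0`` returns zeros.
    """
    if n_steps <= 0:
        raise ValueError(f"n_steps must be > 0, got {n_steps}")
    if dt_ms <= 0:
        raise ValueError(f"dt_ms must be > 0, got {dt_ms}")
    if n_channels <= 0:
        raise ValueError(f"n_channels must be > 0, got {n_channels}")
    if params.amplitude == 0:
        return np.zeros((n_channels, n_steps))
    if streams is None:
        streams = _streams(params.seed, n_channels)
    elif len(streams) != n_channels:
        raise ValueError("len(streams) must equal n_channels")
    unit = filtered_unit_noise(n_steps, dt_ms, params.smoothness_ms, streams)
    return unit * params.amplitude
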