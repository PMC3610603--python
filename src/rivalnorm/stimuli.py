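"""Time-varying contrast inputs for the five canonical conditions and adaptors.

A stimulus is a piecewise-constant function of time returning a 4-vector of
contrasts ordered (left-eye orientation A, left-eye orientation B, right-eye
orientation A, right-eye orientation B).  Orientation A is CCW-of-vertical,
B is CW-of-vertical; the dichoptic condition shows A to the left eye and B
to the right eye.  The models are symmetric under eye/orientation exchange,
so these conventions only fix trace labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

CONDITIONS = (
    "dichoptic_gratings",
    "monocular_plaid",
    "binocular_plaid",
    "monocular_grating",
    "binocular_grating",
)

ADAPTOR_MODES = ("binocular", "monocular")


class UnknownConditionError(ValueError):
    """Raised for a condition or adaptor-mode name outside the battery."""


# Channel patterns (LA, LB, RA, RB) at unit contrast.  Monocular conditions
# stimulate the left eye by default; `eye="right"` flips them.
_PATTERNS = {
    "dichoptic_gratings": {"left": (1, 0, 0, 1), "right": (0, 1, 1, 0)},
    "monocular_plaid": {"left": (1, 1, 0, 0), "right": (0, 0, 1, 1)},
    "binocular_plaid": {"left": (1, 1, 1, 1), "right": (1, 1, 1, 1)},
    "monocular_grating": {"left": (1, 0, 0, 0), "right": (0, 0, 1, 0)},
    "binocular_grating": {"left": (1, 0, 1, 0), "right": (1, 0, 1, 0)},
}


@dataclass(frozen=True)
class StimulusSpec:
    """A stimulus: duration plus a vectorized contrast function.

    ``contrast_fn`` maps an array of times (seconds) to an ``(n, 4)`` array
    of contrasts in [0, 1], piecewise-constant in time.
    """

    duration_s: float
    contrast_fn: Callable[[np.ndarray], np.ndarray]
    label: str

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Contrast at each time in ``t`` (seconds) as an (len(t), 4) array."""
        c = self.contrast_fn(np.atleast_1d(np.asarray(t, dtype=float)))
        return np.asarray(c, dtype=float)


def _check_contrast(contrast: float) -> float:
    c = float(contrast)
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"contrast must be in [0, 1], got {contrast}")
    return c


def make_condition(
    name: str, contrast: float, duration_s: float, eye: str = "left"
) -> StimulusSpec:
    """Constant-contrast stimulus for one of the five canonical conditions.

    ``eye`` selects which eye the monocular conditions stimulate (and which
    eye carries orientation A in the dichoptic condition).
    """
    if name not in _PATTERNS:
        raise UnknownConditionError(
            f"unknown condition {name!r}; expected one of {CONDITIONS}"
        )
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
    c = _check_contrast(contrast)
    pattern = np.array(_PATTERNS[name][eye], dtype=float) * c

    def fn(t: np.ndarray, pattern: np.ndarray = pattern) -> np.ndarray:
        return np.broadcast_to(pattern, (len(t), 4)).copy()

    return StimulusSpec(float(duration_s), fn, label=name)


def make_adaptor(
    mode: str,
    alternation_hz: float,
    contrast: float,
    duration_s: float,
    cycle_convention: str = "full",
) -> StimulusSpec:
    """Orientation-alternating adaptor stimulus.

    The grating reverses orientation as a square wave with 50% duty cycle,
    first half-cycle showing orientation A.  ``binocular`` shows the same
    grating to both eyes, (c,0,c,0) <-> (0,c,0,c).  ``monocular`` shows one
    eye at a time, orientation A only ever in the left eye and B only in
    the right, (c,0,0,0) <-> (0,0,0,c).

    ``alternation_hz`` is read as the full A->B->A cycle rate by default
    (half-period = 1/(2 hz)); ``cycle_convention="half"`` reads it as the
    orientation-transition rate instead (half-period = 1/hz).
    """
    if mode not in ADAPTOR_MODES:
        raise UnknownConditionError(
            f"unknown adaptor mode {mode!r}; expected one of {ADAPTOR_MODES}"
        )
    if alternation_hz <= 0:
        raise ValueError(f"alternation_hz must be > 0, got {alternation_hz}")
    if cycle_convention not in ("full", "half"):
        raise ValueError(f"cycle_convention must be 'full' or 'half'")
    c = _check_contrast(contrast)
    half_period = (
        1.0 / (2.0 * alternation_hz) if cycle_convention == "full" else 1.0 / alternation_hz
    )
    if mode == "binocular":
        pat_a = np.array([1, 0, 1, 0], dtype=float) * c
        pat_b = np.array([0, 1, 0, 1], dtype=float) * c
    else:
        pat_a = np.array([1, 0, 0, 0], dtype=float) * c
        pat_b = np.array([0, 0, 0, 1], dtype=float) * c

    def fn(t: np.ndarray) -> np.ndarray:
        phase_a = (np.floor(t / half_period).astype(np.int64) % 2) == 0
        return np.where(phase_a[:, None], pat_a, pat_b)

    return StimulusSpec(float(duration_s), fn, label=f"adaptor_{mode}")


def concat(specs: list[StimulusSpec]) -> StimulusSpec:
    """Concatenate stimuli in time; durations add.

    Each component's contrast function is evaluated on its own clock
    (shifted so its block starts at 0).  Times at or past the total
    duration fall in the last block.
    """
    if not specs:
        raise ValueError("concat requires a non-empty list of stimuli")
    if len(specs) == 1:
        return specs[0]
    durations = np.array([s.duration_s for s in specs])
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    total = float(edges[-1])

    def fn(t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(edges, t, side="right") - 1
        idx = np.clip(idx, 0, len(specs) - 1)
        out = np.empty((len(t), 4), dtype=float)
        for i, spec in enumerate(specs):
            mask = idx == i
            if mask.any():
                out[mask] = spec.sample(t[mask] - edges[i])
        return out

    label = "+".join(s.label for s in specs)
    return StimulusSpec(total, fn, label=label)


#: Channel permutation that swaps eyes (L<->R) and orientations (A<->B)
#: simultaneously: (LA, LB, RA, RB) -> (RB, RA, LB, LA).
EYE_ORIENTATION_SWAP = np.array([3, 2, 1, 0])


def permute_channels(spec: StimulusSpec, perm: np.ndarray) -> StimulusSpec:
    """Relabel input channels: channel i of the result is channel perm[i]."""
    perm = np.asarray(perm)

    def fn(t: np.ndarray) -> np.ndarray:
        return spec.sample(t)[:, perm]

    return StimulusSpec(spec.duration_s, fn, label=f"{spec.label}_permuted")
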