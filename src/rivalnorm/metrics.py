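"""Rivalry metrics computed from summation-neuron traces.

The percept index P(t) = |rA - rB| / (rA + rB) measures the instantaneous
dominance of one orientation over the other: 0 means a fully mixed percept
(equal responses), 1 complete dominance.  The winner-take-all (WTA) index
is its time average over the simulation window.  The mixed-percept fraction
is the fraction of time P(t) falls below a cutoff (default 0.4).

All functions broadcast over leading axes, so a batch of trace pairs can be
scored in one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricConfig",
    "percept_index",
    "wta_index",
    "mixed_fraction",
    "count_switches",
    "dominance_fractions",
    "eye_imbalance",
]


@dataclass(frozen=True)
class MetricConfig:
    """Tunables shared by the rivalry metrics.

    ``zero_denominator_policy`` decides what a 0/0 sample (both rates zero)
    contributes: "as_zero" scores it as maximally mixed (P = 0), "drop"
    excludes it (NaN, ignored by the averages).  ``switch_epsilon`` is the
    hysteresis half-width of the dominance-switch counter.
    """

    mixed_cutoff: float = 0.4
    zero_denominator_policy: str = "as_zero"
    switch_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mixed_cutoff < 1.0:
            raise ValueError(f"mixed_cutoff must be in (0, 1), got {self.mixed_cutoff}")
        if self.zero_denominator_policy not in ("as_zero", "drop"):
            raise ValueError(
                "zero_denominator_policy must be 'as_zero' or 'drop', "
                f"got {self.zero_denominator_policy!r}"
            )
        if self.switch_epsilon < 0:
            raise ValueError("switch_epsilon must be >= 0")


_DEFAULT = MetricConfig()


def percept_index(
    rA: np.ndarray, rB: np.ndarray, cfg: MetricConfig = _DEFAULT
) -> np.ndarray:
    """Pointwise percept index P(t) = |rA - rB| / (rA + rB), in [0, 1]."""
    rA = np.asarray(rA, dtype=float)
    rB = np.asarray(rB, dtype=float)
    if rA.shape != rB.shape:
        raise ValueError(f"trace shapes differ: {rA.shape} vs {rB.shape}")
    den = rA + rB
    zero = den == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.abs(rA - rB) / den
    fill = 0.0 if cfg.zero_denominator_policy == "as_zero" else np.nan
    return np.where(zero, fill, p)


def wta_index(rA: np.ndarray, rB: np.ndarray, cfg: MetricConfig = _DEFAULT) -> float:
    """Winner-take-all index: time average of the percept index.

    0 means the two summation neurons always responded identically; 1 means
    complete rivalry (only one neuron active at any time).  Averages over
    the last axis; leading axes are preserved (batched traces).
    """
    p = percept_index(rA, rB, cfg)
    if p.shape[-1] < 1:
        raise ValueError("traces must contain at least one sample")
    if cfg.zero_denominator_policy == "drop":
        with np.errstate(invalid="ignore"):
            out = np.nan_to_num(np.nanmean(p, axis=-1), nan=0.0)
    else:
        out = np.mean(p, axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def mixed_fraction(P: np.ndarray, cfg: MetricConfig = _DEFAULT) -> float:
    """Fraction of samples whose percept index is below the mixed cutoff.

    NaN samples (dropped 0/0 points) are excluded from the denominator.
    Averages over the last axis.
    """
    P = np.asarray(P, dtype=float)
    valid = ~np.isnan(P)
    n_valid = valid.sum(axis=-1)
    mixed = np.where(valid, P < cfg.mixed_cutoff, False).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_valid > 0, mixed / np.maximum(n_valid, 1), 0.0)
    return float(frac) if np.ndim(frac) == 0 else frac


def count_switches(
    r_presented: np.ndarray, r_orth: np.ndarray, cfg: MetricConfig = _DEFAULT
) -> int:
    """Dominance switches: hysteresis crossings of d = r_presented - r_orth.

    A switch is counted each time d, having exceeded +epsilon, subsequently
    falls below -epsilon, or vice versa.  With epsilon = 0 this is a strict
    sign-change count (exact zeros never trigger).
    """
    r_presented = np.asarray(r_presented, dtype=float)
    r_orth = np.asarray(r_orth, dtype=float)
    if r_presented.shape != r_orth.shape:
        raise ValueError(
            f"trace shapes differ: {r_presented.shape} vs {r_orth.shape}"
        )
    d = r_presented - r_orth
    s = np.where(d > cfg.switch_epsilon, 1, np.where(d < -cfg.switch_epsilon, -1, 0))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def dominance_fractions(
    rA: np.ndarray, rB: np.ndarray, cfg: MetricConfig = _DEFAULT
) -> tuple[float, float]:
    """Fractions of time each orientation delivered the dominant percept.

    A sample counts as dominant for orientation A when P(t) >= mixed_cutoff
    and rA > rB (and symmetrically for B).  Fractions are over all samples,
    so they need not sum to 1 (the remainder is mixed perception).
    """
    p = percept_index(rA, rB, cfg)
    dominant = p >= cfg.mixed_cutoff
    n = p.shape[-1]
    frac_a = float(np.sum(dominant & (np.asarray(rA) > np.asarray(rB))) / n)
    frac_b = float(np.sum(dominant & (np.asarray(rB) > np.asarray(rA))) / n)
    return frac_a, frac_b


def eye_imbalance(dominance_a_fraction: float, dominance_b_fraction: float) -> float:
    """Absolute difference between the two eyes' dominance fractions.

    Under the dichoptic convention orientation A is the left eye's stimulus
    and B the right eye's, so the two dominance fractions are per-eye.
    """
    for v in (dominance_a_fraction, dominance_b_fraction):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"dominance fractions must be in [0, 1], got {v}")
    return abs(float(dominance_a_fraction) - float(dominance_b_fraction))
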