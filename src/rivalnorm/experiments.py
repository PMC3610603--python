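"""Scripted simulation experiments.

Three protocols: the five-condition battery (WTA index of the summation
neurons per canonical stimulus), the monocular-grating stability check
(dominance switch counts), and the adaptation experiment (mixed-percept
fractions after monocular vs. binocular orientation-alternating adaptors,
the protocol that separates the two models' predictions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import noise as noise_mod
from ._engine import integrate, n_noise_channels
from .metrics import (
    MetricConfig,
    count_switches,
    mixed_fraction,
    percept_index,
    wta_index,
)
from .params import (
    MODELS,
    ModelParams,
    mono_weight_matrix,
    params_to_dict,
    sum_weight_matrix,
)
from .stimuli import StimulusSpec, concat, make_adaptor, make_condition

__all__ = [
    "ExperimentSummary",
    "five_condition_battery",
    "switch_stability",
    "adaptation_experiment",
]

BATTERY_CONDITIONS = (
    "dichoptic_gratings",
    "monocular_plaid",
    "binocular_plaid",
    "monocular_grating",
    "binocular_grating",
)


@dataclass
class ExperimentSummary:
    """Replicate-level results of one experiment.

    ``replicates`` maps a condition label to the per-replicate statistic
    values; means and SDs are recomputed from them on demand.  ``provenance``
    records everything needed to regenerate the numbers (model, params,
    dt, seed scheme, durations).
    """

    model: str
    statistic: str
    replicates: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def mean(self, condition: str) -> float:
        return float(np.mean(self.replicates[condition]))

    def sd(self, condition: str) -> float:
        return float(np.std(self.replicates[condition], ddof=1))

    def n(self, condition: str) -> int:
        return len(self.replicates[condition])


def _rep_streams(seed: int, rep: int, tag: int, n_channels: int):
    return np.random.SeedSequence([int(seed), int(rep), int(tag)]).spawn(n_channels)


def _run_batch(
    model: str,
    stimulus: StimulusSpec,
    params: ModelParams,
    dt_ms: float,
    seed: int,
    reps: Sequence[int],
    tag: int,
    record: tuple[str, ...],
    record_from: int = 0,
) -> dict[str, np.ndarray]:
    """Integrate a batch of replicates (same stimulus, independent noise)."""
    n_steps = int(round(stimulus.duration_s * 1000.0 / dt_ms))
    contrasts = stimulus.sample(np.arange(n_steps) * (dt_ms / 1000.0))
    n_ch = n_noise_channels(model)
    if params.noise.amplitude == 0:
        noise = np.zeros((len(reps), n_ch, n_steps))
    else:
        streams = []
        for rep in reps:
            streams.extend(_rep_streams(seed, rep, tag, n_ch))
        unit = noise_mod.filtered_unit_noise(
            n_steps, dt_ms, params.noise.smoothness_ms, streams
        )
        noise = unit.reshape(len(reps), n_ch, n_steps) * params.noise.amplitude
    return integrate(
        model,
        contrasts,
        noise,
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
        record=record,
        record_from=record_from,
    )


def five_condition_battery(
    model: str,
    params: ModelParams,
    duration_s: float = 160.0,
    dt_ms: float = 2.0,
    n_reps: int = 10,
    seed: int = 0,
    contrast: float = 0.5,
    cfg: MetricConfig = MetricConfig(),
) -> ExperimentSummary:
    """WTA index per canonical condition, replicated over noise seeds.

    160 s of model time per replicate gives a reliable WTA estimate.
    Replicate r of condition i uses noise streams derived from
    (seed, r, i), independent across both axes.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    reps = list(range(n_reps))
    replicates: dict[str, np.ndarray] = {}
    for cond_id, condition in enumerate(BATTERY_CONDITIONS):
        stim = make_condition(condition, contrast, duration_s)
        out = _run_batch(
            model, stim, params, dt_ms, seed, reps, cond_id, record=("sum",)
        )
        replicates[condition] = np.asarray(
            wta_index(out["sum"][:, :, 0], out["sum"][:, :, 1], cfg)
        )
    return ExperimentSummary(
        model=model,
        statistic="wta_index",
        replicates=replicates,
        provenance={
            "params": params_to_dict(params),
            "duration_s": duration_s,
            "dt_ms": dt_ms,
            "n_reps": n_reps,
            "seed": seed,
            "contrast": contrast,
            "seed_scheme": "SeedSequence([seed, replicate, condition_id])",
        },
    )


def switch_stability(
    model: str,
    params: ModelParams,
    duration_s: float = 160.0,
    dt_ms: float = 2.0,
    n_reps: int = 10,
    seed: int = 0,
    contrast: float = 0.5,
    cfg: MetricConfig = MetricConfig(),
) -> np.ndarray:
    """Dominance switch counts for a monocular grating, one per replicate.

    The presented orientation is A (left-eye convention); a switch means
    the summation neuron tuned to the non-presented orthogonal orientation
    transiently out-responded the presented one — implausible behavior for
    a model of normal vision.
    """
    stim = make_condition("monocular_grating", contrast, duration_s)
    out = _run_batch(
        model, stim, params, dt_ms, seed, list(range(n_reps)),
        tag=len(BATTERY_CONDITIONS), record=("sum",),
    )
    return np.array(
        [
            count_switches(out["sum"][r, :, 0], out["sum"][r, :, 1], cfg)
            for r in range(n_reps)
        ]
    )


def adaptation_experiment(
    model: str,
    params: ModelParams | None = None,
    n_blocks: int = 100,
    adapt_duration_s: float = 100.0,
    rivalry_duration_s: float = 80.0,
    adaptor_contrast: float = 1.0,
    rivalry_contrast: float = 0.5,
    alternation_hz: float = 0.94,
    dt_ms: float = 10.0,
    seed: int = 0,
    cutoffs: Sequence[float] = (0.4,),
    cfg: MetricConfig = MetricConfig(),
    carry_state: bool = False,
    chunk_size: int = 50,
) -> ExperimentSummary:
    """Mixed-percept fractions after monocular vs. binocular adaptation.

    Each block presents 100 s of 100%-contrast orientation-alternating
    adaptor, then 80 s of dichoptic rivalry at 50% contrast; long-term
    adaptation (tau_a = 80 s, scale 0.5) accumulates throughout.  The
    percept index is computed over the rivalry window only, and the mixed
    fraction is the time below each cutoff, averaged across blocks.

    Blocks are independent replicates by default; ``carry_state=True``
    chains them (state carries over within a condition) for sensitivity
    analysis.  Replicate keys are ``{mode}`` for the first cutoff and
    ``{mode}_cutoff{c}`` for the others.
    """
    if params is None:
        params = ModelParams(adapt_enabled=True)
    if not params.adapt_enabled:
        raise ValueError(
            "adaptation_experiment requires params.adapt_enabled=True"
        )
    replicates: dict[str, np.ndarray] = {}
    n_rivalry_steps = int(round(rivalry_duration_s * 1000.0 / dt_ms))
    for mode_id, mode in enumerate(("monocular", "binocular")):
        stim = concat(
            [
                make_adaptor(mode, alternation_hz, adaptor_contrast, adapt_duration_s),
                make_condition("dichoptic_gratings", rivalry_contrast, rivalry_duration_s),
            ]
        )
        n_steps = int(round(stim.duration_s * 1000.0 / dt_ms))
        record_from = n_steps - n_rivalry_steps
        fractions = {c: [] for c in cutoffs}
        if carry_state:
            state = None
            for block in range(n_blocks):
                out = _chained(model, stim, params, dt_ms, seed, block,
                               mode_id, record_from, state)
                state = {
                    k: out[k]
                    for k in ("r_mono", "r_sum", "r_opp", "a_mono", "a_sum", "a_opp")
                }
                p = percept_index(out["sum"][0, :, 0], out["sum"][0, :, 1], cfg)
                for c in cutoffs:
                    fractions[c].append(
                        mixed_fraction(p, replace(cfg, mixed_cutoff=c))
                    )
        else:
            for start in range(0, n_blocks, chunk_size):
                blocks = list(range(start, min(start + chunk_size, n_blocks)))
                out = _run_batch(
                    model, stim, params, dt_ms, seed, blocks,
                    tag=100 + mode_id, record=("sum",), record_from=record_from,
                )
                p = percept_index(out["sum"][:, :, 0], out["sum"][:, :, 1], cfg)
                for c in cutoffs:
                    fractions[c].extend(
                        np.atleast_1d(mixed_fraction(p, replace(cfg, mixed_cutoff=c)))
                    )
        for i, c in enumerate(cutoffs):
            key = mode if i == 0 else f"{mode}_cutoff{c:g}"
            replicates[key] = np.asarray(fractions[c])
    return ExperimentSummary(
        model=model,
        statistic="mixed_fraction",
        replicates=replicates,
        provenance={
            "params": params_to_dict(params),
            "n_blocks": n_blocks,
            "adapt_duration_s": adapt_duration_s,
            "rivalry_duration_s": rivalry_duration_s,
            "adaptor_contrast": adaptor_contrast,
            "rivalry_contrast": rivalry_contrast,
            "alternation_hz": alternation_hz,
            "dt_ms": dt_ms,
            "seed": seed,
            "cutoffs": list(cutoffs),
            "carry_state": carry_state,
            "seed_scheme": "SeedSequence([seed, block, 100 + mode_id])",
        },
    )


def _chained(
    model, stim, params, dt_ms, seed, block, mode_id, record_from, state
):
    """One chained block for carry_state mode (state from previous block)."""
    n_steps = int(round(stim.duration_s * 1000.0 / dt_ms))
    contrasts = stim.sample(np.arange(n_steps) * (dt_ms / 1000.0))
    n_ch = n_noise_channels(model)
    streams = _rep_streams(seed, block, 100 + mode_id, n_ch)
    if params.noise.amplitude == 0:
        noise = np.zeros((1, n_ch, n_steps))
    else:
        unit = noise_mod.filtered_unit_noise(
            n_steps, dt_ms, params.noise.smoothness_ms, streams
        )
        noise = unit[None, :, :] * params.noise.amplitude
    return integrate(
        model,
        contrasts,
        noise,
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
        record=("sum",),
        record_from=record_from,
        init_state=state,
    )
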