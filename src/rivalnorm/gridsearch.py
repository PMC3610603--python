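"""Exhaustive grid search over conventional-model parameterizations.

The search asks whether any combination of normalization weights and noise
amplitude lets the conventional model rival strongly for dichoptic gratings
while rivaling only weakly for plaids.  Each parameterization is scored on
three conditions (dichoptic gratings, monocular plaid, binocular plaid) by
the WTA index of the summation neurons and accepted when

    WTA(dichoptic) > wta_min   and
    WTA(dichoptic) >= ratio_min * WTA(each plaid).

Because the noise is regenerated independently per condition, a short
first round (40 s) admits some combinations by chance; survivors are
re-tested at 400 s with fresh noise.  Two-round survivors are then checked
for plausibility on a monocular grating: a parameterization whose summation
responses switch dominance two or more times (i.e. the model "perceives"
the orthogonal, non-presented orientation) is rejected.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from . import noise as noise_mod
from ._engine import integrate, n_noise_channels
from .metrics import MetricConfig, count_switches, wta_index
from .params import (
    WEIGHT_FIELDS,
    ModelParams,
    NoiseParams,
    Weights,
    mono_weight_matrix,
    params_to_dict,
    sum_weight_matrix,
)
from .stimuli import make_condition

__all__ = [
    "GridSpec",
    "ComboResult",
    "ParamGrid",
    "enumerate_grid",
    "combo_streams",
    "evaluate_combo",
    "apply_criteria",
    "run_search",
    "CheckpointError",
]

#: Grid-search condition order and integer ids used in seed derivation.
CONDITIONS = (
    "dichoptic_gratings",
    "monocular_plaid",
    "binocular_plaid",
    "monocular_grating",
)

_DEFAULT_WEIGHT_VALUES = (0.4, 0.8, 1.2, 1.6, 2.0)
_DEFAULT_NOISE_VALUES = (0.01, 0.03, 0.05, 0.09, 0.13)


class CheckpointError(RuntimeError):
    """Unreadable or inconsistent checkpoint data."""


@dataclass(frozen=True)
class GridSpec:
    """Grid-search configuration (defaults reproduce the published search).

    ``weight_values`` maps each of the seven weight names to its candidate
    list; together with ``noise_amplitudes`` they define a Cartesian product
    of 5^8 = 390,625 combinations at the defaults.  sigma, noise smoothness
    and tau are fixed, not searched.
    """

    weight_values: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {w: _DEFAULT_WEIGHT_VALUES for w in WEIGHT_FIELDS}
    )
    noise_amplitudes: tuple[float, ...] = _DEFAULT_NOISE_VALUES
    sigma: float = 0.5
    smoothness_ms: float = 800.0
    tau_ms: float = 50.0
    contrast: float = 0.5
    pass1_duration_s: float = 40.0
    pass2_duration_s: float = 400.0
    dt_ms: float = 10.0
    wta_min: float = 0.4
    ratio_min: float = 1.6
    switch_reject_min: int = 2
    base_seed: int = 0

    def __post_init__(self) -> None:
        missing = [w for w in WEIGHT_FIELDS if w not in self.weight_values]
        if missing:
            raise ValueError(f"weight_values missing entries for {missing}")
        for name, values in self.weight_values.items():
            if len(values) == 0:
                raise ValueError(f"empty candidate list for {name}")
        if len(self.noise_amplitudes) == 0:
            raise ValueError("empty candidate list for noise_amplitudes")
        if self.pass1_duration_s <= 0 or self.pass2_duration_s <= 0:
            raise ValueError("durations must be > 0")

    @property
    def value_lists(self) -> list[tuple[float, ...]]:
        """Candidate lists in canonical order (7 weights, then noise)."""
        return [tuple(self.weight_values[w]) for w in WEIGHT_FIELDS] + [
            tuple(self.noise_amplitudes)
        ]

    def subgrid(self, n_values: int) -> "GridSpec":
        """Spec with ``n_values`` evenly spaced candidates per parameter."""
        from dataclasses import replace

        def thin(values: tuple[float, ...]) -> tuple[float, ...]:
            if n_values >= len(values):
                return values
            idx = np.round(np.linspace(0, len(values) - 1, n_values)).astype(int)
            return tuple(values[i] for i in idx)

        return replace(
            self,
            weight_values={w: thin(v) for w, v in self.weight_values.items()},
            noise_amplitudes=thin(self.noise_amplitudes),
        )


@dataclass
class ComboResult:
    """Per-parameterization grid-search metrics."""

    params: ModelParams
    wta_dichoptic: float = np.nan
    wta_mono_plaid: float = np.nan
    wta_bino_plaid: float = np.nan
    switch_count_mono_grating: int | None = None
    passed_round1: bool | None = None
    passed_round2: bool | None = None
    plausible: bool | None = None
    failed: bool = False


class ParamGrid(Sequence):
    """Lazy ordered sequence of the grid's ModelParams.

    Combinations are the Cartesian product of the candidate lists in
    canonical parameter order (the seven weights, then noise amplitude),
    lexicographic with the last parameter varying fastest.
    """

    def __init__(self, spec: GridSpec):
        self.spec = spec
        self._lists = spec.value_lists
        self._sizes = [len(v) for v in self._lists]
        self._len = math.prod(self._sizes)

    def __len__(self) -> int:
        return self._len

    def values_at(self, index: int) -> tuple[float, ...]:
        """Raw (w1..w7, noise_amplitude) tuple at a grid index."""
        if not 0 <= index < self._len:
            raise IndexError(index)
        out = []
        rem = index
        for size, values in zip(
            reversed(self._sizes), reversed(self._lists)
        ):
            rem, i = divmod(rem, size)
            out.append(values[i])
        return tuple(reversed(out))

    def iter_values(self) -> Iterator[tuple[float, ...]]:
        """Iterate raw value tuples (cheap; no ModelParams construction)."""
        return itertools.product(*self._lists)

    def params_at(self, index: int) -> ModelParams:
        return self._make(self.values_at(index))

    def _make(self, values: tuple[float, ...]) -> ModelParams:
        weights = Weights(**dict(zip(WEIGHT_FIELDS, values[:7])))
        return ModelParams(
            sigma=self.spec.sigma,
            tau_ms=self.spec.tau_ms,
            noise=NoiseParams(
                amplitude=values[7], smoothness_ms=self.spec.smoothness_ms
            ),
            weights=weights,
        )

    def __getitem__(self, index: int) -> ModelParams:
        return self.params_at(index)

    def __iter__(self) -> Iterator[ModelParams]:
        for values in self.iter_values():
            yield self._make(values)


def enumerate_grid(spec: GridSpec) -> ParamGrid:
    """All grid parameterizations in documented lexicographic order."""
    return ParamGrid(spec)


def combo_streams(
    base_seed: int,
    combo_index: int,
    condition_id: int,
    round_id: int,
    n_channels: int,
) -> list[np.random.SeedSequence]:
    """Per-neuron noise streams for one (combo, condition, round) simulation.

    Derived from the tuple itself, so results are independent of evaluation
    order and parallelism.
    """
    root = np.random.SeedSequence(
        [int(base_seed), int(combo_index), int(condition_id), int(round_id)]
    )
    return root.spawn(n_channels)


def _simulate_wta_batch(
    spec: GridSpec,
    combo_indices: np.ndarray,
    values: np.ndarray,
    condition: str,
    round_id: int,
    duration_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """WTA index and blow-up flags for a batch of parameterizations."""
    B = len(combo_indices)
    dt = spec.dt_ms
    n_steps = int(round(duration_s * 1000.0 / dt))
    stim = make_condition(condition, spec.contrast, duration_s)
    contrasts = stim.sample(np.arange(n_steps) * (dt / 1000.0))
    cond_id = CONDITIONS.index(condition)

    n_ch = n_noise_channels("conventional")
    streams: list[np.random.SeedSequence] = []
    for idx in combo_indices:
        streams.extend(combo_streams(spec.base_seed, idx, cond_id, round_id, n_ch))
    unit = noise_mod.filtered_unit_noise(n_steps, dt, spec.smoothness_ms, streams)
    noise = unit.reshape(B, n_ch, n_steps) * values[:, 7][:, None, None]

    W_mono = np.stack(
        [mono_weight_matrix(Weights(**dict(zip(WEIGHT_FIELDS, v[:7])))) for v in values]
    )
    W_sum = np.stack(
        [sum_weight_matrix(Weights(**dict(zip(WEIGHT_FIELDS, v[:7])))) for v in values]
    )
    out = integrate(
        "conventional",
        contrasts,
        noise,
        W_mono=W_mono,
        W_sum=W_sum,
        w_ff=values[:, 6],
        sigma=spec.sigma,
        sigma_opp=0.9,
        tau_ms=spec.tau_ms,
        dt_ms=dt,
        record=("sum",),
        on_blowup="mask",
    )
    wta = wta_index(out["sum"][:, :, 0], out["sum"][:, :, 1])
    return np.atleast_1d(np.asarray(wta)), out["blown"]


def _simulate_switches_batch(
    spec: GridSpec,
    combo_indices: np.ndarray,
    values: np.ndarray,
    round_id: int,
    duration_s: float,
    cfg: MetricConfig = MetricConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Monocular-grating dominance switch counts for a batch of combos."""
    B = len(combo_indices)
    dt = spec.dt_ms
    n_steps = int(round(duration_s * 1000.0 / dt))
    stim = make_condition("monocular_grating", spec.contrast, duration_s)
    contrasts = stim.sample(np.arange(n_steps) * (dt / 1000.0))
    cond_id = CONDITIONS.index("monocular_grating")

    n_ch = n_noise_channels("conventional")
    streams: list[np.random.SeedSequence] = []
    for idx in combo_indices:
        streams.extend(combo_streams(spec.base_seed, idx, cond_id, round_id, n_ch))
    unit = noise_mod.filtered_unit_noise(n_steps, dt, spec.smoothness_ms, streams)
    noise = unit.reshape(B, n_ch, n_steps) * values[:, 7][:, None, None]

    W_mono = np.stack(
        [mono_weight_matrix(Weights(**dict(zip(WEIGHT_FIELDS, v[:7])))) for v in values]
    )
    W_sum = np.stack(
        [sum_weight_matrix(Weights(**dict(zip(WEIGHT_FIELDS, v[:7])))) for v in values]
    )
    out = integrate(
        "conventional",
        contrasts,
        noise,
        W_mono=W_mono,
        W_sum=W_sum,
        w_ff=values[:, 6],
        sigma=spec.sigma,
        sigma_opp=0.9,
        tau_ms=spec.tau_ms,
        dt_ms=dt,
        record=("sum",),
        on_blowup="mask",
    )
    counts = np.array(
        [
            count_switches(out["sum"][b, :, 0], out["sum"][b, :, 1], cfg)
            for b in range(B)
        ]
    )
    return counts, out["blown"]


def evaluate_combo(
    params: ModelParams,
    duration_s: float,
    dt_ms: float,
    base_seed: int,
    combo_index: int = 0,
    round_id: int = 0,
    contrast: float = 0.5,
    cfg: MetricConfig = MetricConfig(),
) -> ComboResult:
    """Score one conventional-model parameterization on all four conditions.

    Each condition gets independently generated noise (its own derived
    stream).  A numerical blow-up is recorded as ``failed`` rather than
    raised.
    """
    from .dynamics import SimulationBlowupError, simulate

    result = ComboResult(params=params)
    n_ch = n_noise_channels("conventional")
    n_steps = int(round(duration_s * 1000.0 / dt_ms))
    for cond_id, condition in enumerate(CONDITIONS):
        stim = make_condition(condition, contrast, duration_s)
        streams = combo_streams(base_seed, combo_index, cond_id, round_id, n_ch)
        noise_matrix = noise_mod.generate(
            n_steps, dt_ms, n_ch, params.noise, streams=streams
        )
        try:
            sim = simulate(
                "conventional", stim, params, dt_ms=dt_ms, noise_matrix=noise_matrix
            )
        except SimulationBlowupError:
            result.failed = True
            return result
        r_sum = sim.r_sum
        if condition == "dichoptic_gratings":
            result.wta_dichoptic = wta_index(r_sum[:, 0], r_sum[:, 1], cfg)
        elif condition == "monocular_plaid":
            result.wta_mono_plaid = wta_index(r_sum[:, 0], r_sum[:, 1], cfg)
        elif condition == "binocular_plaid":
            result.wta_bino_plaid = wta_index(r_sum[:, 0], r_sum[:, 1], cfg)
        else:
            # Orientation A is the presented grating under the left-eye
            # convention; switches are counted on the summation responses.
            result.switch_count_mono_grating = count_switches(
                r_sum[:, 0], r_sum[:, 1], cfg
            )
    return result


def apply_criteria(result: ComboResult, spec: GridSpec) -> bool:
    """The two acceptance criteria on a populated ComboResult."""
    if result.failed:
        return False
    return bool(
        result.wta_dichoptic > spec.wta_min
        and result.wta_dichoptic >= spec.ratio_min * result.wta_mono_plaid
        and result.wta_dichoptic >= spec.ratio_min * result.wta_bino_plaid
    )


def _round1_chunk(
    spec: GridSpec, start: int, stop: int
) -> dict[str, np.ndarray]:
    grid = ParamGrid(spec)
    indices = np.arange(start, stop)
    values = np.array([grid.values_at(i) for i in indices])
    out: dict[str, np.ndarray] = {"indices": indices}
    blown = np.zeros(len(indices), dtype=bool)
    for key, condition in (
        ("wta_d", "dichoptic_gratings"),
        ("wta_mp", "monocular_plaid"),
        ("wta_bp", "binocular_plaid"),
    ):
        wta, b = _simulate_wta_batch(
            spec, indices, values, condition, round_id=0,
            duration_s=spec.pass1_duration_s,
        )
        out[key] = wta
        blown |= b
    out["blown"] = blown
    return out


_CHUNK_KEYS = ("indices", "wta_d", "wta_mp", "wta_bp", "blown")


def _load_chunk(path: str, start: int, stop: int) -> dict[str, np.ndarray] | None:
    if not os.path.exists(path):
        return None
    try:
        with np.load(path) as npz:
            data = {k: npz[k] for k in _CHUNK_KEYS}
    except Exception as exc:
        raise CheckpointError(
            f"unreadable checkpoint chunk {path!r}: {exc}; "
            "delete the checkpoint directory to restart the search"
        ) from exc
    if not np.array_equal(data["indices"], np.arange(start, stop)):
        raise CheckpointError(
            f"checkpoint chunk {path!r} covers different combo indices; "
            "it was written with another grid or chunk size — delete the "
            "checkpoint directory to restart"
        )
    return data


def run_search(
    spec: GridSpec,
    chunk_size: int = 256,
    checkpoint_dir: str | None = None,
    workers: int = 1,
    progress: bool = False,
) -> dict:
    """Run the full two-round grid search with plausibility rejection.

    Round 1 scores every combination on the three WTA conditions at
    ``pass1_duration_s``; combinations passing both criteria are re-scored
    at ``pass2_duration_s`` with fresh noise, and two-round survivors are
    rejected as implausible when their monocular-grating switch count
    reaches ``switch_reject_min``.

    With ``checkpoint_dir`` set, per-chunk round-1 results are saved as
    ``.npz`` files and reused on resume.  Results are reproducible from
    ``spec.base_seed`` and independent of ``chunk_size`` ordering, worker
    count, and checkpoint state.
    """
    grid = ParamGrid(spec)
    n_total = len(grid)
    if checkpoint_dir is not None:
        os.makedirs(checkpoint_dir, exist_ok=True)

    starts = list(range(0, n_total, chunk_size))
    chunks: dict[int, dict[str, np.ndarray]] = {}
    todo = []
    for start in starts:
        stop = min(start + chunk_size, n_total)
        if checkpoint_dir is not None:
            path = os.path.join(checkpoint_dir, f"round1_{start}_{stop}.npz")
            cached = _load_chunk(path, start, stop)
            if cached is not None:
                chunks[start] = cached
                continue
        todo.append((start, stop))

    def _finish(start: int, stop: int, data: dict[str, np.ndarray]) -> None:
        chunks[start] = data
        if checkpoint_dir is not None:
            path = os.path.join(checkpoint_dir, f"round1_{start}_{stop}.npz")
            tmp = path + ".tmp.npz"
            np.savez(tmp, **data)
            os.replace(tmp, path)

    if workers > 1 and todo:
        from concurrent.futures import ProcessPoolExecutor

        with ProcessPoolExecutor(max_workers=workers) as pool:
            futures = {
                pool.submit(_round1_chunk, spec, start, stop): (start, stop)
                for start, stop in todo
            }
            for fut, (start, stop) in futures.items():
                _finish(start, stop, fut.result())
    else:
        iterator = todo
        if progress:
            try:
                from tqdm import tqdm

                iterator = tqdm(todo, desc="round 1")
            except ImportError:
                pass
        for start, stop in iterator:
            _finish(start, stop, _round1_chunk(spec, start, stop))

    order = sorted(chunks)
    wta_d = np.concatenate([chunks[s]["wta_d"] for s in order])
    wta_mp = np.concatenate([chunks[s]["wta_mp"] for s in order])
    wta_bp = np.concatenate([chunks[s]["wta_bp"] for s in order])
    blown = np.concatenate([chunks[s]["blown"] for s in order])
    pass1 = (
        ~blown
        & (wta_d > spec.wta_min)
        & (wta_d >= spec.ratio_min * wta_mp)
        & (wta_d >= spec.ratio_min * wta_bp)
    )
    round1_survivors = np.flatnonzero(pass1)

    # Round 2: re-score round-1 survivors at the long duration with fresh
    # noise, then test the two-round survivors for monocular-grating
    # plausibility.  Batched in chunks like round 1.
    survivors = []
    n_pass_both = 0
    n_plausible = 0
    for start in range(0, len(round1_survivors), chunk_size):
        idx2 = round1_survivors[start : start + chunk_size]
        vals2 = np.array([grid.values_at(int(i)) for i in idx2])
        wta2 = {}
        blown2 = np.zeros(len(idx2), dtype=bool)
        for key, condition in (
            ("d", "dichoptic_gratings"),
            ("mp", "monocular_plaid"),
            ("bp", "binocular_plaid"),
        ):
            w, b = _simulate_wta_batch(
                spec, idx2, vals2, condition, round_id=1,
                duration_s=spec.pass2_duration_s,
            )
            wta2[key] = w
            blown2 |= b
        pass2 = (
            ~blown2
            & (wta2["d"] > spec.wta_min)
            & (wta2["d"] >= spec.ratio_min * wta2["mp"])
            & (wta2["d"] >= spec.ratio_min * wta2["bp"])
        )
        if not pass2.any():
            continue
        idx3 = idx2[pass2]
        vals3 = vals2[pass2]
        switches, blown3 = _simulate_switches_batch(
            spec, idx3, vals3, round_id=1, duration_s=spec.pass2_duration_s
        )
        for j, idx in enumerate(idx3):
            n_pass_both += 1
            plausible = (not blown3[j]) and switches[j] < spec.switch_reject_min
            if plausible:
                n_plausible += 1
            k = int(np.flatnonzero(idx2 == idx)[0])
            survivors.append(
                {
                    "combo_index": int(idx),
                    "params": params_to_dict(grid.params_at(int(idx))),
                    "metrics": {
                        "wta_dichoptic_round1": float(wta_d[idx]),
                        "wta_mono_plaid_round1": float(wta_mp[idx]),
                        "wta_bino_plaid_round1": float(wta_bp[idx]),
                        "wta_dichoptic_round2": float(wta2["d"][k]),
                        "wta_mono_plaid_round2": float(wta2["mp"][k]),
                        "wta_bino_plaid_round2": float(wta2["bp"][k]),
                        "switch_count_mono_grating": int(switches[j]),
                    },
                    "plausible": bool(plausible),
                }
            )

    return {
        "n_total": int(n_total),
        "n_pass_round1": int(pass1.sum()),
        "n_pass_both": int(n_pass_both),
        "n_plausible": int(n_plausible),
        "n_failed": int(blown.sum()),
        "survivors": survivors,
        "seeds": {
            "base_seed": int(spec.base_seed),
            "scheme": "SeedSequence([base_seed, combo_index, condition_id, round_id])",
        },
        "criteria": {
            "wta_min": spec.wta_min,
            "ratio_min": spec.ratio_min,
            "switch_reject_min": spec.switch_reject_min,
        },
    }


def save_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
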