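"""Stochastic signalling-Petri-net (SPN) token-flow simulation.

Tokens represent transcript abundance.  A simulation is a set of independent
runs; each run advances through discrete *time blocks*.  Within a block every
transition fires once, in a fresh uniform-random order.  A firing moves

    f ~ UniformInteger{0 .. cap},   cap = max(0, min(activating) - sum(inhibitory))

tokens from each activating input to every output place.  Entry places are
non-depleting sources by default (an expression level is a sustained
abundance); ``entry_mode="depleting"`` consumes them like any other place.
Averaging token counts per place per block over runs gives the trace.

Reproducibility: run ``r`` draws from ``SeedSequence(seed, spawn_key=(r,))``;
per run, the block-wise transition permutations are drawn first, then the
flow uniforms, so the same seed yields bit-identical traces and adding runs
never reshuffles earlier ones.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PetriNetModel

ENTRY_MODES = ("source", "depleting")


def _flow_kernel(mark, act_ptr, act_idx, inh_ptr, inh_idx, out_ptr, out_idx,
                 clamped, perms, us, states):
    n_blocks, n_trans = perms.shape
    for b in range(n_blocks):
        for k in range(n_trans):
            t = perms[b, k]
            avail = -1
            for j in range(act_ptr[t], act_ptr[t + 1]):
                v = mark[act_idx[j]]
                if avail < 0 or v < avail:
                    avail = v
            inh = 0
            for j in range(inh_ptr[t], inh_ptr[t + 1]):
                inh += mark[inh_idx[j]]
            cap = avail - inh
            if cap < 0:
                cap = 0
            f = int(us[b, k] * (cap + 1))
            if f > cap:  # guard the (measure-zero) float rounding edge
                f = cap
            if f > 0:
                for j in range(act_ptr[t], act_ptr[t + 1]):
                    i = act_idx[j]
                    if not clamped[i]:
                        mark[i] -= f
                for j in range(out_ptr[t], out_ptr[t + 1]):
                    mark[out_idx[j]] += f
        for i in range(mark.shape[0]):
            states[i, b] = mark[i]


try:  # jitted and pure-Python paths use identical integer arithmetic
    from numba import njit

    _flow_kernel_fast = njit(cache=True)(_flow_kernel)
except ImportError:  # pragma: no cover - numba is a declared dependency
    _flow_kernel_fast = _flow_kernel


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation settings; the defaults are the study conditions
    (100 time blocks x 500 runs, outputs summarised over the final 10 blocks).
    """

    n_blocks: int = 100
    n_runs: int = 500
    summary_window: int = 10
    seed: int = 0
    entry_mode: str = "source"

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")
        if not 1 <= self.summary_window <= self.n_blocks:
            raise ValueError("summary_window must be in [1, n_blocks]")
        if self.entry_mode not in ENTRY_MODES:
            raise ValueError(f"entry_mode must be one of {ENTRY_MODES}")

    def to_dict(self) -> dict:
        return {
            "n_blocks": self.n_blocks, "n_runs": self.n_runs,
            "summary_window": self.summary_window, "seed": self.seed,
            "entry_mode": self.entry_mode,
        }


@dataclass
class Marking:
    """Tokens per place: the network state / initial parameterisation."""

    tokens: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for pid, v in self.tokens.items():
            if v < 0:
                raise ValueError(f"negative token count for place {pid!r}")

    def validate_against(self, model: PetriNetModel) -> None:
        for pid in self.tokens:
            if pid not in model:
                raise ValueError(f"marking references unknown place {pid!r}")

    def get(self, pid: str) -> int:
        return self.tokens.get(pid, 0)


@dataclass
class TokenTrace:
    """Per-place token time series: mean and sd across runs (place x block)."""

    place_ids: tuple[str, ...]
    output_place_ids: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    config: SimulationConfig
    model_name: str
    #: per-run summary of each output place over the final summary window
    per_run_output_summary: np.ndarray | None = None

    @property
    def n_blocks(self) -> int:
        return self.mean.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, pid in enumerate(self.place_ids):
            for b in range(self.n_blocks):
                rows.append((pid, b, self.mean[i, b], self.sd[i, b]))
        return pd.DataFrame(rows, columns=["place", "block", "mean", "sd"])

    def write_tsv(self, path, sidecar_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        if sidecar_path is not None:
            with open(sidecar_path, "w", encoding="utf-8") as fh:
                json.dump(
                    {"model": self.model_name, "config": self.config.to_dict()},
                    fh, indent=2, sort_keys=True,
                )
                fh.write("\n")


def compute_flow(available: int, inhibitor_tokens: int, rng) -> int:
    """Draw one token flow: uniform on {0..cap}, cap = available - inhibitors."""
    if available < 0 or inhibitor_tokens < 0:
        raise ValueError("token counts must be non-negative")
    cap = max(0, available - inhibitor_tokens)
    return min(int(rng.random() * (cap + 1)), cap)


def _compile_arrays(model: PetriNetModel):
    pidx = {p.id: i for i, p in enumerate(model.places)}
    act_ptr, act_idx = [0], []
    inh_ptr, inh_idx = [0], []
    out_ptr, out_idx = [0], []
    for t in model.transitions:
        act_idx.extend(pidx[p] for p in t.activating_inputs)
        inh_idx.extend(pidx[p] for p in t.inhibitory_inputs)
        out_idx.extend(pidx[p] for p in t.outputs)
        act_ptr.append(len(act_idx))
        inh_ptr.append(len(inh_idx))
        out_ptr.append(len(out_idx))
    i64 = np.int64
    return pidx, (
        np.array(act_ptr, i64), np.array(act_idx, i64),
        np.array(inh_ptr, i64), np.array(inh_idx, i64),
        np.array(out_ptr, i64), np.array(out_idx, i64),
    )


def simulate(model: PetriNetModel, initial: Marking,
             config: SimulationConfig) -> TokenTrace:
    """Run the stochastic token-flow simulation and aggregate across runs."""
    initial.validate_against(model)
    pidx, arrays = _compile_arrays(model)
    act_ptr, act_idx, inh_ptr, inh_idx, out_ptr, out_idx = arrays
    n_places = len(model.places)
    n_trans = len(model.transitions)
    n_blocks, n_runs = config.n_blocks, config.n_runs

    m0 = np.zeros(n_places, dtype=np.int64)
    for pid, v in initial.tokens.items():
        m0[pidx[pid]] = v
    clamped = np.zeros(n_places, dtype=np.bool_)
    if config.entry_mode == "source":
        for p in model.entry_places:
            clamped[pidx[p.id]] = True

    out_ids = tuple(p.id for p in model.output_places)
    out_rows = np.array([pidx[p] for p in out_ids], dtype=np.int64)
    w = config.summary_window

    total = np.zeros((n_places, n_blocks), dtype=np.float64)
    total_sq = np.zeros((n_places, n_blocks), dtype=np.float64)
    per_run = np.zeros((n_runs, len(out_ids)), dtype=np.float64)
    states = np.empty((n_places, n_blocks), dtype=np.int64)
    base_perm = np.tile(np.arange(n_trans, dtype=np.int64), (n_blocks, 1))
    kernel = _flow_kernel_fast if n_trans > 0 else None

    for run in range(n_runs):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(run,))
        )
        if kernel is not None:
            perms = rng.permuted(base_perm, axis=1)
            us = rng.random((n_blocks, n_trans))
            mark = m0.copy()
            kernel(mark, act_ptr, act_idx, inh_ptr, inh_idx, out_ptr, out_idx,
                   clamped, perms, us, states)
        else:
            states[:] = m0[:, None]
        total += states
        total_sq += states.astype(np.float64) ** 2
        if len(out_rows):
            per_run[run] = states[out_rows, n_blocks - w:].mean(axis=1)

    mean = total / n_runs
    var = np.maximum(total_sq / n_runs - mean ** 2, 0.0)
    return TokenTrace(
        place_ids=tuple(p.id for p in model.places),
        output_place_ids=out_ids,
        mean=mean, sd=np.sqrt(var),
        config=config, model_name=model.name,
        per_run_output_summary=per_run,
    )


def summarize_outputs(trace: TokenTrace, window: int | None = None
                      ) -> dict[str, float]:
    """Mean token count of each output place over the final ``window`` blocks."""
    if window is None:
        window = trace.config.summary_window
    if not 1 <= window <= trace.n_blocks:
        raise ValueError(
            f"window must be in [1, {trace.n_blocks}], got {window}"
        )
    idx = {pid: i for i, pid in enumerate(trace.place_ids)}
    return {
        pid: float(trace.mean[idx[pid], trace.n_blocks - window:].mean())
        for pid in trace.output_place_ids
    }


def write_summary_tsv(summary: dict[str, float], path) -> None:
    frame = pd.DataFrame(
        sorted(summary.items()), columns=["place", "summary"]
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
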