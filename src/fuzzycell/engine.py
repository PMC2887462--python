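"""Deterministic synchronous time-stepping of a rule-based fuzzy model.

Each reaction's instantaneous rate is its rate coefficient times the
product of the fuzzy-inferred factors of *all* its participants (products
and substrates gate their own reaction exactly like activators and
inhibitors do; the roles differ only in stoichiometry).  A step advances
every product up and every substrate down by ``rate * dt``, computing all
rates from the state at the start of the step, then clamps every node to
the unit interval.  The factor of one participant as a function of its
node value is piecewise linear with breakpoints at the partition
centroids, which lets the whole state update be evaluated with a handful
of vectorized array operations per step.

Interventions activate at the first step boundary at or after their start
time: ``clamp_node`` pins a node after every subsequent step,
``scale_rate`` multiplies a reaction's rate coefficient, and
``scale_rule_sensitivity`` multiplies the inferred factor of one named
participant of a reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .fuzzy_core import (
    DEFAULT_PARTITION,
    N_LEVELS,
    FuzzyPartition,
    fuzzify,
    infer_rule,
)
from .model_spec import ModelSpec, Reaction

__all__ = [
    "SimulationConfig",
    "Intervention",
    "SimulationResult",
    "reaction_rate",
    "step",
    "simulate",
    "downsample",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Time grid and clamping bounds of a run.

    Defaults reproduce the reference protocol: model time 0 to 40 covered
    by 10000 synchronous iterations (dt = 0.004), node values clamped to
    the unit interval.
    """

    t_start: float = 0.0
    t_end: float = 40.0
    n_steps: int = 10000
    clamp_low: float = 0.0
    clamp_high: float = 1.0
    record_stride: int = 1

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if self.clamp_low >= self.clamp_high:
            raise ValueError("clamp_low must be below clamp_high")
        if self.record_stride < 1:
            raise ValueError("record_stride must be at least 1")

    @property
    def dt(self) -> float:
        return (self.t_end - self.t_start) / self.n_steps


@dataclass(frozen=True)
class Intervention:
    """A timed perturbation applied during a run.

    kind:
        ``clamp_node``   -- pin node ``target`` to ``value`` from
        ``start_time`` on.
        ``scale_rate``   -- multiply reaction ``target``'s rate
        coefficient by ``value``.
        ``scale_rule_sensitivity`` -- multiply the inferred factor of
        participant node ``participant`` within reaction ``target`` by
        ``value``.
    """

    kind: str
    target: str
    value: float
    start_time: float = 0.0
    participant: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("clamp_node", "scale_rate", "scale_rule_sensitivity"):
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if self.kind == "clamp_node" and not 0.0 <= self.value <= 1.0:
            raise ValueError("clamp level must lie in [0, 1]")
        if self.kind != "clamp_node" and self.value < 0:
            raise ValueError("scale factors must be non-negative")
        if self.kind == "scale_rule_sensitivity" and self.participant is None:
            raise ValueError("scale_rule_sensitivity needs a participant node")


@dataclass
class SimulationResult:
    """Recorded trajectories of one run."""

    times: np.ndarray
    series: Dict[str, np.ndarray]
    config: SimulationConfig
    interventions_applied: Tuple[str, ...] = ()

    def __getitem__(self, node: str) -> np.ndarray:
        try:
            return self.series[node]
        except KeyError:
            raise KeyError(f"no recorded series for node {node!r}") from None

    @property
    def node_names(self) -> Tuple[str, ...]:
        return tuple(self.series)

    def final_state(self) -> Dict[str, float]:
        return {name: float(s[-1]) for name, s in self.series.items()}

    def to_frame(self):
        """Tidy (time, node, value) DataFrame."""
        import pandas as pd

        frames = [
            pd.DataFrame({"time": self.times, "node": name, "value": values})
            for name, values in self.series.items()
        ]
        return pd.concat(frames, ignore_index=True)


# -- reference scalar path -------------------------------------------------

def reaction_rate(
    state: Mapping[str, float],
    reaction: Reaction,
    partition: FuzzyPartition = DEFAULT_PARTITION,
) -> float:
    """Instantaneous rate of one reaction at the given state."""
    rate = reaction.rate_coefficient
    for p in reaction.participants:
        if p.node not in state:
            raise KeyError(
                f"reaction {reaction.name}: node {p.node!r} missing from state"
            )
        rate *= infer_rule(fuzzify(state[p.node], partition), p.rule)
    return rate


def step(
    state: Mapping[str, float],
    model: ModelSpec,
    dt: float,
    partition: FuzzyPartition = DEFAULT_PARTITION,
    clamp: Tuple[float, float] = (0.0, 1.0),
) -> Dict[str, float]:
    """One synchronous forward-Euler step (reference implementation)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    new = dict(state)
    for r in model.reactions:
        rate = reaction_rate(state, r, partition)
        if not np.isfinite(rate):
            raise ArithmeticError(f"non-finite rate in reaction {r.name}")
        for p in r.participants:
            if p.role == "pro":
                new[p.node] += rate * dt
            elif p.role == "sub":
                new[p.node] -= rate * dt
    lo, hi = clamp
    return {k: min(max(v, lo), hi) for k, v in new.items()}


# -- compiled vectorized path ---------------------------------------------

class _Compiled:
    """Array form of a model: padded participant tables per reaction."""

    def __init__(self, model: ModelSpec, partition: FuzzyPartition):
        names = model.node_names
        self.node_index = {n: i for i, n in enumerate(names)}
        self.names = names
        n_reac = len(model.reactions)
        max_p = max((len(r.participants) for r in model.reactions), default=1)
        self.centroids = np.asarray(partition.centroids)
        # Padded slots point at node 0 with a constant-1 table.
        self.p_node = np.zeros((n_reac, max_p), dtype=np.intp)
        self.tables = np.ones((n_reac, max_p, N_LEVELS))
        self.k = np.empty(n_reac)
        stoich_rows: List[Tuple[int, int, float]] = []
        for i, r in enumerate(model.reactions):
            self.k[i] = r.rate_coefficient
            for j, p in enumerate(r.participants):
                ni = self.node_index[p.node]
                self.p_node[i, j] = ni
                self.tables[i, j] = np.asarray(p.rule.outputs) / (N_LEVELS - 1)
                if p.role == "pro":
                    stoich_rows.append((i, ni, +1.0))
                elif p.role == "sub":
                    stoich_rows.append((i, ni, -1.0))
        # Stoichiometry as a dense (n_nodes x n_reac) matrix.
        self.stoich = np.zeros((len(names), n_reac))
        for reac, node, sign in stoich_rows:
            self.stoich[node, reac] += sign
        self.reaction_index = {r.name: i for i, r in enumerate(model.reactions)}
        self.participant_index = {
            (r.name, p.node): (i, j)
            for i, r in enumerate(model.reactions)
            for j, p in enumerate(r.participants)
        }

    def rates(self, state: np.ndarray, k: np.ndarray, p_scale: np.ndarray) -> np.ndarray:
        x = state[self.p_node]  # (n_reac, max_p)
        hi = np.clip(
            np.searchsorted(self.centroids, x, side="right"), 1, N_LEVELS - 1
        )
        lo = hi - 1
        c_lo = self.centroids[lo]
        frac = (x - c_lo) / (self.centroids[hi] - c_lo)
        f_lo = np.take_along_axis(self.tables, lo[..., None], axis=2)[..., 0]
        f_hi = np.take_along_axis(self.tables, hi[..., None], axis=2)[..., 0]
        factors = (f_lo * (1.0 - frac) + f_hi * frac) * p_scale
        return k * factors.prod(axis=1)


def simulate(
    model: ModelSpec,
    config: SimulationConfig = SimulationConfig(),
    interventions: Sequence[Intervention] = (),
    partition: FuzzyPartition = DEFAULT_PARTITION,
) -> SimulationResult:
    """Run the model over the configured horizon.

    Identical inputs give bit-identical outputs; there is no randomness
    anywhere in the stepper.
    """
    comp = _Compiled(model, partition)
    for iv in interventions:
        if iv.kind == "clamp_node":
            if iv.target not in comp.node_index:
                raise ValueError(f"intervention targets unknown node {iv.target!r}")
        else:
            if iv.target not in comp.reaction_index:
                raise ValueError(
                    f"intervention targets unknown reaction {iv.target!r}"
                )
            if iv.kind == "scale_rule_sensitivity":
                if (iv.target, iv.participant) not in comp.participant_index:
                    raise ValueError(
                        f"reaction {iv.target!r} has no participant "
                        f"{iv.participant!r}"
                    )
        if not config.t_start <= iv.start_time <= config.t_end:
            raise ValueError(
                f"intervention start time {iv.start_time} outside the horizon"
            )

    dt = config.dt
    state = np.array(
        [model.initial_state[n] for n in comp.names], dtype=np.float64
    )
    np.clip(state, config.clamp_low, config.clamp_high, out=state)

    n_rec = config.n_steps // config.record_stride + 1
    recorded = np.empty((n_rec, len(state)))
    rec_times = np.empty(n_rec)
    recorded[0] = state
    rec_times[0] = config.t_start
    rec = 1

    k = comp.k.copy()
    p_scale = np.ones_like(comp.p_node, dtype=np.float64)
    pending = sorted(interventions, key=lambda iv: iv.start_time)
    active_clamps: List[Tuple[int, float]] = []
    applied: List[str] = []

    for i in range(config.n_steps):
        t = config.t_start + i * dt
        while pending and pending[0].start_time <= t + 1e-12:
            iv = pending.pop(0)
            if iv.kind == "clamp_node":
                ni = comp.node_index[iv.target]
                active_clamps.append((ni, iv.value))
                state[ni] = iv.value
            elif iv.kind == "scale_rate":
                k[comp.reaction_index[iv.target]] *= iv.value
            else:
                ri, pj = comp.participant_index[(iv.target, iv.participant)]
                p_scale[ri, pj] *= iv.value
            applied.append(
                f"t={t:g} {iv.kind} {iv.target}"
                + (f"/{iv.participant}" if iv.participant else "")
                + f" value={iv.value:g}"
            )
        rates = comp.rates(state, k, p_scale)
        state += comp.stoich @ (rates * dt)
        if not np.all(np.isfinite(state)):
            bad = [comp.names[j] for j in np.where(~np.isfinite(state))[0]]
            raise ArithmeticError(
                f"non-finite node value(s) at t={t:g}: {', '.join(bad)}"
            )
        np.clip(state, config.clamp_low, config.clamp_high, out=state)
        for ni, value in active_clamps:
            state[ni] = value
        if (i + 1) % config.record_stride == 0:
            recorded[rec] = state
            rec_times[rec] = config.t_start + (i + 1) * dt
            rec += 1

    series = {name: recorded[:rec, j].copy() for j, name in enumerate(comp.names)}
    return SimulationResult(
        times=rec_times[:rec],
        series=series,
        config=config,
        interventions_applied=tuple(applied),
    )


def downsample(result: SimulationResult, window: int) -> SimulationResult:
    """Non-overlapping window means of every series (trailing partial kept)."""
    if window < 1:
        raise ValueError("window must be a positive integer")
    if window == 1:
        return result
    n = len(result.times)
    edges = np.arange(0, n, window)
    times = np.array(
        [result.times[s : s + window].mean() for s in edges]
    )
    series = {
        name: np.array([v[s : s + window].mean() for s in edges])
        for name, v in result.series.items()
    }
    return SimulationResult(
        times=times,
        series=series,
        config=result.config,
        interventions_applied=result.interventions_applied,
    )
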