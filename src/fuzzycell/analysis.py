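"""Lifespan evaluation, intervention experiments and sensitivity analyses.

Model lifespan ends at the earliest crossing of a fitness criterion:
oxidised proteins rising to 0.4, ROS rising to 0.4, or ATP consumption
falling to 0.4.  The sensitivity objective function (SOF) of a reaction
is the percent change in lifespan divided by the percent change applied
to its rate coefficient; |SOF| > 2.5 marks a significant reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .engine import (
    Intervention,
    SimulationConfig,
    SimulationResult,
    simulate,
)
from .model_spec import ModelSpec

__all__ = [
    "FitnessCriteria",
    "LifespanResult",
    "SOFRecord",
    "SweepRun",
    "lifespan",
    "accumulated_energy",
    "run_blockade_experiment",
    "run_mtor_experiment",
    "sof_screen",
    "sensor_sweep",
    "rate_magnitude_regression",
    "SENSOR_PARTICIPANTS",
]

SOF_SIGNIFICANCE = 2.5


@dataclass(frozen=True)
class FitnessCriteria:
    """Thresholds ending cellular lifespan (first crossing wins)."""

    oxprot_max: float = 0.4
    ros_max: float = 0.4
    atpconsume_min: float = 0.4

    def __post_init__(self) -> None:
        for v in (self.oxprot_max, self.ros_max, self.atpconsume_min):
            if not 0.0 < v < 1.0:
                raise ValueError("fitness thresholds must lie in (0, 1)")

    def conditions(self) -> Tuple[Tuple[str, str, float], ...]:
        """(node, direction, threshold) triples; direction 'ge' or 'le'."""
        return (
            ("OXPROT", "ge", self.oxprot_max),
            ("ROS", "ge", self.ros_max),
            ("ATPconsume", "le", self.atpconsume_min),
        )


#: OXPROT-only stopping rule used by the sensor sweeps.
OXPROT_ONLY = FitnessCriteria(oxprot_max=0.4, ros_max=1.0 - 1e-9, atpconsume_min=1e-9)


@dataclass(frozen=True)
class LifespanResult:
    lifespan: float
    censored: bool
    triggering_criterion: Optional[str]
    crossing_times: Tuple[Tuple[str, float], ...]  # per criterion, nan if never

    def crossing(self, criterion: str) -> float:
        return dict(self.crossing_times)[criterion]


def _first_crossing(
    times: np.ndarray, values: np.ndarray, direction: str, threshold: float
) -> float:
    hit = values >= threshold if direction == "ge" else values <= threshold
    idx = np.argmax(hit)
    if not hit[idx]:
        return float("nan")
    return float(times[idx])


def lifespan(
    result: SimulationResult, criteria: FitnessCriteria = FitnessCriteria()
) -> LifespanResult:
    """Earliest fitness-criterion crossing in a recorded run.

    Crossings are reported at the first recorded time at which the
    condition holds; a run in which no criterion fires is censored at the
    end of the horizon.
    """
    crossings = []
    for node, direction, threshold in criteria.conditions():
        if node not in result.series:
            raise KeyError(f"criterion node {node!r} absent from result")
        label = f"{node}_{direction}_{threshold:g}"
        t = _first_crossing(result.times, result[node], direction, threshold)
        crossings.append((label, t))
    finite = [(label, t) for label, t in crossings if not np.isnan(t)]
    if finite:
        label, t = min(finite, key=lambda item: item[1])
        return LifespanResult(t, False, label, tuple(crossings))
    return LifespanResult(float(result.times[-1]), True, None, tuple(crossings))


def accumulated_energy(
    result: SimulationResult,
    node: str = "ATPconsume",
    until: Optional[float] = None,
) -> float:
    """Trapezoidal time-integral of the ATP-consumption trajectory.

    ``until`` restricts the integral to recorded times at or before a
    cutoff (typically the lifespan), which is how accumulated energy
    turnover over a life is compared between models.
    """
    if node not in result.series:
        raise KeyError(f"node {node!r} absent from result")
    values, times = result[node], result.times
    if until is not None:
        mask = times <= until
        values, times = values[mask], times[mask]
    return float(np.trapezoid(values, times))


# -- intervention experiments ---------------------------------------------


@dataclass(frozen=True)
class BlockadeOutcome:
    baseline: SimulationResult
    blocked: SimulationResult
    blockade_time: float
    ros_slope_baseline: float
    ros_slope_blocked: float
    lifespan_baseline: LifespanResult
    lifespan_blocked: LifespanResult


def _mean_slope(result: SimulationResult, node: str, t0: float, t1: float) -> float:
    mask = (result.times >= t0) & (result.times <= t1)
    t, v = result.times[mask], result[node][mask]
    if len(t) < 2:
        return 0.0
    return float(np.polyfit(t, v, 1)[0])


def run_blockade_experiment(
    model: ModelSpec,
    blockade_time: float,
    config: SimulationConfig = SimulationConfig(),
    criteria: FitnessCriteria = OXPROT_ONLY,
) -> BlockadeOutcome:
    """Clamp NF-κB to its initial activity from ``blockade_time`` on.

    Returns both runs plus the mean post-blockade ROS slope of each and
    their lifespans.
    """
    if not model.has_node("NFkB"):
        raise ValueError("model has no NFkB node to block")
    initial = model.initial_state["NFkB"]
    baseline = simulate(model, config)
    blocked = simulate(
        model,
        config,
        [Intervention("clamp_node", "NFkB", initial, start_time=blockade_time)],
    )
    window_end = min(blockade_time + 0.25 * (config.t_end - config.t_start),
                     config.t_end)
    return BlockadeOutcome(
        baseline=baseline,
        blocked=blocked,
        blockade_time=blockade_time,
        ros_slope_baseline=_mean_slope(baseline, "ROS", blockade_time, window_end),
        ros_slope_blocked=_mean_slope(blocked, "ROS", blockade_time, window_end),
        lifespan_baseline=lifespan(baseline, criteria),
        lifespan_blocked=lifespan(blocked, criteria),
    )


@dataclass(frozen=True)
class MtorOutcome:
    baseline: SimulationResult
    perturbed: SimulationResult
    sensitivity_factor: float
    lifespan_baseline: LifespanResult
    lifespan_perturbed: LifespanResult


def run_mtor_experiment(
    model: ModelSpec,
    sensitivity_factor: float,
    config: SimulationConfig = SimulationConfig(),
    criteria: FitnessCriteria = OXPROT_ONLY,
) -> MtorOutcome:
    """Scale mTOR's sensitivity to ATP levels (reaction MTOR_ATP)."""
    try:
        reaction = model.reaction("MTOR_ATP")
    except KeyError:
        raise ValueError("model has no MTOR_ATP reaction") from None
    if not any(p.node == "ATP" for p in reaction.participants):
        raise ValueError("MTOR_ATP has no ATP participant to scale")
    baseline = simulate(model, config)
    perturbed = simulate(
        model,
        config,
        [Intervention(
            "scale_rule_sensitivity", "MTOR_ATP", sensitivity_factor,
            participant="ATP",
        )],
    )
    return MtorOutcome(
        baseline=baseline,
        perturbed=perturbed,
        sensitivity_factor=sensitivity_factor,
        lifespan_baseline=lifespan(baseline, criteria),
        lifespan_perturbed=lifespan(perturbed, criteria),
    )


# -- sensitivity analyses --------------------------------------------------


@dataclass(frozen=True)
class SOFRecord:
    reaction: str
    rate_coefficient: float
    perturbation: float
    lifespan_baseline: float
    lifespan_perturbed: float
    lifespan_change: float  # fractional
    sof: float
    significant: bool


def sof_screen(
    model: ModelSpec,
    perturbation: float = 0.05,
    criteria: FitnessCriteria = FitnessCriteria(),
    config: SimulationConfig = SimulationConfig(),
) -> List[SOFRecord]:
    """Perturb every reaction rate by the given fraction, one at a time.

    SOF = (% change in lifespan) / (% change in rate); significance at
    |SOF| > 2.5 under the earliest-of-three fitness criteria.
    """
    if perturbation == 0:
        raise ValueError("perturbation must be nonzero")
    base_life = lifespan(simulate(model, config), criteria).lifespan
    records = []
    for r in model.reactions:
        scaled = model.with_rate(r.name, r.rate_coefficient * (1.0 + perturbation))
        life = lifespan(simulate(scaled, config), criteria).lifespan
        change = (life - base_life) / base_life
        sof = change / perturbation
        records.append(
            SOFRecord(
                reaction=r.name,
                rate_coefficient=r.rate_coefficient,
                perturbation=perturbation,
                lifespan_baseline=base_life,
                lifespan_perturbed=life,
                lifespan_change=change,
                sof=sof,
                significant=abs(sof) > SOF_SIGNIFICANCE,
            )
        )
    return records


#: Activating participants whose inferred factor a sensor sweep rescales.
SENSOR_PARTICIPANTS: Dict[str, Tuple[Tuple[str, str], ...]] = {
    "nfkb": (("NFkB_ROS", "ROS"), ("NFkB_OXPROT", "OXPROT")),
    "mtor": (("MTOR_ATP", "ATP"),),
}


@dataclass(frozen=True)
class SweepRun:
    delta: float
    result: SimulationResult
    lifespan: LifespanResult
    atpconsume_crossing: float  # nan if never below threshold


def sensor_sweep(
    model: ModelSpec,
    sensor: str,
    deltas: Sequence[float],
    criteria: FitnessCriteria = OXPROT_ONLY,
    config: SimulationConfig = SimulationConfig(),
    atpconsume_min: float = 0.4,
) -> List[SweepRun]:
    """Rescale a stress sensor's activation sensitivity across deltas.

    ``sensor`` is ``"nfkb"`` (activation by ROS and oxidised proteins) or
    ``"mtor"`` (activation by ATP).  Each delta multiplies the inferred
    factor of the activating participant(s) by (1 + delta).  Lifespan uses
    the oxidised-protein criterion alone; the time at which ATP
    consumption drops to ``atpconsume_min`` is annotated separately.
    """
    key = sensor.lower()
    if key not in SENSOR_PARTICIPANTS:
        raise ValueError(f"unknown sensor {sensor!r}; use 'nfkb' or 'mtor'")
    targets = SENSOR_PARTICIPANTS[key]
    for rname, pnode in targets:
        reaction = model.reaction(rname)
        if not any(p.node == pnode for p in reaction.participants):
            raise ValueError(f"reaction {rname} lacks participant {pnode}")
    runs = []
    for delta in deltas:
        interventions = [
            Intervention(
                "scale_rule_sensitivity", rname, 1.0 + delta, participant=pnode
            )
            for rname, pnode in targets
        ]
        result = simulate(model, config, interventions)
        life = lifespan(result, criteria)
        atp_cross = _first_crossing(
            result.times, result["ATPconsume"], "le", atpconsume_min
        )
        runs.append(SweepRun(delta, result, life, atp_cross))
    return runs


def rate_magnitude_regression(
    records: Sequence[SOFRecord],
) -> Tuple[float, float, float]:
    """OLS of the fractional lifespan change on rate-coefficient
    magnitude: (slope, intercept, p).

    Tests whether large rate coefficients systematically shift lifespan
    further; the p-value is the two-sided slope test.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for a regression")
    x = np.array([r.rate_coefficient for r in records])
    y = np.array([r.lifespan_change for r in records])
    if np.ptp(x) == 0:
        raise ValueError("rate coefficients are constant; regression undefined")
    from scipy.stats import linregress

    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.pvalue)
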