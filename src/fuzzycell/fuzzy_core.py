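"""Six-level triangular fuzzy system on the unit interval.

Every node in a model carries a real value in [0, 1].  The value is mapped
onto six overlapping triangular fuzzy sets whose centroids partition the
interval; a real number lying exactly on a centroid belongs 100% to that
set, any other number belongs fractionally to the two sets whose centroids
bracket it.  Inference follows the standard additive model: the membership
weights of the input are applied unchanged to the rule's output levels,
and the weighted output level (rescaled to [0, 1]) is the inferred factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "N_LEVELS",
    "FuzzyPartition",
    "MembershipVector",
    "RuleVector",
    "DEFAULT_PARTITION",
    "fuzzify",
    "defuzzify",
    "infer_rule",
]

#: Number of fuzzy states; fixed by the modelling framework.
N_LEVELS = 6

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class FuzzyPartition:
    """Ordered centroids of the six triangular membership functions.

    Centroids must be strictly increasing, start at 0.0 and end at 1.0 so
    that the partition covers the unit interval and fuzzify/defuzzify form
    an exact round trip.
    """

    centroids: Tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

    def __post_init__(self) -> None:
        c = tuple(float(v) for v in self.centroids)
        if len(c) != N_LEVELS:
            raise ValueError(f"partition needs {N_LEVELS} centroids, got {len(c)}")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("centroids must be strictly increasing")
        if c[0] != 0.0 or c[-1] != 1.0:
            raise ValueError("centroids must span [0, 1] exactly")
        object.__setattr__(self, "centroids", c)

    @property
    def n_levels(self) -> int:
        return N_LEVELS


#: The evenly spaced partition used by all shipped models.
DEFAULT_PARTITION = FuzzyPartition()


@dataclass(frozen=True)
class MembershipVector:
    """Fractional membership weights over the six fuzzy levels.

    Weights are non-negative, sum to one, and at most two (adjacent)
    weights are nonzero -- the defining property of the triangular overlap.
    """

    weights: Tuple[float, ...]

    def __post_init__(self) -> None:
        w = tuple(float(v) for v in self.weights)
        if len(w) != N_LEVELS:
            raise ValueError(f"membership vector needs {N_LEVELS} weights")
        if any(v < -_NORM_TOL or v > 1.0 + _NORM_TOL for v in w):
            raise ValueError("membership weights must lie in [0, 1]")
        if abs(sum(w) - 1.0) > _NORM_TOL:
            raise ValueError(f"membership weights must sum to 1, got {sum(w)!r}")
        nz = [i for i, v in enumerate(w) if v != 0.0]
        if len(nz) > 2 or (len(nz) == 2 and nz[1] - nz[0] != 1):
            raise ValueError("at most two adjacent weights may be nonzero")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class RuleVector:
    """Output fuzzy level (0..5) assigned to each input fuzzy level.

    A rule vector encodes one participant's response curve, e.g.
    ``(0, 1, 2, 3, 4, 5)`` is proportional activation and
    ``(5, 2, 1, 0, 0, 0)`` promotes strongly only at low input.
    """

    outputs: Tuple[int, ...]

    def __post_init__(self) -> None:
        out = tuple(int(v) for v in self.outputs)
        if len(out) != N_LEVELS:
            raise ValueError(f"rule vector needs {N_LEVELS} outputs")
        if any(v < 0 or v >= N_LEVELS for v in out):
            raise ValueError(f"rule outputs must be in 0..{N_LEVELS - 1}: {out}")
        object.__setattr__(self, "outputs", out)

    def is_nondecreasing(self) -> bool:
        return all(b >= a for a, b in zip(self.outputs, self.outputs[1:]))

    def is_nonincreasing(self) -> bool:
        return all(b <= a for a, b in zip(self.outputs, self.outputs[1:]))


def fuzzify(x: float, partition: FuzzyPartition = DEFAULT_PARTITION) -> MembershipVector:
    """Map a real number in [0, 1] to its unique membership vector.

    The weights are the linear-interpolation coefficients of ``x`` between
    the two bracketing centroids; a value sitting exactly on a centroid is
    one-hot at that level.
    """
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"value {x!r} outside the fuzzy domain [0, 1]")
    c = partition.centroids
    hi = int(np.searchsorted(c, x))
    w = [0.0] * N_LEVELS
    if c[hi] == x:
        w[hi] = 1.0
    else:
        lo = hi - 1
        frac = (x - c[lo]) / (c[hi] - c[lo])
        w[lo] = 1.0 - frac
        w[hi] = frac
    return MembershipVector(tuple(w))


def defuzzify(
    membership: MembershipVector, partition: FuzzyPartition = DEFAULT_PARTITION
) -> float:
    """Centroid read-out: the membership-weighted mean of the centroids."""
    return float(
        sum(m * c for m, c in zip(membership.weights, partition.centroids))
    )


def infer_rule(membership: MembershipVector, rule: RuleVector) -> float:
    """Single-rule standard-additive inference.

    The input membership weights are applied to the rule's output levels
    and the weighted level is rescaled by the top level, giving a factor
    in [0, 1].
    """
    level = sum(m * o for m, o in zip(membership.weights, rule.outputs))
    return float(level / (N_LEVELS - 1))
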