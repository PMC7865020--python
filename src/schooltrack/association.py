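"""Cost-matrix construction and one-to-one Hungarian data association.

The per-pair cost couples Euclidean position distance with an
angle-agreement term: ``w1*d + w2*d*dtheta/(2*pi)``, where ``d`` is the
position distance between a predicted track state and a detection and
``dtheta`` their minimal circular angle difference in ``[0, pi]``.  The
angle term is a bounded modulation of distance (at most ``d/2``), so
heading disagreement breaks ties between nearby candidates without ever
dominating geometry.

Assignment is solved to global optimality with the Munkres/Hungarian
algorithm (scipy's ``linear_sum_assignment``); a post-solve cost gate
discards implausible long-range matches and reports them as unmatched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .kalman import angle_difference

TWO_PI = 2.0 * math.pi


def pair_cost(
    s: tuple[float, float, float],
    r: tuple[float, float, float],
    w1: float = 1.0,
    w2: float = 1.0,
) -> float:
    """Association cost between one source ``(s_x, s_y, s_theta)`` and
    one target ``(r_x, r_y, r_theta)``."""
    d = math.hypot(s[0] - r[0], s[1] - r[1])
    dtheta = abs(angle_difference(s[2], r[2]))
    return w1 * d + w2 * d * dtheta / TWO_PI


@dataclass(frozen=True)
class CostMatrix:
    """m x k association costs between predicted states and detections."""

    costs: np.ndarray
    sources: tuple[tuple[float, float, float], ...] = ()
    targets: tuple[tuple[float, float, float], ...] = ()
    w1: float = 1.0
    w2: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.costs, dtype=float)
        if c.ndim != 2:
            raise ValueError("cost matrix must be 2-D")
        if c.size and (not np.all(np.isfinite(c)) or np.any(c < 0)):
            raise ValueError("costs must be finite and non-negative")
        object.__setattr__(self, "costs", c)

    @property
    def shape(self) -> tuple[int, int]:
        return self.costs.shape


def build_cost_matrix(
    predicted: list[tuple[float, float, float]],
    detections: list,
    w1: float = 1.0,
    w2: float = 1.0,
) -> CostMatrix:
    """Dense cost matrix; ``detections`` may be ``HeadDetection`` objects
    or raw ``(x, y, theta)`` triples.  Either list may be empty."""
    targets = []
    for det in detections:
        if hasattr(det, "centroid"):
            targets.append((det.centroid[0], det.centroid[1], det.angle))
        else:
            targets.append((float(det[0]), float(det[1]), float(det[2])))
    m, k = len(predicted), len(targets)
    costs = np.zeros((m, k))
    for i, s in enumerate(predicted):
        for j, r in enumerate(targets):
            costs[i, j] = pair_cost(s, r, w1, w2)
    return CostMatrix(costs, tuple(predicted), tuple(targets), w1, w2)


@dataclass(frozen=True)
class Assignment:
    """One-to-one matching result with leftover indices on both sides."""

    pairs: tuple[tuple[int, int], ...]
    unmatched_sources: tuple[int, ...]
    unmatched_targets: tuple[int, ...]
    total_cost: float = 0.0


def solve_assignment(
    costs: CostMatrix | np.ndarray, gate: float = math.inf
) -> Assignment:
    """Globally optimal one-to-one assignment with post-solve gating.

    Rectangular matrices are solved directly (every row or every column
    is matched, whichever side is smaller).  Any matched pair whose cost
    exceeds ``gate`` is struck afterwards and both members reported
    unmatched; ``gate = inf`` disables gating.
    """
    c = costs.costs if isinstance(costs, CostMatrix) else np.asarray(costs, dtype=float)
    m, k = c.shape
    if m == 0 or k == 0:
        return Assignment((), tuple(range(m)), tuple(range(k)), 0.0)
    rows, cols = linear_sum_assignment(c)
    pairs = []
    for i, j in zip(rows, cols):
        if c[i, j] <= gate:
            pairs.append((int(i), int(j)))
    matched_s = {i for i, _ in pairs}
    matched_t = {j for _, j in pairs}
    return Assignment(
        tuple(pairs),
        tuple(i for i in range(m) if i not in matched_s),
        tuple(j for j in range(k) if j not in matched_t),
        float(sum(c[i, j] for i, j in pairs)),
    )
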