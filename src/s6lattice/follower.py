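"""The Follower validation scan.

A distance algorithm on a boundary-glued space is easy to get subtly wrong;
the Follower is the quality-control instrument.  It draws the straight S6
segment from an (unreduced) start point to that point's Selling-reduced
image, and at evenly spaced positions records the distance from the sample's
lattice to the endpoint's lattice.  For a correct metric the trace is zero
at both ends (the two endpoints present the same lattice), is 1-Lipschitz in
the evaluated points (every candidate map is an isometry), and shows at most
occasional slope breaks where the segment crosses a boundary.

Note the Lipschitz bound is phrased against the distance moved by the
*evaluated* points, not the raw segment step: intermediate samples are
Selling-reduced before evaluation, and the reduction shears can move a
representative faster than the raw point (their operator norm exceeds 1),
which is legitimate and not a metric defect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cells import _as_s6
from .distance import Strategy, _DISPATCH
from .reduction import selling_reduce

__all__ = ["FollowerTrace", "FollowerQC", "follower_trace", "follower_qc"]

DEFAULT_N_SAMPLES = 200


@dataclass(frozen=True)
class FollowerTrace:
    """Distances from points along start→reduce(start) to the endpoint."""

    t: np.ndarray  # (n,) in [0, 1], strictly increasing
    points: np.ndarray  # (n, 6) raw segment points
    evaluated: np.ndarray  # (n, 6) points actually passed to the metric
    distances: np.ndarray  # (n,) distance of each sample's lattice to the endpoint
    strategy: str
    start: np.ndarray
    end: np.ndarray  # selling_reduce(start)

    @property
    def step_length(self) -> float:
        """Euclidean length of one sampling step along the raw segment (Å²)."""
        return float(np.linalg.norm(self.end - self.start)) / max(len(self.t) - 1, 1)


@dataclass(frozen=True)
class FollowerQC:
    """Quality-control report for a trace."""

    endpoint_zero: bool
    endpoint_values: tuple[float, float]
    max_jump: float
    max_jump_excess: float  # max over intervals of (jump − Lipschitz allowance)
    continuity_ok: bool
    n_slope_breaks: int

    @property
    def all_ok(self) -> bool:
        return self.endpoint_zero and self.continuity_ok


def follower_trace(
    start,
    n_samples: int = DEFAULT_N_SAMPLES,
    strategy: Strategy = "vcp1",
    reduce_intermediate: bool = True,
) -> FollowerTrace:
    """Scan distances along the segment from ``start`` to its reduced image.

    Each sample point is itself Selling-reduced before the distance to the
    endpoint is evaluated (without this, a multi-step-unreduced start could
    not reach zero at t = 0); set ``reduce_intermediate=False`` to evaluate
    raw segment points instead.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be ≥ 2")
    start = _as_s6(start)
    end = selling_reduce(start).reduced
    t = np.linspace(0.0, 1.0, n_samples)
    points = (1.0 - t)[:, None] * start[None, :] + t[:, None] * end[None, :]
    dist = _DISPATCH[strategy]
    evaluated = np.empty_like(points)
    distances = np.empty(n_samples)
    for i, x in enumerate(points):
        sample = selling_reduce(x).reduced if reduce_intermediate else x
        evaluated[i] = sample
        distances[i] = dist(sample, end).distance
    return FollowerTrace(
        t=t,
        points=points,
        evaluated=evaluated,
        distances=distances,
        strategy=strategy,
        start=start,
        end=end,
    )


def follower_qc(
    trace: FollowerTrace,
    tol: float | None = None,
    lipschitz_slack: float = 1.0001,
) -> FollowerQC:
    """Check endpoint-zeroness, the 1-Lipschitz jump bound and slope breaks.

    ``tol`` defaults to 1e−8 × |start| (absolute floor 1e−8).  The continuity
    check requires every consecutive distance jump to stay within
    ``lipschitz_slack`` × the Euclidean distance between the two evaluated
    points (the candidate maps are isometries, so the metric is 1-Lipschitz
    in each argument).  A slope break is a sign change of the discrete slope.
    With only two samples continuity is vacuously true.
    """
    if tol is None:
        tol = 1e-8 * max(1.0, float(np.linalg.norm(trace.start)))
    d = trace.distances
    endpoint_values = (float(d[0]), float(d[-1]))
    endpoint_zero = endpoint_values[0] <= tol and endpoint_values[1] <= tol
    if len(d) >= 3:
        jumps = np.abs(np.diff(d))
        moved = np.linalg.norm(np.diff(trace.evaluated, axis=0), axis=1)
        allowance = lipschitz_slack * moved + tol
        excess = jumps - allowance
        max_jump = float(jumps.max())
        max_excess = float(excess.max())
        continuity_ok = max_excess <= 0.0
        slopes = np.diff(d)
        signs = np.sign(np.where(np.abs(slopes) <= tol, 0.0, slopes))
        nz = signs[signs != 0.0]
        n_breaks = int(np.sum(nz[1:] != nz[:-1])) if nz.size > 1 else 0
    else:
        max_jump = float(np.abs(np.diff(d)).max()) if len(d) == 2 else 0.0
        max_excess = 0.0
        continuity_ok = True
        n_breaks = 0
    return FollowerQC(
        endpoint_zero=endpoint_zero,
        endpoint_values=endpoint_values,
        max_jump=max_jump,
        max_jump_excess=max_excess,
        continuity_ok=continuity_ok,
        n_slope_breaks=n_breaks,
    )
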