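"""Piecewise integration of the flare-cycle system and therapy scenarios.

Integration proceeds interval by interval: within each therapy interval the
forcing rates (s_i, s_id, s_a) are constant and the solver runs with those
values; at each breakpoint the state is carried over continuously and the
solver is restarted, so a parameter discontinuity never straddles an
adaptive step. Only the parameters jump at a breakpoint, never the state.

Scenario support mirrors the in-silico intervention experiments a
clinician-modeller would run: edit the therapy levels on part of the cycle
(e.g. "keep the maintenance dose from two months before flare") or
override a global rate (e.g. halve the anti-inflammatory decay ``mu_a``),
re-simulate, and compare peak/endpoint/AUC metrics against the unedited
baseline on a common grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    EQUATION_VERSION,
    InvalidParameterError,
    InvalidStateError,
    KineticParameters,
    ScheduleRangeError,
    StateVector,
    TherapyLevels,
    TherapySchedule,
    Trajectory,
    params_at,
    rhs,
)

__all__ = [
    "IntegrationError",
    "TherapyEdit",
    "RateOverride",
    "ScenarioSpec",
    "TrajectoryMetrics",
    "default_grid",
    "simulate",
    "apply_scenario",
    "summarize",
    "run_scenarios",
]

logger = logging.getLogger(__name__)

#: Default output spacing in days.
DEFAULT_GRID_STEP = 0.5

#: Default solver tolerances.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """The ODE solver failed inside a named therapy interval."""


def default_grid(
    schedule: TherapySchedule, step: float = DEFAULT_GRID_STEP
) -> np.ndarray:
    """Output grid: ``step``-day spacing over the schedule span plus all
    breakpoints."""
    t0, t1 = schedule.span
    grid = np.arange(t0, t1 + step / 2, step)
    grid = np.union1d(grid, np.asarray(schedule.breakpoints))
    return grid[(grid >= t0) & (grid <= t1)]


def simulate(
    params: KineticParameters,
    schedule: TherapySchedule,
    state0: StateVector,
    t_grid: Sequence[float] | None = None,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the system under a therapy schedule.

    Parameters
    ----------
    params
        Time-invariant kinetic parameters; the (s_i, s_id, s_a) fields are
        overridden interval by interval from ``schedule``.
    schedule
        Piecewise-constant therapy over the flare cycle.
    state0
        State at the first grid time.
    t_grid
        Strictly increasing output times within the schedule span. Defaults
        to 0.5-day spacing plus all breakpoints. Interior breakpoints are
        always included in the output.
    rtol, atol, method
        Passed to :func:`scipy.integrate.solve_ivp`; the solver restarts at
        every breakpoint.

    Returns
    -------
    Trajectory
        States at every requested grid time and interior breakpoint.
    """
    if t_grid is None:
        grid = default_grid(schedule)
    else:
        grid = np.asarray(t_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 1:
            raise InvalidParameterError("t_grid must be a non-empty 1-D sequence")
        if grid.size > 1 and np.any(np.diff(grid) <= 0):
            raise InvalidParameterError("t_grid must be strictly increasing")
        lo, hi = schedule.span
        if grid[0] < lo or grid[-1] > hi:
            raise ScheduleRangeError(
                f"t_grid [{grid[0]}, {grid[-1]}] outside schedule span [{lo}, {hi}]"
            )

    t_start, t_end = float(grid[0]), float(grid[-1])
    bps = np.asarray(schedule.breakpoints)
    interior = bps[(bps > t_start) & (bps < t_end)]
    out_times = np.union1d(grid, interior)

    y = state0.to_array()
    states = np.empty((out_times.size, 4))
    written = 0
    if out_times[0] == t_start:
        states[0] = y
        written = 1

    # segment boundaries: start, interior breakpoints, end
    seg_edges = np.concatenate(([t_start], interior, [t_end]))
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        if b == a:  # degenerate single-point request
            continue
        # right-open convention: the interval in force on [a, b) is looked
        # up at a (b may be the next interval's start)
        p_seg = params_at(params, schedule, a)
        requested = out_times[(out_times > a) & (out_times <= b)]
        # always integrate through b so the state carries across continuously
        t_eval = requested if requested.size and requested[-1] == b \
            else np.append(requested, b)
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            t_eval=t_eval,
            args=(p_seg,),
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed on interval [{a}, {b}] days "
                f"(schedule interval {schedule.interval_index(a)}): {sol.message}"
            )
        seg_states = np.asarray(sol.y).T
        n = requested.size
        states[written : written + n] = seg_states[:n]
        written += n
        y = seg_states[-1].copy()
    assert written == out_times.size

    # tolerance-level undershoot is numerical, not a model violation
    floor = -10.0 * atol
    if np.any(states < floor):
        worst = states.min()
        raise IntegrationError(
            f"state went negative ({worst:.3e}) beyond integrator tolerance; "
            "model/parameter violation"
        )
    if np.any(states < 0):
        logger.warning(
            "clipping negative undershoot within tolerance (min %.3e) [%s]",
            states.min(), EQUATION_VERSION,
        )
        states = np.clip(states, 0.0, None)

    return Trajectory(out_times, states, params, schedule)


# ---------------------------------------------------------------------------
# scenarios


@dataclass(frozen=True)
class TherapyEdit:
    """Override therapy levels on the part of the cycle from ``t_from`` to
    ``t_until`` (defaults to the end of the schedule). Fields left as None
    keep the underlying interval's value. Edit boundaries that fall inside
    an interval split it, so the edit applies exactly on [t_from, t_until).
    """

    t_from: float
    t_until: float | None = None
    s_i: float | None = None
    s_id: float | None = None
    s_a: float | None = None

    def __post_init__(self) -> None:
        for name in ("s_i", "s_id", "s_a"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise InvalidParameterError(f"edited {name} must be finite and >= 0")


@dataclass(frozen=True)
class RateOverride:
    """Replace one global kinetic rate (e.g. mu_a, mu_p, mu_d, k_ip)."""

    name: str
    value: float

    def __post_init__(self) -> None:
        if self.name not in KineticParameters.field_names():
            raise InvalidParameterError(f"unknown kinetic parameter {self.name!r}")
        if self.name in ("s_i", "s_id", "s_a"):
            raise InvalidParameterError(
                f"{self.name} is therapy-scheduled; use TherapyEdit"
            )
        if not math.isfinite(self.value) or self.value < 0:
            raise InvalidParameterError("override value must be finite and >= 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named intervention: schedule edits plus global rate overrides."""

    label: str
    edits: tuple = ()

    def therapy_edits(self) -> tuple[TherapyEdit, ...]:
        return tuple(e for e in self.edits if isinstance(e, TherapyEdit))

    def rate_overrides(self) -> tuple[RateOverride, ...]:
        return tuple(e for e in self.edits if isinstance(e, RateOverride))


def _split_at(schedule: TherapySchedule, t: float) -> TherapySchedule:
    """Insert a breakpoint at ``t`` (no-op if already present)."""
    bp = schedule.breakpoints
    if t in bp:
        return schedule
    lo, hi = schedule.span
    if not (lo < t < hi):
        raise InvalidParameterError(f"edit time {t} outside schedule span [{lo}, {hi}]")
    idx = schedule.interval_index(t)
    new_bp = tuple(sorted(bp + (float(t),)))
    new_iv = (
        schedule.intervals[: idx + 1]
        + (schedule.intervals[idx],)
        + schedule.intervals[idx + 1 :]
    )
    return TherapySchedule(new_bp, new_iv)


def apply_scenario(
    schedule: TherapySchedule,
    params: KineticParameters,
    scenario: ScenarioSpec,
) -> tuple[TherapySchedule, KineticParameters]:
    """Return edited copies of the schedule and parameters.

    The inputs are never mutated; an empty edit list returns the inputs
    unchanged.
    """
    sched = schedule
    for edit in scenario.therapy_edits():
        t_until = schedule.span[1] if edit.t_until is None else edit.t_until
        if t_until <= edit.t_from:
            raise InvalidParameterError(
                f"edit range [{edit.t_from}, {t_until}] is empty"
            )
        sched = _split_at(sched, edit.t_from)
        if t_until < sched.span[1]:
            sched = _split_at(sched, t_until)
        changes = {
            k: v
            for k, v in (("s_i", edit.s_i), ("s_id", edit.s_id), ("s_a", edit.s_a))
            if v is not None
        }
        first = sched.interval_index(edit.t_from)
        last = (
            sched.n_intervals - 1
            if t_until >= sched.span[1]
            else sched.interval_index(t_until) - 1
        )
        for i in range(first, last + 1):
            sched = sched.with_interval(i, **changes)
    pars = params
    for ov in scenario.rate_overrides():
        pars = pars.replace(**{ov.name: ov.value})
    return sched, pars


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class TrajectoryMetrics:
    """Comparable summary of one simulated flare cycle."""

    peak_P: float
    t_peak_P: float
    peak_D: float
    t_peak_D: float
    P_at_flare: float
    D_at_flare: float
    P_end: float
    D_end: float
    auc_P: float  # trapezoid area of (P - baseline_P) over the grid
    auc_D: float


def summarize(
    trajectory: Trajectory,
    baseline_P: float | None = None,
    baseline_D: float | None = None,
    flare_time: float = 0.0,
) -> TrajectoryMetrics:
    """Peak, flare-time, endpoint and area-over-baseline metrics.

    Baselines default to the trajectory's initial P and D values. The areas
    are signed trapezoid integrals of the excursion above baseline.
    """
    t = trajectory.times
    if t.size == 0:
        raise InvalidStateError("empty trajectory")
    P, D = trajectory.P, trajectory.D
    bP = float(P[0]) if baseline_P is None else float(baseline_P)
    bD = float(D[0]) if baseline_D is None else float(baseline_D)
    iP, iD = int(np.argmax(P)), int(np.argmax(D))
    if t[0] <= flare_time <= t[-1]:
        P_fl = float(np.interp(flare_time, t, P))
        D_fl = float(np.interp(flare_time, t, D))
    else:
        P_fl = D_fl = float("nan")
    if t.size > 1:
        auc_P = float(np.trapezoid(P - bP, t))
        auc_D = float(np.trapezoid(D - bD, t))
    else:
        auc_P = auc_D = 0.0
    return TrajectoryMetrics(
        peak_P=float(P[iP]),
        t_peak_P=float(t[iP]),
        peak_D=float(D[iD]),
        t_peak_D=float(t[iD]),
        P_at_flare=P_fl,
        D_at_flare=D_fl,
        P_end=float(P[-1]),
        D_end=float(D[-1]),
        auc_P=auc_P,
        auc_D=auc_D,
    )


def run_scenarios(
    params: KineticParameters,
    schedule: TherapySchedule,
    state0: StateVector,
    scenarios: Iterable[ScenarioSpec],
    t_grid: Sequence[float] | None = None,
    *,
    baseline_P: float | None = None,
    baseline_D: float | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> dict[str, tuple[Trajectory, TrajectoryMetrics]]:
    """Simulate the unedited baseline plus each scenario on a common grid.

    Returns an ordered mapping label -> (trajectory, metrics); the entry
    ``"baseline"`` is always present and first.
    """
    grid = default_grid(schedule) if t_grid is None else np.asarray(t_grid, float)
    results: dict[str, tuple[Trajectory, TrajectoryMetrics]] = {}
    base_traj = simulate(params, schedule, state0, grid, rtol=rtol, atol=atol)
    results["baseline"] = (
        base_traj,
        summarize(base_traj, baseline_P, baseline_D),
    )
    for sc in scenarios:
        if sc.label == "baseline":
            raise InvalidParameterError('scenario label "baseline" is reserved')
        ed_sched, ed_params = apply_scenario(schedule, params, sc)
        traj = simulate(ed_params, ed_sched, state0, grid, rtol=rtol, atol=atol)
        results[sc.label] = (traj, summarize(traj, baseline_P, baseline_D))
    return results
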