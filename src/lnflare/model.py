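"""Core model of lupus nephritis flare dynamics.

The model tracks four lumped quantities over a renal flare cycle:

* ``I`` — immune complexes deposited in the kidney,
* ``P`` — pro-inflammatory mediators (surrogate: urine MCP-1),
* ``D`` — damaged tissue (surrogate: urine protein:creatinine ratio),
* ``A`` — anti-inflammatory mediators, endogenous plus therapeutic.

Production terms are inhibited by the anti-inflammatory state through a
shared factor ``x / (1 + (A/A_inf)^2)``, and the damage-driven induction of
new immune complexes follows second-order Hill kinetics. Therapy enters as
piecewise-constant values of the source rates ``s_i`` (immune-complex
deposition), ``s_id`` (intrarenal induction saturation) and ``s_a``
(anti-inflammatory input) over intervals of the flare cycle, with the flare
at t = 0 days.

The right-hand side implemented by :func:`rhs` is

    dI/dt = f(s_i) + f(s_id) * D^2/(k_id^2 + D^2) - k_ip * I * P
    dP/dt = f(k_pi*I + k_pp*P + k_pd*D) - mu_p * P
    dD/dt = f(k_dip*I*P + k_dp*P) - mu_d * D
    dA/dt = s_a + k_ap*P + k_ad*D - mu_a * A

with ``f(x) = x / (1 + (A/A_inf)^2)`` applied once per production group.
The algebraic form is kept behind this single function so an alternative
reading of the interaction network can be swapped in; outputs are tagged
with :data:`EQUATION_VERSION` for traceability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EQUATION_VERSION",
    "InvalidParameterError",
    "InvalidStateError",
    "ScheduleRangeError",
    "StateVector",
    "KineticParameters",
    "TherapyLevels",
    "TherapySchedule",
    "Trajectory",
    "inhibition",
    "hill2",
    "rhs",
    "params_at",
    "DEFAULT_BREAKPOINTS",
]

#: Version tag of the reconstructed equation set, recorded in outputs.
EQUATION_VERSION = "lnflare-rhs-v1"

#: Default flare-cycle breakpoints in days (flare at t = 0): 6, 4, 2 months
#: and 2 weeks before flare, then 2 weeks, 6 weeks, 2 and 4 months after,
#: with 1 month = 30 days and 1 week = 7 days.
DEFAULT_BREAKPOINTS = (-180.0, -120.0, -60.0, -14.0, 0.0, 14.0, 42.0, 60.0, 120.0)


class InvalidParameterError(ValueError):
    """A kinetic or schedule parameter violates its constraints."""


class InvalidStateError(ValueError):
    """A model state is negative or non-finite."""


class ScheduleRangeError(ValueError):
    """A time falls outside the therapy schedule's span."""


def _check_finite_nonneg(name: str, value: float, exc: type[ValueError]) -> None:
    if not math.isfinite(value):
        raise exc(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise exc(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class StateVector:
    """Model state at one time point, in the model's generic units."""

    I: float
    P: float
    D: float
    A: float

    def __post_init__(self) -> None:
        for name in ("I", "P", "D", "A"):
            _check_finite_nonneg(name, getattr(self, name), InvalidStateError)

    def to_array(self) -> np.ndarray:
        return np.array([self.I, self.P, self.D, self.A], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "StateVector":
        I, P, D, A = (float(v) for v in y)
        return cls(I=I, P=P, D=D, A=A)


@dataclass(frozen=True)
class KineticParameters:
    """All rate and saturation constants of the four-variable system.

    Rates are per day; coupling constants carry the implied generic-unit
    ratios (e.g. ``k_pi`` is P-units per I-unit per day). ``s_i``, ``s_id``
    and ``s_a`` hold the values of the *current* therapy interval; the
    time-dependence lives in :class:`TherapySchedule`.
    """

    s_i: float       # immune-complex deposition rate
    s_id: float      # saturation of damage-driven immune-complex induction
    k_id: float      # Hill half-saturation constant (D-units)
    k_ip: float      # immune-complex removal by pro-inflammatory cells
    k_pi: float      # activation of P by I
    k_pp: float      # self-amplification of P
    k_pd: float      # activation of P by D
    mu_p: float      # decay of P
    k_dip: float     # damage from phagocytosis of immune complexes
    k_dp: float      # collateral damage from P
    mu_d: float      # damage resolution
    s_a: float       # anti-inflammatory source (therapy)
    k_ap: float      # A production induced by P
    k_ad: float      # A production induced by D
    mu_a: float      # decay of A
    A_inf: float     # inhibition scale constant (A-units)

    def __post_init__(self) -> None:
        for f_ in fields(self):
            _check_finite_nonneg(f_.name, getattr(self, f_.name), InvalidParameterError)
        for name in ("mu_a", "mu_p", "mu_d"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0 (dissipative decay)")
        if self.k_id <= 0:
            raise InvalidParameterError("k_id must be > 0")
        if self.A_inf <= 0:
            raise InvalidParameterError("A_inf must be > 0")

    def replace(self, **changes: float) -> "KineticParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f_.name: getattr(self, f_.name) for f_ in fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f_.name for f_ in fields(cls))


@dataclass(frozen=True)
class TherapyLevels:
    """The three therapy-controlled rates on one schedule interval."""

    s_i: float
    s_id: float
    s_a: float

    def __post_init__(self) -> None:
        for name in ("s_i", "s_id", "s_a"):
            _check_finite_nonneg(name, getattr(self, name), InvalidParameterError)


@dataclass(frozen=True)
class TherapySchedule:
    """Piecewise-constant therapy over the flare cycle.

    ``breakpoints`` are strictly increasing times in days (flare at 0);
    interval k covers ``[breakpoints[k], breakpoints[k+1])``, right-open so
    a lookup exactly at an interior breakpoint takes the *following*
    interval's values. The final breakpoint is attributed to the last
    interval so the full closed span is covered.
    """

    breakpoints: tuple[float, ...]
    intervals: tuple[TherapyLevels, ...]

    def __post_init__(self) -> None:
        bp = tuple(float(t) for t in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        iv = tuple(
            lv if isinstance(lv, TherapyLevels) else TherapyLevels(*lv)
            for lv in self.intervals
        )
        object.__setattr__(self, "intervals", iv)
        if len(bp) < 2:
            raise InvalidParameterError("schedule needs at least two breakpoints")
        if any(not math.isfinite(t) for t in bp):
            raise InvalidParameterError("breakpoints must be finite")
        if any(b - a <= 0 for a, b in zip(bp, bp[1:])):
            raise InvalidParameterError("breakpoints must be strictly increasing")
        if len(iv) != len(bp) - 1:
            raise InvalidParameterError(
                f"{len(bp)} breakpoints require {len(bp) - 1} intervals, got {len(iv)}"
            )

    @property
    def span(self) -> tuple[float, float]:
        return self.breakpoints[0], self.breakpoints[-1]

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def interval_index(self, t: float) -> int:
        """Index of the interval containing time ``t`` (right-open lookup)."""
        t0, t1 = self.span
        if not (t0 <= t <= t1):
            raise ScheduleRangeError(
                f"t={t} outside schedule span [{t0}, {t1}]"
            )
        if t == t1:
            return self.n_intervals - 1
        idx = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return idx

    def levels_at(self, t: float) -> TherapyLevels:
        return self.intervals[self.interval_index(t)]

    def with_interval(self, index: int, **changes: float) -> "TherapySchedule":
        """Copy with one interval's levels partially replaced."""
        if not (0 <= index < self.n_intervals):
            raise InvalidParameterError(
                f"interval index {index} out of range 0..{self.n_intervals - 1}"
            )
        new = list(self.intervals)
        new[index] = replace(new[index], **changes)
        return TherapySchedule(self.breakpoints, tuple(new))


@dataclass(frozen=True)
class Trajectory:
    """Solution of the system on an output grid."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 4), columns I, P, D, A
    params_used: KineticParameters
    schedule_used: TherapySchedule

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)
        if t.ndim != 1 or y.shape != (t.size, 4):
            raise InvalidStateError("states must have shape (len(times), 4)")
        if t.size and np.any(np.diff(t) <= 0):
            raise InvalidStateError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise InvalidStateError("trajectory states must be finite and >= 0")

    @property
    def I(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def P(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def D(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def A(self) -> np.ndarray:
        return self.states[:, 3]

    def at(self, t: float) -> StateVector:
        """State at grid time ``t`` (must be an output grid point)."""
        idx = np.searchsorted(self.times, t)
        if idx == self.times.size or not np.isclose(self.times[idx], t):
            raise KeyError(f"t={t} is not on the output grid")
        return StateVector.from_array(self.states[idx])

    def sample(self, times: Iterable[float]) -> np.ndarray:
        """Linear interpolation of all four states at arbitrary times."""
        ts = np.asarray(list(times), dtype=float)
        if ts.size and (ts.min() < self.times[0] or ts.max() > self.times[-1]):
            raise ScheduleRangeError("sample times outside trajectory span")
        return np.column_stack(
            [np.interp(ts, self.times, self.states[:, j]) for j in range(4)]
        )


def inhibition(x, A, A_inf):
    """Anti-inflammatory inhibition of a production rate.

    Returns ``x / (1 + (A/A_inf)**2)``: equal to ``x`` when A = 0, halved
    when A = A_inf, and vanishing as A grows. Accepts scalars or arrays.
    """
    A = np.asarray(A, dtype=float)
    if np.any(~np.isfinite(A)) or np.any(A < 0):
        raise InvalidStateError("A must be finite and >= 0")
    if not np.isscalar(A_inf) or A_inf <= 0:
        raise InvalidParameterError("A_inf must be a positive scalar")
    out = np.asarray(x, dtype=float) / (1.0 + (A / A_inf) ** 2)
    return out if out.ndim else float(out)


def hill2(D, k_id):
    """Second-order Hill response ``D^2 / (k_id^2 + D^2)``.

    Sigmoidal in D, bounded in [0, 1): little induction while debris is
    scarce, approaching saturation once D well exceeds ``k_id``.
    """
    if not np.isscalar(k_id) or k_id <= 0:
        raise InvalidParameterError("k_id must be a positive scalar")
    D = np.asarray(D, dtype=float)
    out = D**2 / (k_id**2 + D**2)
    return out if out.ndim else float(out)


def rhs(t: float, state, params: KineticParameters) -> np.ndarray:
    """Time derivatives (dI/dt, dP/dt, dD/dt, dA/dt) at state ``state``.

    ``state`` may be a :class:`StateVector` or any length-4 array-like
    (I, P, D, A). ``t`` is accepted for ODE-solver compatibility; the
    system is autonomous within one therapy interval.
    """
    if isinstance(state, StateVector):
        I, P, D, A = state.I, state.P, state.D, state.A
    else:
        I, P, D, A = (float(v) for v in state)
    if not all(map(math.isfinite, (I, P, D, A))):
        raise InvalidStateError(f"non-finite state {(I, P, D, A)}")
    p = params
    inhib = 1.0 / (1.0 + (A / p.A_inf) ** 2)
    hl = D * D / (p.k_id * p.k_id + D * D)
    dI = (p.s_i + p.s_id * hl) * inhib - p.k_ip * I * P
    dP = (p.k_pi * I + p.k_pp * P + p.k_pd * D) * inhib - p.mu_p * P
    dD = (p.k_dip * I * P + p.k_dp * P) * inhib - p.mu_d * D
    dA = p.s_a + p.k_ap * P + p.k_ad * D - p.mu_a * A
    return np.array([dI, dP, dD, dA])


def params_at(
    base: KineticParameters, schedule: TherapySchedule, t: float
) -> KineticParameters:
    """Kinetic parameters in force at time ``t`` under ``schedule``.

    Replaces (s_i, s_id, s_a) of ``base`` with the levels of the schedule
    interval containing ``t``; all other rates are time-invariant.
    """
    lv = schedule.levels_at(t)
    return base.replace(s_i=lv.s_i, s_id=lv.s_id, s_a=lv.s_a)
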