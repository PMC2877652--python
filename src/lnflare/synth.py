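"""Virtual-patient biomarker series generator.

Emulates the sampling design of the longitudinal cohort the model was
built around: roughly bimonthly clinic visits spanning six months before
to four months after a renal flare at t = 0, with urine MCP-1 tracking the
pro-inflammatory state P and the urine protein:creatinine ratio tracking
the damage state D. Observation noise is multiplicative lognormal —
both biomarkers are nonnegative concentration-like quantities, so a
constant coefficient of variation is the natural error model:

    obs = truth * exp(eps),   eps ~ Normal(0, sigma^2) i.i.d.

Each generated patient returns both the noisy series and the clean truth
trajectory so parameter-recovery studies have their oracle built in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .calibrate import PatientSeries
from .model import (
    InvalidParameterError,
    KineticParameters,
    StateVector,
    TherapySchedule,
    Trajectory,
)
from .simulate import simulate

__all__ = [
    "DEFAULT_SAMPLING_DAYS",
    "SyntheticPatientConfig",
    "generate_patient",
    "generate_cohort",
]

#: Bimonthly visit grid over the 10-month flare cycle (days, flare at 0).
DEFAULT_SAMPLING_DAYS = (-180.0, -120.0, -60.0, 0.0, 60.0, 120.0)

#: Default multiplicative noise standard deviation (log scale).
DEFAULT_SIGMA = 0.15


@dataclass(frozen=True)
class SyntheticPatientConfig:
    """Truth model plus sampling design for one virtual patient."""

    params: KineticParameters
    schedule: TherapySchedule
    state0: StateVector
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_DAYS
    sigma_P: float = DEFAULT_SIGMA
    sigma_D: float = DEFAULT_SIGMA
    missing_prob: float = 0.0
    seed: int = 0
    patient_id: str = "synthetic"

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.sampling_times)
        object.__setattr__(self, "sampling_times", ts)
        if len(ts) < 1 or any(b - a <= 0 for a, b in zip(ts, ts[1:])):
            raise InvalidParameterError("sampling_times must be strictly increasing")
        lo, hi = self.schedule.span
        if ts[0] < lo or ts[-1] > hi:
            raise InvalidParameterError("sampling_times outside schedule span")
        if self.sigma_P < 0 or self.sigma_D < 0:
            raise InvalidParameterError("noise sigma must be >= 0")
        if not (0.0 <= self.missing_prob < 1.0):
            raise InvalidParameterError("missing_prob must be in [0, 1)")


def generate_patient(
    config: SyntheticPatientConfig,
) -> tuple[PatientSeries, Trajectory]:
    """Simulate the truth model and sample a noisy biomarker series.

    Returns ``(series, truth)``: the series holds noisy uMCP-1 (from P)
    and uP:C (from D) at the visit times with baselines set to the truth
    values at the schedule start; the truth trajectory covers the sampled
    span for use as a test oracle.
    """
    ts = np.asarray(config.sampling_times)
    lo = config.schedule.span[0]
    grid = np.union1d(ts, [lo]) if ts[0] > lo else ts
    truth = simulate(config.params, config.schedule, config.state0, grid)
    sampled = truth.sample(ts)
    P_true, D_true = sampled[:, 1], sampled[:, 2]

    rng = np.random.default_rng(config.seed)
    ump1 = P_true * np.exp(rng.normal(0.0, config.sigma_P, ts.size))
    upc = D_true * np.exp(rng.normal(0.0, config.sigma_D, ts.size))
    if config.missing_prob > 0:
        ump1 = np.where(rng.random(ts.size) < config.missing_prob, np.nan, ump1)
        upc = np.where(rng.random(ts.size) < config.missing_prob, np.nan, upc)

    start = truth.sample([lo])[0]
    series = PatientSeries(
        patient_id=config.patient_id,
        obs_times=ts,
        ump1=ump1,
        upc=upc,
        baseline_P=float(start[1]),
        baseline_D=float(start[2]),
    )
    return series, truth


def generate_cohort(
    n: int,
    base: SyntheticPatientConfig,
    jitter: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[tuple[PatientSeries, SyntheticPatientConfig]]:
    """Generate ``n`` virtual patients around a shared truth model.

    ``jitter`` maps kinetic-parameter names to lognormal standard
    deviations (log scale): each patient's value is the base value times
    ``exp(Normal(0, sd^2))``. Per-patient noise sub-seeds derive
    deterministically from ``seed``, so a cohort is reproducible. Each
    element pairs the noisy series with the patient's own (jittered) truth
    configuration.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    jitter = dict(jitter or {})
    for name, sd in jitter.items():
        if name not in KineticParameters.field_names():
            raise InvalidParameterError(f"unknown jitter parameter {name!r}")
        if not (sd >= 0 and np.isfinite(sd)):
            raise InvalidParameterError(f"jitter sd for {name} must be >= 0")

    master = np.random.default_rng(seed)
    out = []
    for i in range(n):
        sub_seed = int(master.integers(0, 2**31 - 1))
        factors = {
            name: float(np.exp(master.normal(0.0, sd))) for name, sd in jitter.items()
        }
        params_i = base.params.replace(
            **{k: getattr(base.params, k) * f for k, f in factors.items()}
        )
        cfg_i = replace(
            base,
            params=params_i,
            seed=sub_seed,
            patient_id=f"{base.patient_id}-{i:03d}",
        )
        series, _ = generate_patient(cfg_i)
        out.append((series, cfg_i))
    return out
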