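"""Readers, writers and the bundled patient fixtures.

File dialects
-------------
* Patient series: comma-separated, dot-decimal CSV with header
  ``t_days,ump1,upc``; optional metadata as leading ``# key: value``
  comment lines (patient_id, baseline_P, baseline_D). Blank cells are
  missing observations.
* Parameters / schedules / scenarios: YAML. Parameters are one key per
  rate symbol; a schedule is a list of
  ``{t_start_days, t_end_days, s_i, s_id, s_a}`` rows.
* Four bundled fixtures (patients 416, 444, 448, 491) carry the published
  calibrated parameter sets and therapy schedules for the 10-month flare
  cycle.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .calibrate import FitResult, PatientSeries
from .model import (
    EQUATION_VERSION,
    InvalidParameterError,
    KineticParameters,
    StateVector,
    TherapyLevels,
    TherapySchedule,
    Trajectory,
)
from .simulate import RateOverride, ScenarioSpec, TherapyEdit

__all__ = [
    "FIXTURE_IDS",
    "load_fixture",
    "read_patient_series",
    "write_patient_series",
    "read_params",
    "write_params",
    "read_schedule",
    "write_schedule",
    "read_scenarios",
    "write_trajectory",
    "write_fit_report",
]

FIXTURE_IDS = ("416", "444", "448", "491")


class SeriesParseError(ValueError):
    """A patient-series file failed validation; the message names the line."""


# ---------------------------------------------------------------------------
# fixtures


def load_fixture(
    patient_id: str | int,
) -> tuple[KineticParameters, TherapySchedule, StateVector]:
    """Published calibrated model for one of the four study patients.

    Returns (parameters, therapy schedule, initial state). The parameter
    object's (s_i, s_id, s_a) hold the first interval's levels; the
    schedule supplies the full piecewise-constant therapy.
    """
    pid = str(patient_id)
    if pid not in FIXTURE_IDS:
        raise KeyError(f"unknown fixture {pid!r}; available: {FIXTURE_IDS}")
    ref = resources.files("lnflare").joinpath(f"fixtures/patient_{pid}.yaml")
    doc = yaml.safe_load(ref.read_text())
    params = KineticParameters(**doc["parameters"])
    schedule = _schedule_from_rows(doc["schedule"])
    state0 = StateVector(**doc["state0"])
    return params, schedule, state0


# ---------------------------------------------------------------------------
# patient series CSV


def read_patient_series(path: str | Path) -> PatientSeries:
    """Read a biomarker series CSV (header ``t_days,ump1,upc``).

    Leading ``# key: value`` comments may set patient_id, baseline_P and
    baseline_D. Raises :class:`SeriesParseError` naming the offending line
    for malformed headers, non-monotone times or negative values.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    if body_start >= len(lines):
        raise SeriesParseError(f"{path}: no data rows")
    header = [c.strip() for c in lines[body_start].split(",")]
    if header[:3] != ["t_days", "ump1", "upc"]:
        raise SeriesParseError(
            f"{path}, line {body_start + 1}: expected header 't_days,ump1,upc', "
            f"got {lines[body_start].strip()!r}"
        )
    df = pd.read_csv(path, comment="#")
    t = df["t_days"].to_numpy(float)
    p = df["ump1"].to_numpy(float)
    d = df["upc"].to_numpy(float)
    if t.size and np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 1
        raise SeriesParseError(
            f"{path}, data row {bad + 1}: t_days not strictly increasing"
        )
    for col, arr in (("ump1", p), ("upc", d)):
        neg = np.where(arr < 0)[0]
        if neg.size:
            raise SeriesParseError(
                f"{path}, data row {int(neg[0]) + 1}: negative {col} value"
            )
    def _fmeta(key):
        return float(meta[key]) if key in meta else None
    return PatientSeries(
        patient_id=meta.get("patient_id", path.stem),
        obs_times=t,
        ump1=p,
        upc=d,
        baseline_P=_fmeta("baseline_P"),
        baseline_D=_fmeta("baseline_D"),
    )


def write_patient_series(series: PatientSeries, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# patient_id: {series.patient_id}\n")
        if series.baseline_P is not None:
            fh.write(f"# baseline_P: {series.baseline_P!r}\n")
        if series.baseline_D is not None:
            fh.write(f"# baseline_D: {series.baseline_D!r}\n")
        fh.write("t_days,ump1,upc\n")
        for t, p, d in zip(series.obs_times, series.ump1, series.upc):
            ps = "" if math.isnan(p) else repr(float(p))
            ds = "" if math.isnan(d) else repr(float(d))
            fh.write(f"{float(t)!r},{ps},{ds}\n")


# ---------------------------------------------------------------------------
# params / schedule YAML


def read_params(path: str | Path) -> KineticParameters:
    doc = yaml.safe_load(Path(path).read_text())
    return KineticParameters(**doc)


def write_params(params: KineticParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def _schedule_from_rows(rows: Iterable[Mapping]) -> TherapySchedule:
    rows = list(rows)
    if not rows:
        raise InvalidParameterError("schedule has no intervals")
    bps = [float(rows[0]["t_start_days"])]
    levels = []
    for row in rows:
        if float(row["t_start_days"]) != bps[-1]:
            raise InvalidParameterError(
                "schedule rows must tile the span contiguously"
            )
        bps.append(float(row["t_end_days"]))
        levels.append(
            TherapyLevels(float(row["s_i"]), float(row["s_id"]), float(row["s_a"]))
        )
    return TherapySchedule(tuple(bps), tuple(levels))


def _schedule_to_rows(schedule: TherapySchedule) -> list[dict]:
    return [
        dict(t_start_days=a, t_end_days=b, s_i=lv.s_i, s_id=lv.s_id, s_a=lv.s_a)
        for a, b, lv in zip(
            schedule.breakpoints, schedule.breakpoints[1:], schedule.intervals
        )
    ]


def read_schedule(path: str | Path) -> TherapySchedule:
    return _schedule_from_rows(yaml.safe_load(Path(path).read_text()))


def write_schedule(schedule: TherapySchedule, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(_schedule_to_rows(schedule), sort_keys=False)
    )


def read_scenarios(path: str | Path) -> list[ScenarioSpec]:
    """Scenario YAML: a list of ``{label, edits: [...]}`` where each edit is
    either ``{t_from, t_until?, s_i?, s_id?, s_a?}`` (therapy edit) or
    ``{rate, value}`` (global rate override)."""
    doc = yaml.safe_load(Path(path).read_text())
    scenarios = []
    for entry in doc:
        edits: list = []
        for e in entry.get("edits", []):
            if "rate" in e:
                edits.append(RateOverride(e["rate"], float(e["value"])))
            else:
                edits.append(
                    TherapyEdit(
                        t_from=float(e["t_from"]),
                        t_until=(
                            float(e["t_until"]) if e.get("t_until") is not None
                            else None
                        ),
                        s_i=(float(e["s_i"]) if "s_i" in e else None),
                        s_id=(float(e["s_id"]) if "s_id" in e else None),
                        s_a=(float(e["s_a"]) if "s_a" in e else None),
                    )
                )
        scenarios.append(ScenarioSpec(label=str(entry["label"]), edits=tuple(edits)))
    return scenarios


# ---------------------------------------------------------------------------
# outputs


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Trajectory CSV with columns (t_days, I, P, D, A), tagged with the
    equation-form version for traceability."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# equation_form: {EQUATION_VERSION}\n")
        df = pd.DataFrame(
            dict(
                t_days=trajectory.times,
                I=trajectory.I,
                P=trajectory.P,
                D=trajectory.D,
                A=trajectory.A,
            )
        )
        df.to_csv(fh, index=False)


def read_trajectory_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_fit_report(result: FitResult, path: str | Path) -> None:
    """Fit report YAML: fitted values, SSR and the per-start table."""
    doc = dict(
        equation_form=EQUATION_VERSION,
        ssr=float(result.ssr),
        free_parameters=list(result.free_names),
        best_values={k: float(v) for k, v in result.best_values.items()},
        parameters=result.params.to_dict(),
        schedule=_schedule_to_rows(result.schedule),
        starts=[
            dict(
                x0=[float(v) for v in s["x0"]],
                x=([float(v) for v in s["x"]] if s["x"] is not None else None),
                ssr=(float(s["ssr"]) if np.isfinite(s["ssr"]) else None),
                success=bool(s["success"]),
                message=str(s["message"]),
            )
            for s in result.starts
        ],
    )
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
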