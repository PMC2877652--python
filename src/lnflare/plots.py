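"""Two-panel flare-cycle plots (requires matplotlib, an optional extra)."""

from __future__ import annotations

from .calibrate import PatientSeries
from .model import Trajectory

__all__ = ["plot_flare_cycle"]


def plot_flare_cycle(
    trajectory: Trajectory,
    series: PatientSeries | None = None,
    label: str | None = None,
    axes=None,
):
    """Plot P (top) and D (bottom) over the cycle, with the flare marked.

    Optionally overlays an observed biomarker series (squares) and its
    baselines (dotted). Returns the two axes; pass them back in to overlay
    another trajectory (e.g. an intervention scenario, dashed).
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
        style = {}
    else:
        style = {"linestyle": "--"}
    (ax_p, ax_d) = axes
    ax_p.plot(trajectory.times, trajectory.P, label=label, **style)
    ax_d.plot(trajectory.times, trajectory.D, label=label, **style)
    if series is not None:
        ax_p.plot(series.obs_times, series.ump1, "s:", color="k", ms=5)
        ax_d.plot(series.obs_times, series.upc, "s:", color="k", ms=5)
        if series.baseline_P is not None:
            ax_p.axhline(series.baseline_P, ls=":", color="gray")
        if series.baseline_D is not None:
            ax_d.axhline(series.baseline_D, ls=":", color="gray")
    for ax in axes:
        ax.axvline(0.0, color="0.7")
    ax_p.set_ylabel("P (uMCP-1 surrogate)")
    ax_d.set_ylabel("D (uP:C surrogate)")
    ax_d.set_xlabel("days from flare")
    if label:
        ax_p.legend(frameon=False)
    return axes
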