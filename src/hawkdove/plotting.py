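"""Plotting conveniences for trajectories and sweep summaries."""

from __future__ import annotations

from .engine import TimeSeries
from .game import GameParams, ess_hawk_frequency

__all__ = ["plot_time_series", "plot_sweep_summary"]


def plot_time_series(series: TimeSeries, ax=None, show_prediction=True):
    """Hawk frequency over time, with the analytic b/c line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = series.dataframe
    ax.plot(df["step"], df["hawk_frequency"], lw=1)
    if show_prediction and series.config is not None:
        bc = ess_hawk_frequency(
            GameParams(series.config.b, series.config.c)
        )
        ax.axhline(bc, ls="--", color="grey", label=f"b/c = {bc:.2f}")
        ax.legend()
    ax.set_xlabel("time step")
    ax.set_ylabel("hawk frequency")
    ax.set_ylim(0, 1)
    return ax


def plot_sweep_summary(summary, x: str, ax=None, hue: str | None = None):
    """Mean equilibrium hawk frequency vs a swept parameter.

    ``summary`` is the aggregate table from
    :func:`hawkdove.experiments.summarize_sweep`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if hue is None:
        ax.errorbar(
            summary[x], summary["mean_p_hat"], yerr=summary["sd_p_hat"],
            marker="o",
        )
    else:
        for key, grp in summary.groupby(hue):
            ax.errorbar(
                grp[x], grp["mean_p_hat"], yerr=grp["sd_p_hat"],
                marker="o", label=f"{hue}={key}",
            )
        ax.legend()
    ax.set_xlabel(x)
    ax.set_ylabel("equilibrium hawk frequency")
    ax.set_ylim(0, 1)
    return ax
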