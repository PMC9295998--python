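"""Basic timeline plots (mass, protein fractions, growth, fluxes)."""

from __future__ import annotations

import matplotlib.pyplot as plt

from .dynamics import Timeline

__all__ = ["plot_timeline"]


def plot_timeline(timeline: Timeline, normalise_by_glucose: bool = True):
    """Four-panel overview of a lifespan simulation.

    Panels: cell mass with division marks; intact/damaged protein
    fractions; growth rate; exchange fluxes (optionally normalised by
    the glucose uptake rate, production positive, uptake negative).
    Returns the matplotlib figure.
    """
    df = timeline.to_dataframe()
    fig, axes = plt.subplots(4, 1, sharex=True, figsize=(7, 9))

    axes[0].plot(df["t"], df["M"], lw=0.8)
    for event in timeline.events:
        if event["kind"] == "division":
            axes[0].axvline(event["t"], color="0.85", lw=0.5, zorder=0)
    axes[0].set_ylabel("mass [gDW]")

    axes[1].plot(df["t"], df["P"], label="intact P")
    axes[1].plot(df["t"], df["D"], label="damaged D")
    axes[1].set_ylabel("fraction [g/gDW]")
    axes[1].legend(frameon=False, fontsize=8)

    axes[2].plot(df["t"], df["g"])
    axes[2].set_ylabel("growth rate [1/h]")

    norm = df["glucose_uptake"].where(df["glucose_uptake"] > 1e-12, 1.0) \
        if normalise_by_glucose else 1.0
    for role, sign in (("glucose_uptake", -1), ("ethanol_exchange", 1),
                       ("o2_uptake", -1), ("co2_exchange", 1),
                       ("acetate_exchange", 1)):
        if role in df:
            axes[3].plot(df["t"], sign * df[role] / norm,
                         label=role.replace("_", " "), lw=0.9)
    axes[3].axhline(0.0, color="0.8", lw=0.5)
    axes[3].set_ylabel("exchange flux" +
                       (" / glc uptake" if normalise_by_glucose else ""))
    axes[3].set_xlabel("time [h]")
    axes[3].legend(frameon=False, fontsize=7, ncol=2)

    for event in timeline.events:
        if event["kind"] == "death":
            for ax in axes:
                ax.axvline(event["t"], color="firebrick", lw=0.8, ls="--")
    fig.tight_layout()
    return fig
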