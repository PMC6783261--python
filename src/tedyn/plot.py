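"""Plotting helpers (requires matplotlib, installed via the 'plot' extra)."""

from __future__ import annotations

from typing import Optional, Sequence

from .engine import Trajectory

__all__ = ["plot_trajectories"]


def plot_trajectories(trajectories: Sequence[Trajectory], ax=None,
                      color: str = "C0", label: Optional[str] = None,
                      show_modifier: bool = False):
    """Plot replicate mean-load (or modifier-frequency) time series.

    Each replicate is a dotted line, mirroring how replicate simulations of
    TE load decline are usually displayed; pass two trajectory sets with
    different colors to contrast sexual and asexual scenarios.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    attr = "modifier_freq" if show_modifier else "mean_load"
    for i, t in enumerate(trajectories):
        ax.plot(t.sampled_generations, getattr(t, attr), ls=":", color=color,
                label=label if i == 0 else None)
    ax.set_xlabel("generation")
    ax.set_ylabel("modifier frequency" if show_modifier
                  else "mean TE copies per individual")
    if label:
        ax.legend()
    return ax
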