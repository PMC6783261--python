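"""Headline summaries of simulation trajectories.

Turns per-replicate load time series into the quantities of interest: the
linear-model estimate of average TE loss per 1000 generations, and the
generation at which the excision-rate modifier reaches fixation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .engine import Trajectory

__all__ = ["LossEstimate", "fit_loss_regression", "modifier_fixation_time"]


@dataclass(frozen=True)
class LossEstimate:
    """OLS summary of the average TE loss across replicate trajectories."""

    slope: float            # copies per generation
    intercept: float        # copies at generation 0
    se_slope: float
    tes_lost_1000: float    # implied copies lost over 1000 generations

    def summary(self) -> pd.Series:
        return pd.Series({
            "slope_per_generation": self.slope,
            "se_slope": self.se_slope,
            "intercept": self.intercept,
            "tes_lost_1000": self.tes_lost_1000,
        })


def fit_loss_regression(trajectories: Sequence[Trajectory],
                        method: str = "pooled") -> LossEstimate:
    """Estimate the average TE loss rate by ordinary least squares.

    ``method="pooled"`` (default) regresses mean load on generation over all
    (generation, mean_load) points of all replicates jointly, matching a
    single linear fit across the replicate set; ``method="replicate_mean"``
    first averages the replicate loads at each sampled generation and fits
    the averaged series.  For balanced sampling the two slopes coincide.

    Returns the slope (copies/generation), its standard error, and the
    implied loss over 1000 generations ``tes_lost_1000 = -slope * 1000``
    (positive when load declines).
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    gens = np.concatenate([t.sampled_generations for t in trajectories])
    loads = np.concatenate([t.mean_load for t in trajectories])
    if method == "replicate_mean":
        df = pd.DataFrame({"g": gens, "y": loads}).groupby("g")["y"].mean()
        gens, loads = df.index.to_numpy(float), df.to_numpy()
    elif method != "pooled":
        raise ValueError(f"unknown method {method!r}")
    if np.unique(gens).size < 2:
        raise ValueError("need at least 2 distinct sampled generations "
                         "to estimate a slope")
    X = sm.add_constant(np.asarray(gens, dtype=float))
    fit = sm.OLS(loads, X).fit()
    slope = float(fit.params[1])
    return LossEstimate(slope=slope, intercept=float(fit.params[0]),
                        se_slope=float(fit.bse[1]),
                        tes_lost_1000=-slope * 1000.0)


def modifier_fixation_time(trajectory: Trajectory,
                           threshold: float = 1.0) -> Optional[int]:
    """First sampled generation with modifier frequency >= ``threshold``.

    Returns ``None`` if the threshold is never reached within the sampled
    series.  The default threshold 1.0 is exact fixation (allele counts are
    discrete, so frequency 1.0 is attainable).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    hit = np.flatnonzero(trajectory.modifier_freq >= threshold)
    if hit.size == 0:
        return None
    return int(trajectory.sampled_generations[hit[0]])
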