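"""Permutation ANOVA of TE counts with sequencing coverage as a nuisance.

The inferential model is the fixed linear-model family

    count ~ coverage + generation + mode + generation:mode

with term F statistics computed by sequential (type-I) sums of squares in
that order, and per-term p-values obtained from a permutation null rather
than the F distribution.  ``generation`` is a numeric covariate (consistent
with slope-based loss estimates) and ``mode`` a binary sexual/asexual
indicator.

Two permutation schemes are available:

``freedman-lane`` (default)
    For each term, the response is decomposed against the reduced model of
    all preceding terms; the reduced-model residuals are permuted and added
    back to the reduced-model fit before the term's F statistic is
    recomputed.  This conditions correctly on the nuisance covariate.
``raw``
    The response vector itself is permuted; all term statistics are
    recomputed from each permuted response.

Also here: coverage residualisation for plotting/slope estimation, and the
conversion of a residual-vs-generation slope into "TEs lost per 1000
generations".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["PermutationAnova", "PermAnovaResults", "residualize",
           "tes_lost_from_residual_slope", "ResidualLoss"]

TERMS = ("coverage", "generation", "mode", "generation:mode")
MODES = ("sexual", "asexual")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"strain", "mode", "generation", "coverage", "count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"count table misses columns: {sorted(missing)}")
    bad = set(table["mode"].unique()) - set(MODES)
    if bad:
        raise ValueError(f"mode must be one of {MODES}, got {sorted(bad)}")
    if (table["coverage"] <= 0).any():
        raise ValueError("coverage must be > 0")
    if (table["generation"] < 0).any():
        raise ValueError("generations must be non-negative")
    return table.reset_index(drop=True)


class PermutationAnova:
    """Permutation ANOVA model for a per-sample TE count table.

    Parameters
    ----------
    table
        DataFrame with columns ``strain, mode, generation, coverage, count``
        (one row per sequenced sample); ``mode`` is "sexual" or "asexual".

    Examples
    --------
    >>> model = PermutationAnova.from_dataframe(counts)   # doctest: +SKIP
    >>> res = model.fit(n_permutations=10_000, seed=7)    # doctest: +SKIP
    >>> res.p_interaction                                  # doctest: +SKIP
    """

    def __init__(self, table: pd.DataFrame):
        table = _validate_table(table)
        if set(table["mode"].unique()) != set(MODES):
            raise ValueError("both reproductive modes must be present")
        if table["generation"].nunique() < 2:
            raise ValueError("need at least 2 distinct generations")
        self.table = table
        y = table["count"].to_numpy(dtype=float)
        gen = table["generation"].to_numpy(dtype=float)
        cov = table["coverage"].to_numpy(dtype=float)
        mode = (table["mode"] == "asexual").to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(y), cov, gen, mode, gen * mode])
        self.endog = y
        self.exog = X
        self._check_rank(X)
        # thin QR in model-term order makes sequential SS_j = (q_j' y)^2
        self._Q, self._R = np.linalg.qr(X)

    @staticmethod
    def _check_rank(X: np.ndarray) -> None:
        names = ("intercept",) + TERMS
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, :j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                raise ValueError(
                    f"design is rank deficient: term '{names[j]}' is "
                    "collinear with the preceding terms")
        if X.shape[0] <= X.shape[1]:
            raise ValueError("need more samples than model terms")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, count_col: str = "count",
                       coverage_col: str = "coverage",
                       generation_col: str = "generation",
                       mode_col: str = "mode",
                       strain_col: str = "strain") -> "PermutationAnova":
        table = df.rename(columns={count_col: "count", coverage_col: "coverage",
                                   generation_col: "generation",
                                   mode_col: "mode", strain_col: "strain"})
        return cls(table)

    # -- sequential ANOVA internals ------------------------------------

    def _seq_f(self, Y: np.ndarray) -> np.ndarray:
        """Sequential-SS F statistics for each response column of ``Y``.

        Returns shape (4, n_cols): F for coverage, generation, mode,
        interaction.  Defined as 0 where the residual SS vanishes (constant
        response), so a degenerate table yields p = 1.
        """
        Y = np.atleast_2d(Y.T).T  # (n, B)
        Z = self._Q.T @ Y         # (5, B)
        ss_terms = Z[1:] ** 2
        rss = np.sum(Y * Y, axis=0) - np.sum(Z * Z, axis=0)
        df_resid = Y.shape[0] - self.exog.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ss_terms / (rss / df_resid)
        F[:, rss <= 1e-12 * np.maximum(np.sum(Y * Y, axis=0), 1.0)] = 0.0
        return F

    def fit(self, n_permutations: int = 10_000, seed: Optional[int] = None,
            scheme: str = "freedman-lane") -> "PermAnovaResults":
        """Fit the model and compute permutation p-values per term.

        ``seed`` is required: permutation p-values are only reproducible
        with an explicit seed.
        """
        if seed is None:
            raise ValueError("seed is required for reproducible permutation "
                             "p-values")
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if scheme not in ("freedman-lane", "raw"):
            raise ValueError("scheme must be 'freedman-lane' or 'raw'")
        rng = np.random.default_rng(seed)
        y = self.endog
        F_obs = self._seq_f(y)[:, 0]
        n = y.size
        B = n_permutations
        exceed = np.zeros(4)
        if scheme == "raw":
            perms = rng.permuted(np.tile(y, (B, 1)), axis=1).T
            exceed = np.sum(self._seq_f(perms) >= F_obs[:, None], axis=1)
        else:
            for j in range(4):
                Qred = self._Q[:, :j + 1]       # intercept + preceding terms
                fitted = Qred @ (Qred.T @ y)
                resid = y - fitted
                R = rng.permuted(np.tile(resid, (B, 1)), axis=1).T
                Fstar = self._seq_f(fitted[:, None] + R)[j]
                exceed[j] = np.sum(Fstar >= F_obs[j])
        pvals = (1.0 + exceed) / (1.0 + B)
        beta = np.linalg.solve(self._R, self._Q.T @ y)
        return PermAnovaResults(model=self, params=beta, f_obs=F_obs,
                                pvalues=pvals, n_permutations=B,
                                scheme=scheme)


@dataclass(frozen=True)
class PermAnovaResults:
    """Fitted permutation ANOVA: coefficients, F statistics, p-values."""

    model: PermutationAnova
    params: np.ndarray          # intercept, coverage, generation, mode, g:m
    f_obs: np.ndarray           # observed sequential F per term
    pvalues: np.ndarray         # permutation p per term, order as TERMS
    n_permutations: int
    scheme: str

    @property
    def p_coverage(self) -> float:
        return float(self.pvalues[0])

    @property
    def p_generation(self) -> float:
        return float(self.pvalues[1])

    @property
    def p_mode(self) -> float:
        return float(self.pvalues[2])

    @property
    def p_interaction(self) -> float:
        return float(self.pvalues[3])

    def summary(self) -> pd.DataFrame:
        """Sequential ANOVA table with permutation p-values."""
        return pd.DataFrame({
            "term": list(TERMS),
            "coef": self.params[1:],
            "F": self.f_obs,
            "p_perm": self.pvalues,
        }).set_index("term")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = self.summary().to_string(float_format=lambda v: f"{v:.4g}")
        return (f"PermAnovaResults({self.scheme}, "
                f"B={self.n_permutations})\n{body}")


def residualize(table: pd.DataFrame) -> np.ndarray:
    """Residuals of TE count after removing the linear coverage effect.

    TE detection probability depends on sequencing coverage, so counts are
    expressed as residuals of the least-squares regression of count on
    coverage.  With constant coverage the fit degenerates to a mean-only
    model, i.e. residuals are the centred counts.
    """
    table = _validate_table(table)
    if len(table) < 3:
        raise ValueError("need at least 3 rows to residualise")
    y = table["count"].to_numpy(dtype=float)
    cov = table["coverage"].to_numpy(dtype=float)
    if np.ptp(cov) == 0.0:
        return y - y.mean()
    X = np.column_stack([np.ones_like(cov), cov])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass(frozen=True)
class ResidualLoss:
    """TE loss implied by the residual-vs-generation regression slope."""

    slope: float                # residual copies per generation
    se_slope: float
    tes_lost_1000: float        # -slope * 1000; negative values mean a gain
    implied_final_count: float  # ancestral count minus the loss

    def summary(self) -> pd.Series:
        return pd.Series({
            "slope_per_generation": self.slope,
            "se_slope": self.se_slope,
            "tes_lost_1000": self.tes_lost_1000,
            "implied_final_count": self.implied_final_count,
        })


def tes_lost_from_residual_slope(residuals: Sequence[float],
                                 generations: Sequence[float],
                                 ancestral_full_length: int = 50
                                 ) -> ResidualLoss:
    """TEs lost over 1000 generations from coverage-corrected counts.

    Fits OLS of the coverage residuals on generation and converts the slope
    to a loss over 1000 generations; sign convention: a declining residual
    series gives a positive ``tes_lost_1000``, an increasing one a negative
    value (a gain).  The implied final count is the ancestral full-length
    count minus the loss.
    """
    residuals = np.asarray(residuals, dtype=float)
    generations = np.asarray(generations, dtype=float)
    if residuals.shape != generations.shape:
        raise ValueError("residuals and generations must have equal length")
    if np.unique(generations).size < 2:
        raise ValueError("need at least 2 distinct generations")
    X = np.column_stack([np.ones_like(generations), generations])
    beta, *_ = np.linalg.lstsq(X, residuals, rcond=None)
    resid = residuals - X @ beta
    dof = max(len(residuals) - 2, 1)
    sxx = np.sum((generations - generations.mean()) ** 2)
    se = float(np.sqrt(np.sum(resid ** 2) / dof / sxx))
    slope = float(beta[1])
    lost = -slope * 1000.0
    return ResidualLoss(slope=slope, se_slope=se, tes_lost_1000=lost,
                        implied_final_count=ancestral_full_length - lost)
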