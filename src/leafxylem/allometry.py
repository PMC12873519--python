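"""Log-log allometric scaling fits and slope comparison.

All continuous traits are log10-transformed before fitting, so a simple
OLS fit of ``log10 y ~ log10 x`` estimates the exponent ``b`` and the
(log-scale) prefactor of the power law ``y = 10**a * x**b``.  OLS rather
than standardised/reduced major axis is used throughout because the
predictor (e.g. path length) is treated as causally upstream of the
response (conduit diameter).

The central objects follow the statsmodels convention: build a
:class:`ScalingOLS` model from a trait table, call :meth:`~ScalingOLS.fit`,
and read estimates, intervals and the ANOVA-style statistics off the
returned :class:`ScalingResults`.  Two fitted slopes from independent
data sets are compared with :func:`compare_slopes`, a Welch-style t test
on the slope standard errors with Welch-Satterthwaite degrees of
freedom.  :func:`summary_table` runs the standard nine-regression suite
linking leaf length, petiole-base and twig vessel diameters, wood
density and plant height.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TRAIT_COLUMNS",
    "STANDARD_REGRESSIONS",
    "ScalingOLS",
    "ScalingResults",
    "GroupScalingResults",
    "SlopeComparison",
    "compare_slopes",
    "fit_loglog",
    "fit_with_group",
    "summary_table",
    "descriptive_stats",
]

#: continuous trait columns of a trait table (all strictly positive)
TRAIT_COLUMNS = (
    "leaf_length_cm",
    "d_pet_um",
    "d_twig_um",
    "wood_density_g_cm3",
    "height_m",
)

#: the standard (response, predictor) suite: petiole and twig vessel
#: diameters against leaf length, wood density and height, twig diameter
#: against petiole diameter, plus wood density ~ leaf length and leaf
#: length ~ height.
STANDARD_REGRESSIONS = (
    ("d_pet_um", "leaf_length_cm"),
    ("d_pet_um", "wood_density_g_cm3"),
    ("d_pet_um", "height_m"),
    ("d_twig_um", "leaf_length_cm"),
    ("d_twig_um", "wood_density_g_cm3"),
    ("d_twig_um", "height_m"),
    ("d_twig_um", "d_pet_um"),
    ("wood_density_g_cm3", "leaf_length_cm"),
    ("leaf_length_cm", "height_m"),
)


def _log10_pair(
    table: pd.DataFrame, response: str, predictor: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pairwise-complete log10-transformed response/predictor arrays."""
    for col in (response, predictor):
        if col not in table.columns:
            raise KeyError(f"trait table has no column {col!r}")
    sub = table[[response, predictor]].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.info(
            "fit %s ~ %s: %d of %d records dropped (missing values)",
            response, predictor, n_dropped, len(sub),
        )
    bad = complete[(complete[response] <= 0) | (complete[predictor] <= 0)]
    if len(bad):
        names = (
            table.loc[bad.index, "species"].tolist()
            if "species" in table.columns
            else bad.index.tolist()
        )
        raise ValueError(
            f"non-positive trait values for {response!r}/{predictor!r} in: {names}"
        )
    if len(complete) < 3:
        raise ValueError(
            f"need >= 3 complete records for {response} ~ {predictor}, "
            f"got {len(complete)}"
        )
    y = np.log10(complete[response].to_numpy(dtype=float))
    x = np.log10(complete[predictor].to_numpy(dtype=float))
    return y, x, n_dropped


@dataclass(frozen=True)
class SlopeComparison:
    """Welch-style comparison of two independently fitted slopes.

    ``t = (b1 - b2) / sqrt(se1**2 + se2**2)`` with Welch-Satterthwaite
    degrees of freedom pooling the two slope-variance terms at their
    residual degrees of freedom; ``pvalue`` is the two-sided tail.
    """

    t: float
    df: float
    pvalue: float
    slope_diff: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"slope difference {self.slope_diff:+.4f}: "
            f"t = {self.t:.3f}, df = {self.df:.2f}, p = {self.pvalue:.4g}"
        )


class ScalingResults:
    """Results of one log10-log10 OLS scaling fit.

    Thin wrapper over the statsmodels OLS results exposing the
    quantities conventionally reported for allometric fits: the slope
    (scaling exponent) and intercept with standard errors and 95%
    t-based confidence intervals, adjusted R^2, the overall F statistic
    and residual degrees of freedom.
    """

    def __init__(
        self,
        sm_results,
        response: str,
        predictor: str,
        n_dropped: int = 0,
    ) -> None:
        self._res = sm_results
        self.response = response
        self.predictor = predictor
        self.n_dropped = n_dropped

    # -- estimates ---------------------------------------------------
    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    @property
    def df_resid(self) -> int:
        return int(self._res.df_resid)

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def slope(self) -> float:
        return float(self._res.params[self._slope_name])

    @property
    def intercept(self) -> float:
        return float(self._res.params["const"])

    @property
    def slope_se(self) -> float:
        return float(self._res.bse[self._slope_name])

    @property
    def _slope_name(self) -> str:
        names = [p for p in self._res.params.index if p != "const"]
        return names[0]

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self._res.conf_int(alpha=alpha)

    @property
    def slope_ci(self) -> tuple[float, float]:
        lo, hi = self.conf_int().loc[self._slope_name]
        return float(lo), float(hi)

    @property
    def intercept_ci(self) -> tuple[float, float]:
        lo, hi = self.conf_int().loc["const"]
        return float(lo), float(hi)

    @property
    def rsquared(self) -> float:
        return float(self._res.rsquared)

    @property
    def rsquared_adj(self) -> float:
        return float(self._res.rsquared_adj)

    @property
    def fvalue(self) -> float:
        return float(self._res.fvalue)

    @property
    def f_pvalue(self) -> float:
        return float(self._res.f_pvalue)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._res.resid)

    @property
    def is_simple(self) -> bool:
        return len(self._res.params) == 2

    # -- presentation ------------------------------------------------
    def to_row(self) -> dict:
        """One machine-readable summary row (slope/intercept with CIs)."""
        s_lo, s_hi = self.slope_ci
        i_lo, i_hi = self.intercept_ci
        return {
            "response": self.response,
            "predictor": self.predictor,
            "n": self.nobs,
            "r2_adj": self.rsquared_adj,
            "df_resid": self.df_resid,
            "F": self.fvalue,
            "p": self.f_pvalue,
            "slope": self.slope,
            "slope_lo": s_lo,
            "slope_hi": s_hi,
            "intercept": self.intercept,
            "intercept_lo": i_lo,
            "intercept_hi": i_hi,
        }

    def summary(self) -> str:
        row = self.to_row()
        return (
            f"log10({self.response}) ~ log10({self.predictor})  [OLS]\n"
            f"  n = {row['n']}, df_resid = {row['df_resid']}, "
            f"R2_adj = {row['r2_adj']:.3f}, F = {row['F']:.1f} (p = {row['p']:.3g})\n"
            f"  slope     = {row['slope']:.4f}  "
            f"95% CI ({row['slope_lo']:.4f}, {row['slope_hi']:.4f})\n"
            f"  intercept = {row['intercept']:.4f}  "
            f"95% CI ({row['intercept_lo']:.4f}, {row['intercept_hi']:.4f})"
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ScalingResults {self.response}~{self.predictor} "
            f"slope={self.slope:.4f} n={self.nobs}>"
        )


class ScalingOLS:
    """OLS power-law scaling model ``log10(response) ~ log10(predictor)``.

    Construct from arrays of raw (untransformed, strictly positive)
    trait values or, more conveniently, with :meth:`from_dataframe`.
    """

    def __init__(
        self,
        response_values: np.ndarray,
        predictor_values: np.ndarray,
        response: str = "y",
        predictor: str = "x",
        n_dropped: int = 0,
    ) -> None:
        y = np.asarray(response_values, dtype=float)
        x = np.asarray(predictor_values, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("response and predictor must be 1-D arrays of equal length")
        if np.any(y <= 0) or np.any(x <= 0):
            raise ValueError("trait values must be strictly positive for log10 transform")
        if len(y) < 3:
            raise ValueError(f"need >= 3 records, got {len(y)}")
        self._logy = np.log10(y)
        self._logx = np.log10(x)
        self.response = response
        self.predictor = predictor
        self._n_dropped = n_dropped

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, response: str, predictor: str
    ) -> "ScalingOLS":
        """Build from a trait table, pairwise-dropping incomplete records."""
        logy, logx, n_dropped = _log10_pair(table, response, predictor)
        obj = cls.__new__(cls)
        obj._logy = logy
        obj._logx = logx
        obj.response = response
        obj.predictor = predictor
        obj._n_dropped = n_dropped
        return obj

    def fit(self) -> ScalingResults:
        X = sm.add_constant(
            pd.DataFrame({f"log10_{self.predictor}": self._logx})
        )
        res = sm.OLS(self._logy, X).fit()
        return ScalingResults(res, self.response, self.predictor, self._n_dropped)


def fit_loglog(table: pd.DataFrame, response: str, predictor: str) -> ScalingResults:
    """Fit ``log10(response) ~ log10(predictor)`` by OLS on a trait table."""
    return ScalingOLS.from_dataframe(table, response, predictor).fit()


def compare_slopes(fit1: ScalingResults, fit2: ScalingResults) -> SlopeComparison:
    """Welch t test for a difference between two independent slopes.

    The statistic divides the slope difference by the root of the summed
    squared slope standard errors; degrees of freedom follow
    Welch-Satterthwaite, pooling each slope-variance term at its fit's
    residual degrees of freedom.  Antisymmetric in its arguments.
    """
    for f in (fit1, fit2):
        if not f.is_simple:
            raise ValueError("compare_slopes requires simple (one-predictor) fits")
    b1, b2 = fit1.slope, fit2.slope
    v1, v2 = fit1.slope_se**2, fit2.slope_se**2
    t = (b1 - b2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / fit1.df_resid + v2**2 / fit2.df_resid)
    p = 2.0 * stats.t.sf(abs(t), df)
    return SlopeComparison(t=t, df=df, pvalue=min(p, 1.0), slope_diff=b1 - b2)


class GroupScalingResults:
    """Scaling fit with a categorical group main effect and interaction.

    Model: ``log10 y ~ log10 x * group``.  ``interaction_pvalue`` tests
    whether the scaling exponent differs between groups (slope
    heterogeneity); ``group_pvalue`` tests the group main effect
    (intercept shift).  For two-level groups these are the coefficient
    Wald t tests; for more levels they are joint type-II F tests.
    """

    def __init__(self, sm_results, anova: pd.DataFrame, response, predictor, group):
        self._res = sm_results
        self._anova = anova
        self.response = response
        self.predictor = predictor
        self.group = group
        self.levels = sorted(anova.attrs["levels"])

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    @property
    def rsquared_adj(self) -> float:
        return float(self._res.rsquared_adj)

    def _terms(self, kind: str) -> list[str]:
        names = list(self._res.params.index)
        if kind == "interaction":
            return [n for n in names if ":" in n]
        return [n for n in names if n.startswith("C(grp)") and ":" not in n]

    @property
    def interaction_pvalue(self) -> float:
        terms = self._terms("interaction")
        if len(terms) == 1:
            return float(self._res.pvalues[terms[0]])
        return float(self._anova.loc["logx:C(grp)", "PR(>F)"])

    @property
    def group_pvalue(self) -> float:
        terms = self._terms("group")
        if len(terms) == 1:
            return float(self._res.pvalues[terms[0]])
        return float(self._anova.loc["C(grp)", "PR(>F)"])

    @property
    def interaction_coef(self) -> float:
        terms = self._terms("interaction")
        if len(terms) != 1:
            raise ValueError("single interaction coefficient only defined for 2-level groups")
        return float(self._res.params[terms[0]])

    @property
    def group_coef(self) -> float:
        terms = self._terms("group")
        if len(terms) != 1:
            raise ValueError("single group coefficient only defined for 2-level groups")
        return float(self._res.params[terms[0]])

    @property
    def group_coef_se(self) -> float:
        terms = self._terms("group")
        if len(terms) != 1:
            raise ValueError("single group SE only defined for 2-level groups")
        return float(self._res.bse[terms[0]])

    def to_row(self) -> dict:
        return {
            "response": self.response,
            "predictor": self.predictor,
            "group": self.group,
            "n": self.nobs,
            "r2_adj": self.rsquared_adj,
            "interaction_p": self.interaction_pvalue,
            "group_p": self.group_pvalue,
        }

    def summary(self) -> str:
        return (
            f"log10({self.response}) ~ log10({self.predictor}) * {self.group}\n"
            f"  n = {self.nobs}, levels = {self.levels}\n"
            f"  slope heterogeneity ({self.group} x {self.predictor}): "
            f"p = {self.interaction_pvalue:.4g}\n"
            f"  intercept shift ({self.group}): p = {self.group_pvalue:.4g}"
        )


def fit_with_group(
    table: pd.DataFrame, response: str, predictor: str, group: str
) -> GroupScalingResults:
    """Scaling fit allowing slope and intercept to differ by group.

    Requires at least two group levels with at least three records each.
    """
    if group not in table.columns:
        raise KeyError(f"trait table has no column {group!r}")
    sub = table[[response, predictor, group]].dropna()
    counts = sub[group].value_counts()
    if len(counts) < 2 or counts.min() < 3:
        raise ValueError(
            f"group {group!r} must have >= 2 levels with >= 3 records each; "
            f"got {counts.to_dict()}"
        )
    if (sub[response] <= 0).any() or (sub[predictor] <= 0).any():
        raise ValueError("trait values must be strictly positive for log10 transform")
    frame = pd.DataFrame(
        {
            "logy": np.log10(sub[response].to_numpy(dtype=float)),
            "logx": np.log10(sub[predictor].to_numpy(dtype=float)),
            "grp": sub[group].astype(str).to_numpy(),
        }
    )
    res = smf.ols("logy ~ logx * C(grp)", data=frame).fit()
    anova = sm.stats.anova_lm(res, typ=2)
    anova.attrs["levels"] = list(counts.index.astype(str))
    return GroupScalingResults(res, anova, response, predictor, group)


def descriptive_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Min/max/mean/SD per continuous trait, with the extreme species."""
    rows = []
    for col in TRAIT_COLUMNS:
        if col not in table.columns:
            continue
        vals = pd.to_numeric(table[col], errors="coerce").dropna()
        row = {
            "variable": col,
            "n": len(vals),
            "min": vals.min(),
            "max": vals.max(),
            "mean": vals.mean(),
            "sd": vals.std(ddof=1),
        }
        if "species" in table.columns and len(vals):
            row["min_species"] = table.loc[vals.idxmin(), "species"]
            row["max_species"] = table.loc[vals.idxmax(), "species"]
        rows.append(row)
    return pd.DataFrame(rows)


def summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Run the standard nine-regression scaling suite on a trait table.

    Returns one row per (response, predictor) pair in
    :data:`STANDARD_REGRESSIONS` with slopes, intercepts, 95% CIs,
    adjusted R^2 and F statistics.
    """
    rows = [fit_loglog(table, resp, pred).to_row() for resp, pred in STANDARD_REGRESSIONS]
    return pd.DataFrame(rows)
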