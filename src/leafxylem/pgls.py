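"""Phylogenetic generalized least squares with AICc model selection.

A PGLS regression is a Gaussian linear model whose residual covariance
is proportional to a structure derived from a phylogeny: the identity
(white noise, WN — equivalent to OLS), the Brownian-motion matrix of
shared-ancestor depths (BM), or an Ornstein-Uhlenbeck correlation
``exp(-alpha * d_ij)`` in patristic distance (OU).  The residual
variance is profiled by maximum likelihood, so each fit reports a
log-likelihood comparable across correlation structures, and candidate
structures are ranked by the small-sample Akaike criterion

    AICc = -2 logL + 2k + 2k(k+1) / (n - k - 1),

where k counts the regression coefficients plus the profiled variance.

Usage mirrors statsmodels: build a :class:`PGLS` model (most easily via
:meth:`PGLS.from_dataframe`, which log10-transforms the traits), call
:meth:`~PGLS.fit`, and read coefficients/intervals/AICc off the
:class:`PGLSResults`.  :func:`select_model` fits WN, BM and OU(alpha=1)
and returns the fits ranked by AICc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .trees import CorrelationStructure, covariance_matrix, tip_labels

logger = logging.getLogger(__name__)

__all__ = ["PGLS", "PGLSResults", "ModelSelection", "gls_fit", "select_model"]

DEFAULT_STRUCTURES = (
    CorrelationStructure("WN"),
    CorrelationStructure("BM"),
    CorrelationStructure("OU", 1.0),
)


def _ensure_pd(C: np.ndarray) -> tuple[np.ndarray, bool]:
    """Return a positive-definite version of C, adding jitter if needed."""
    C = np.asarray(C, dtype=float)
    try:
        np.linalg.cholesky(C)
        return C, False
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(C) / len(C)
        Cj = C + jitter * np.eye(len(C))
        try:
            np.linalg.cholesky(Cj)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(
                f"covariance matrix singular even after jitter {jitter:g}"
            ) from err
        logger.info("covariance not PD; added jitter %g to the diagonal", jitter)
        return Cj, True


class PGLSResults:
    """Fitted PGLS coefficients with likelihood-based model criteria."""

    def __init__(self, sm_results, structure: CorrelationStructure,
                 response: str, predictors: list[str]) -> None:
        self._res = sm_results
        self.structure = structure
        self.response = response
        self.predictors = predictors

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
    def bse(self) -> pd.Series:
        return self._res.bse

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self._res.conf_int(alpha=alpha)

    @property
    def slope(self) -> float:
        names = [p for p in self._res.params.index if p != "const"]
        return float(self._res.params[names[0]])

    @property
    def intercept(self) -> float:
        return float(self._res.params["const"])

    @property
    def llf(self) -> float:
        """Profile (ML) Gaussian log-likelihood of the fitted model."""
        return float(self._res.llf)

    @property
    def k_params(self) -> int:
        """Parameter count for information criteria: coefficients + variance."""
        return len(self._res.params) + 1

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def aicc(self) -> float:
        n, k = self.nobs, self.k_params
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    def to_row(self) -> dict:
        ci = self.conf_int()
        names = [p for p in self._res.params.index if p != "const"]
        slope_lo, slope_hi = (float(v) for v in ci.loc[names[0]])
        int_lo, int_hi = (float(v) for v in ci.loc["const"])
        return {
            "response": self.response,
            "predictor": names[0],
            "model": self.structure.label,
            "n": self.nobs,
            "df_resid": self.df_resid,
            "slope": self.slope,
            "slope_lo": slope_lo,
            "slope_hi": slope_hi,
            "intercept": self.intercept,
            "intercept_lo": int_lo,
            "intercept_hi": int_hi,
            "intercept_backtransformed": 10.0 ** self.intercept,
            "loglik": self.llf,
            "aic": self.aic,
            "aicc": self.aicc,
        }

    def summary(self) -> str:
        row = self.to_row()
        return (
            f"PGLS {self.response} ~ {row['predictor']}  "
            f"[{self.structure.label}]\n"
            f"  n = {row['n']}, df_resid = {row['df_resid']}\n"
            f"  slope     = {row['slope']:.4f}  "
            f"95% CI ({row['slope_lo']:.4f}, {row['slope_hi']:.4f})\n"
            f"  intercept = {row['intercept']:.4f}  "
            f"(back-transformed {row['intercept_backtransformed']:.3f})\n"
            f"  logL = {row['loglik']:.3f}, AIC = {row['aic']:.3f}, "
            f"AICc = {row['aicc']:.3f}"
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PGLSResults {self.response} [{self.structure.label}] "
            f"slope={self.slope:.4f} AICc={self.aicc:.2f}>"
        )


class PGLS:
    """Generalized least squares model with phylogenetic residual covariance.

    Parameters
    ----------
    y : (n,) array
        Response values (already transformed as desired).
    X : (n, p) array or DataFrame
        Design matrix.  A constant column is added if absent.
    covariance : (n, n) array
        Residual covariance (up to scale) aligned with the rows of y/X.
    structure : CorrelationStructure
        Label describing where the covariance came from.
    """

    def __init__(self, y, X, covariance, structure=CorrelationStructure("WN"),
                 response: str = "y") -> None:
        y = np.asarray(y, dtype=float)
        if isinstance(X, pd.DataFrame):
            self._xnames = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[0] != len(y):
                X = X.T
            self._xnames = [f"x{i}" for i in range(X.shape[1])]
        if not np.allclose(X[:, 0], 1.0):
            X = np.column_stack([np.ones(len(y)), X])
            self._xnames = ["const"] + self._xnames
        else:
            self._xnames[0] = "const"
        C = np.asarray(covariance, dtype=float)
        if C.shape != (len(y), len(y)):
            raise ValueError(
                f"covariance shape {C.shape} does not match n = {len(y)}"
            )
        self._y = y
        self._X = pd.DataFrame(X, columns=self._xnames)
        self._C, _ = _ensure_pd(C)
        self.structure = structure
        self.response = response

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        response: str,
        predictor: str,
        tree: dendropy.Tree,
        structure: CorrelationStructure = CorrelationStructure("BM"),
    ) -> "PGLS":
        """Build a log10-log10 PGLS from a species trait table and a tree.

        The table must have a ``species`` column; only species present in
        both the table and the tree are used (the intersection count is
        logged, since trait tables and supertrees frequently disagree by
        a species or two).
        """
        if "species" not in table.columns:
            raise KeyError("trait table needs a 'species' column for PGLS")
        tips = set(tip_labels(tree))
        sub = table.dropna(subset=[response, predictor])
        matched = sub[sub["species"].isin(tips)]
        if len(matched) < len(sub) or len(tips) > len(matched):
            logger.info(
                "PGLS %s ~ %s: using %d species (table %d, tree %d tips)",
                response, predictor, len(matched), len(sub), len(tips),
            )
        if len(matched) < 3:
            raise ValueError(
                f"only {len(matched)} species shared between table and tree"
            )
        if (matched[response] <= 0).any() or (matched[predictor] <= 0).any():
            raise ValueError("trait values must be strictly positive for log10 transform")
        taxa = matched["species"].tolist()
        C = covariance_matrix(tree, structure, taxa=taxa)
        y = np.log10(matched[response].to_numpy(dtype=float))
        X = pd.DataFrame(
            {"const": 1.0, f"log10_{predictor}": np.log10(matched[predictor].to_numpy(dtype=float))}
        )
        return cls(y, X, C, structure=structure, response=response)

    def fit(self) -> PGLSResults:
        res = sm.GLS(self._y, self._X, sigma=self._C).fit()
        names = [n for n in self._xnames if n != "const"]
        return PGLSResults(res, self.structure, self.response, names)


def gls_fit(y, X, covariance,
            structure: CorrelationStructure = CorrelationStructure("WN"),
            response: str = "y") -> PGLSResults:
    """One-shot GLS fit of ``y`` on ``X`` under a given residual covariance."""
    return PGLS(y, X, covariance, structure=structure, response=response).fit()


@dataclass
class ModelSelection:
    """Ranked correlation-structure fits for one regression."""

    fits: list[PGLSResults] = field(default_factory=list)

    @property
    def best(self) -> PGLSResults:
        return self.fits[0]

    @property
    def delta_aicc(self) -> float:
        """AICc gap between the best model and the runner-up."""
        if len(self.fits) < 2:
            return np.inf
        return self.fits[1].aicc - self.fits[0].aicc

    def table(self) -> pd.DataFrame:
        rows = []
        best = self.fits[0].aicc
        for f in self.fits:
            row = f.to_row()
            row["delta_aicc"] = f.aicc - best
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"{f.structure.label}: AICc = {f.aicc:.3f}" for f in self.fits]
        return (
            f"best: {self.best.structure.label} "
            f"(delta to runner-up {self.delta_aicc:.3f})\n  " + "\n  ".join(lines)
        )


def select_model(
    table: pd.DataFrame,
    response: str,
    predictor: str,
    tree: dendropy.Tree,
    structures=DEFAULT_STRUCTURES,
) -> ModelSelection:
    """Fit PGLS under each candidate structure and rank by AICc.

    Defaults to white noise, Brownian motion, and OU with alpha = 1.
    """
    fits = [
        PGLS.from_dataframe(table, response, predictor, tree, structure=s).fit()
        for s in structures
    ]
    fits.sort(key=lambda f: f.aicc)
    return ModelSelection(fits=fits)
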