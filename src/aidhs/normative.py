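"""Normative growth charts of hippocampal features over age.

For each scalar feature and sex, a generalized additive model (penalized
B-spline smooth of age, basis dimension 5, penalty weight chosen by
generalized cross-validation) is fitted to the harmonized features of the
healthy controls, with both hemispheres of each control contributing
observations.  Residuals are modelled as Gaussian with constant SD per
feature x sex, so the p-th centile curve is

    c_p(age) = mu_hat(age, sex) + z_p * sigma_hat,

with ``z_p`` the standard normal quantile, and an individual hippocampus is
scored as ``100 * Phi((value - mu_hat) / sigma_hat)``.  Charts are displayed
at the 5th/50th/95th centiles; individual scores are clipped to (0.1, 99.9)
for display.

The module also provides the ordinary least-squares regression of the
harmonized control features on age, sex and hemisphere used to summarize
healthy hippocampal anatomy.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.gam.api import BSplines, GLMGam

from .cohort_io import SCALAR_FEATURES

logger = logging.getLogger(__name__)

SEXES = ("M", "F")
DISPLAY_CLIP = (0.1, 99.9)


class NormativeGrowthChart(BaseEstimator):
    """Per-feature, per-sex GAM normative model with Gaussian centiles.

    Parameters
    ----------
    basis_df : int
        B-spline basis dimension for the age smooth (default 5; small
        control cohorts do not support more flexible smooths).
    min_per_sex : int
        Minimum observations per sex stratum (default 10; fewer is an error).
    n_warn : int
        Warn when fitted on fewer than this many controls (default 30).

    Attributes
    ----------
    mu_ : dict mapping (feature, sex) to a dense age grid of the smooth mean.
    sigma_ : dict mapping (feature, sex) to the residual SD.
    age_support_ : (min, max) ages seen at fit time.
    n_fit_ : number of control subjects used.
    """

    def __init__(self, basis_df: int = 5, min_per_sex: int = 10, n_warn: int = 30,
                 grid_size: int = 256):
        self.basis_df = basis_df
        self.min_per_sex = min_per_sex
        self.n_warn = n_warn
        self.grid_size = grid_size

    def fit(self, X: pd.DataFrame, y=None):
        """Fit on a long table of healthy-control rows.

        ``X`` needs columns ``age_years``, ``sex`` and the five scalar
        features; both hemispheres of each control should be present as
        separate rows (hemisphere is ignored for the charts).
        """
        n_subj = X.index.nunique()
        if n_subj < self.n_warn:
            logger.warning("normative fit on only %d controls (< %d recommended)",
                           n_subj, self.n_warn)
        ages = X["age_years"].to_numpy(dtype=float)
        self.age_support_ = (float(ages.min()), float(ages.max()))
        self.n_fit_ = int(n_subj)
        grid = np.linspace(*self.age_support_, self.grid_size)
        self.age_grid_ = grid
        self.mu_, self.sigma_ = {}, {}
        for sex in SEXES:
            rows = X[X["sex"] == sex]
            if len(rows) < self.min_per_sex:
                raise ValueError(
                    f"sex stratum {sex!r} has {len(rows)} observations "
                    f"(< {self.min_per_sex})")
            age = rows["age_years"].to_numpy(dtype=float)
            bs = BSplines(age[:, None], df=[self.basis_df], degree=[3])
            const = np.ones((len(rows), 1))
            for feat in SCALAR_FEATURES:
                vals = rows[feat].to_numpy(dtype=float)
                res = self._fit_gcv(vals, const, bs)
                grid_c = np.clip(grid, age.min(), age.max())
                mu = res.predict(exog=np.ones((len(grid), 1)),
                                 exog_smooth=grid_c[:, None])
                resid = vals - res.predict(exog=const, exog_smooth=age[:, None])
                self.mu_[(feat, sex)] = np.asarray(mu, dtype=float)
                self.sigma_[(feat, sex)] = float(np.sqrt(np.mean(resid ** 2)))
        return self

    @staticmethod
    def _fit_gcv(vals, const, bs):
        """Penalty weight by generalized cross-validation over a log grid.

        GCV(alpha) = n * RSS / (n - edf)^2; the grid spans effectively
        unpenalized to effectively linear fits and is deterministic.
        """
        best = (np.inf, None)
        n = len(vals)
        for alpha in np.logspace(-3, 8, 12):
            res = GLMGam(vals, exog=const, smoother=bs, alpha=[alpha]).fit()
            edf = float(np.sum(res.edf))
            gcv = n * float(np.sum(res.resid_response ** 2)) / (n - edf) ** 2
            if gcv < best[0]:
                best = (gcv, res)
        return best[1]

    def _mu_at(self, feature: str, sex: str, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        lo, hi = self.age_support_
        if (age < lo).any() or (age > hi).any():
            logger.warning("age outside normative support [%.1f, %.1f]; "
                           "evaluating at the nearest supported age", lo, hi)
        return np.interp(np.clip(age, lo, hi), self.age_grid_,
                         self.mu_[(feature, sex)])

    def centile_curve(self, feature: str, sex: str, percentile: float,
                      age_grid=None) -> pd.DataFrame:
        """Centile curve ``mu_hat + z_p sigma_hat`` on an age grid."""
        check_is_fitted(self, "mu_")
        if not 0 < percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if age_grid is None:
            age_grid = self.age_grid_
        age_grid = np.asarray(age_grid, dtype=float)
        z = stats.norm.ppf(percentile / 100.0)
        vals = self._mu_at(feature, sex, age_grid) + z * self.sigma_[(feature, sex)]
        return pd.DataFrame({"age_years": age_grid, "value": vals})

    def percentile_score(self, feature: str, value, age, sex: str,
                         clip: bool = False) -> np.ndarray:
        """Gaussian percentile of ``value`` against the normative band.

        ``clip=True`` applies the (0.1, 99.9) display clip used in reports.
        """
        check_is_fitted(self, "mu_")
        mu = self._mu_at(feature, sex, age)
        z = (np.asarray(value, dtype=float) - mu) / self.sigma_[(feature, sex)]
        pct = 100.0 * stats.norm.cdf(z)
        if clip:
            pct = np.clip(pct, *DISPLAY_CLIP)
        return pct

    def to_dict(self) -> dict:
        check_is_fitted(self, "mu_")
        return {
            "version": 1, "basis_df": self.basis_df,
            "age_support": list(self.age_support_), "n_fit": self.n_fit_,
            "age_grid": self.age_grid_.tolist(),
            "mu": {f"{f}|{s}": v.tolist() for (f, s), v in self.mu_.items()},
            "sigma": {f"{f}|{s}": v for (f, s), v in self.sigma_.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeGrowthChart":
        obj = cls(basis_df=d["basis_df"])
        obj.age_support_ = tuple(d["age_support"])
        obj.n_fit_ = d["n_fit"]
        obj.age_grid_ = np.array(d["age_grid"])
        obj.mu_ = {tuple(k.split("|")): np.array(v) for k, v in d["mu"].items()}
        obj.sigma_ = {tuple(k.split("|")): float(v) for k, v in d["sigma"].items()}
        return obj


def fit_normative(controls_long: pd.DataFrame, **params) -> NormativeGrowthChart:
    """Thin wrapper: fit the growth charts on healthy-control rows."""
    return NormativeGrowthChart(**params).fit(controls_long)


def covariate_regression(controls_long: pd.DataFrame) -> pd.DataFrame:
    """OLS of each harmonized feature on hemisphere, sex and age in controls.

    ``controls_long`` needs one row per control hemisphere with columns
    ``hemisphere``, ``sex``, ``age_years`` and the five features.  Returns a
    tidy table of coefficients and p-values (references: left hemisphere,
    female sex).
    """
    X = np.column_stack([
        np.ones(len(controls_long)),
        (controls_long["hemisphere"] == "right").to_numpy(dtype=float),
        (controls_long["sex"] == "M").to_numpy(dtype=float),
        controls_long["age_years"].to_numpy(dtype=float),
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant covariate?)")
    names = ["intercept", "hemisphere_right", "sex_M", "age"]
    rows = []
    for feat in SCALAR_FEATURES:
        res = sm.OLS(controls_long[feat].to_numpy(dtype=float), X).fit()
        for i, nm in enumerate(names):
            rows.append({"feature": feat, "term": nm, "coef": res.params[i],
                         "se": res.bse[i], "p_value": res.pvalues[i]})
    return pd.DataFrame(rows)
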