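"""Multi-site harmonization and asymmetry normalization.

Scanner/site batch effects are removed with a parametric empirical-Bayes
location/scale adjustment (the ComBat model): per feature, site offsets are
shrunk toward a normal prior and site scale factors toward an inverse-gamma
prior, while biological covariates (age, sex, disease status) are estimated
jointly and re-added, so harmonization removes site signal without flattening
biology.  Left and right hemisphere values enter as separate feature columns
(10 columns = 5 features x 2 hemispheres), preserving within-subject pairing.

Downstream of harmonization, each subject is reduced to a left-referenced
asymmetry index per feature,

    AI = 2 (lh - rh) / (lh + rh),

signed, unitless and bounded in (-2, 2) for positive features, and the AIs
are z-scored by the mean/SD of the healthy controls of the training sample
("normalized asymmetries") so that typical left-right asymmetry maps to 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort_io import SCALAR_FEATURES, HEMISPHERES

logger = logging.getLogger(__name__)

#: wide-format feature columns, hemispheres as separate columns
WIDE_COLUMNS = [f"{feat}_{hemi}" for feat in SCALAR_FEATURES for hemi in HEMISPHERES]

MIN_SITE_SIZE = 20  # harmonization needs >= 20 subjects per scanner


def to_wide(long_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long (subject, hemisphere) feature table to one row/subject."""
    wide = long_df.pivot(index="subject_id", columns="hemisphere",
                         values=list(SCALAR_FEATURES))
    wide.columns = [f"{feat}_{hemi}" for feat, hemi in wide.columns]
    return wide[WIDE_COLUMNS]


def to_long(wide_df: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Inverse of :func:`to_wide`; tags rows with a processing ``stage``."""
    frames = []
    for hemi in HEMISPHERES:
        df = pd.DataFrame({"subject_id": wide_df.index, "hemisphere": hemi})
        for feat in SCALAR_FEATURES:
            df[feat] = wide_df[f"{feat}_{hemi}"].to_numpy()
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["stage"] = stage
    return out


def _design_matrices(demo: pd.DataFrame):
    """Covariate design: age (linear), sex (M=1), two disease-status dummies."""
    cov = np.column_stack([
        demo["age_years"].to_numpy(dtype=float),
        (demo["sex"] == "M").to_numpy(dtype=float),
        (demo["group"] == "patient_HS").to_numpy(dtype=float),
        (demo["group"] == "disease_control").to_numpy(dtype=float),
    ])
    names = ["age", "sex_M", "group_patient_HS", "group_disease_control"]
    return cov, names


class SingleSiteError(ValueError):
    """Raised when harmonization is requested with a single batch."""


class CombatHarmonizer(BaseEstimator, TransformerMixin):
    """Parametric empirical-Bayes ComBat over hemisphere-feature columns.

    ``fit(X)`` expects a DataFrame indexed by subject id containing the 10
    wide feature columns plus ``site_id``, ``age_years``, ``sex`` and
    ``group``.  ``transform`` adjusts rows of seen sites using the stored
    parameters only, so re-applying the model to its training rows reproduces
    the stored harmonized table.

    Parameters
    ----------
    enabled : bool
        ``False`` selects the no-op harmonization mode (identity transform);
        the pipeline is designed to run with and without harmonization.
    min_site_size : int
        Minimum subjects per site (default 20, the empirical-Bayes model's
        practical floor for stable site-scale estimates).
    unseen_site : {"error", "passthrough"}
        Behaviour when ``transform`` meets a site absent from training:
        raise, or pass features through unadjusted with a warning.

    Attributes
    ----------
    sites_, alpha_, beta_, var_pooled_, gamma_star_, delta_star_ :
        Fitted grand means, covariate coefficients, pooled residual
        variances, and per-site shrunken location/scale parameters.
    """

    def __init__(self, enabled: bool = True, min_site_size: int = MIN_SITE_SIZE,
                 unseen_site: str = "error"):
        self.enabled = enabled
        self.min_site_size = min_site_size
        self.unseen_site = unseen_site

    # -- empirical-Bayes machinery -------------------------------------------

    @staticmethod
    def _it_solve(z_batch, g_hat, d_hat, g_bar, t2, a_prior, b_prior,
                  conv: float = 1e-4, max_iter: int = 500):
        """Iterative posterior-mode estimates of site location/scale."""
        n = z_batch.shape[0]
        g_old, d_old = g_hat.copy(), d_hat.copy()
        for _ in range(max_iter):
            g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
            sum2 = ((z_batch - g_new) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
            change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        return g_old, d_old

    def fit(self, X: pd.DataFrame, y=None):
        if not self.enabled:
            self.sites_ = sorted(X["site_id"].unique())
            return self
        sites = sorted(X["site_id"].unique())
        if len(sites) < 2:
            raise SingleSiteError(
                "harmonization requires >= 2 sites; use CombatHarmonizer("
                "enabled=False) to run the pipeline without harmonization")
        counts = X["site_id"].value_counts()
        small = [s for s in sites if counts[s] < self.min_site_size]
        if small:
            raise ValueError(
                f"sites below the minimum of {self.min_site_size} subjects: {small}")
        Y = X[WIDE_COLUMNS].to_numpy(dtype=float)
        if not np.isfinite(Y).all():
            raise ValueError("non-finite feature values")
        sds = Y.std(axis=0)
        if (sds == 0).any():
            bad = [WIDE_COLUMNS[i] for i in np.flatnonzero(sds == 0)]
            raise ValueError(f"zero-variance feature columns: {bad}")
        n, p = Y.shape
        batch = pd.Categorical(X["site_id"], categories=sites).codes
        B = np.eye(len(sites))[batch]                       # (n, n_sites)
        C, self.covariate_names_ = _design_matrices(X)
        M = np.hstack([B, C])
        coef, *_ = np.linalg.lstsq(M, Y, rcond=None)
        n_b = len(sites)
        gamma_hat_ols = coef[:n_b]                          # per-site intercepts
        self.beta_ = coef[n_b:]                             # covariate effects
        frac = np.bincount(batch, minlength=n_b) / n
        self.alpha_ = frac @ gamma_hat_ols                  # size-weighted grand mean
        resid = Y - M @ coef
        self.var_pooled_ = (resid ** 2).mean(axis=0)
        stand_mean = self.alpha_ + C @ self.beta_
        Z = (Y - stand_mean) / np.sqrt(self.var_pooled_)

        gamma_hat = np.vstack([Z[batch == i].mean(axis=0) for i in range(n_b)])
        delta_hat = np.vstack([Z[batch == i].var(axis=0, ddof=1)
                               for i in range(n_b)])
        gamma_bar = gamma_hat.mean(axis=1)                  # prior over features
        t2 = gamma_hat.var(axis=1, ddof=1)
        m = delta_hat.mean(axis=1)
        s2 = delta_hat.var(axis=1, ddof=1)
        a_prior = (2 * s2 + m ** 2) / s2
        b_prior = (m * s2 + m ** 3) / s2

        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i in range(n_b):
            gamma_star[i], delta_star[i] = self._it_solve(
                Z[batch == i], gamma_hat[i], delta_hat[i],
                gamma_bar[i], t2[i], a_prior[i], b_prior[i])
        self.sites_ = sites
        self.gamma_star_ = gamma_star
        self.delta_star_ = delta_star
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "sites_")
        out = X.copy()
        if not self.enabled:
            return out
        unseen = sorted(set(X["site_id"]) - set(self.sites_))
        if unseen and self.unseen_site == "error":
            raise ValueError(
                f"sites not present at fit time: {unseen}; refit, or construct "
                "with unseen_site='passthrough' to leave them unadjusted")
        Y = X[WIDE_COLUMNS].to_numpy(dtype=float)
        C, _ = _design_matrices(X)
        stand_mean = self.alpha_ + C @ self.beta_
        Z = (Y - stand_mean) / np.sqrt(self.var_pooled_)
        adj = Y.copy()
        for i, site in enumerate(self.sites_):
            rows = (X["site_id"] == site).to_numpy()
            if not rows.any():
                continue
            z_adj = (Z[rows] - self.gamma_star_[i]) / np.sqrt(self.delta_star_[i])
            adj[rows] = z_adj * np.sqrt(self.var_pooled_) + stand_mean[rows]
        if unseen:
            logger.warning("passing through unharmonized sites: %s", unseen)
        out[WIDE_COLUMNS] = adj
        return out

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = {"version": 1, "enabled": self.enabled, "sites": self.sites_,
             "min_site_size": self.min_site_size, "unseen_site": self.unseen_site}
        if self.enabled:
            d.update(
                alpha=self.alpha_.tolist(), beta=self.beta_.tolist(),
                var_pooled=self.var_pooled_.tolist(),
                gamma_star=self.gamma_star_.tolist(),
                delta_star=self.delta_star_.tolist(),
                covariate_names=self.covariate_names_,
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CombatHarmonizer":
        obj = cls(enabled=d["enabled"], min_site_size=d["min_site_size"],
                  unseen_site=d["unseen_site"])
        obj.sites_ = list(d["sites"])
        if d["enabled"]:
            obj.alpha_ = np.array(d["alpha"])
            obj.beta_ = np.array(d["beta"])
            obj.var_pooled_ = np.array(d["var_pooled"])
            obj.gamma_star_ = np.array(d["gamma_star"])
            obj.delta_star_ = np.array(d["delta_star"])
            obj.covariate_names_ = list(d["covariate_names"])
        return obj


def fit_combat(features_wide: pd.DataFrame, **params):
    """Fit ComBat and return ``(model, harmonized_table)``."""
    model = CombatHarmonizer(**params)
    return model, model.fit(features_wide).transform(features_wide)


def apply_combat(model: CombatHarmonizer, features_wide: pd.DataFrame) -> pd.DataFrame:
    """Deterministically adjust new rows with a fitted model."""
    return model.transform(features_wide)


# -- asymmetry ---------------------------------------------------------------


def compute_asymmetry(wide_df: pd.DataFrame) -> pd.DataFrame:
    """Left-referenced asymmetry index ``2 (lh - rh) / (lh + rh)`` per feature.

    Returns a DataFrame indexed like ``wide_df`` with one column per scalar
    feature.  Raises if any denominator is non-positive, naming the feature
    and subject (positive-valued morphometry guarantees positivity).
    """
    out = {}
    for feat in SCALAR_FEATURES:
        lh = wide_df[f"{feat}_left"].to_numpy(dtype=float)
        rh = wide_df[f"{feat}_right"].to_numpy(dtype=float)
        denom = lh + rh
        bad = denom <= 0
        if bad.any():
            sid = wide_df.index[np.argmax(bad)]
            raise ValueError(
                f"non-positive lh+rh for feature {feat!r}, subject {sid!r}")
        out[feat] = 2.0 * (lh - rh) / denom
    return pd.DataFrame(out, index=wide_df.index)


class AsymmetryZScorer(BaseEstimator, TransformerMixin):
    """Z-score asymmetry indices by healthy-control mean and SD.

    ``fit`` consumes the raw asymmetries of the healthy controls of the
    training sample only (never disease controls, never patients) and stores
    per-feature ``mean_`` and ``std_`` (ddof=1); ``transform`` maps any
    subject's raw asymmetries to normalized asymmetries.
    """

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) < 2:
            raise ValueError("need >= 2 healthy controls to estimate asymmetry stats")
        vals = X[list(SCALAR_FEATURES)]
        self.mean_ = vals.mean(axis=0).to_numpy()
        self.std_ = vals.std(axis=0, ddof=1).to_numpy()
        tiny = 1e-12 + 1e-9 * np.abs(self.mean_)
        if (self.std_ <= tiny).any():
            bad = [f for f, s, t in zip(SCALAR_FEATURES, self.std_, tiny)
                   if s <= t]
            raise ValueError(f"zero asymmetry SD among controls for: {bad}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        vals = X[list(SCALAR_FEATURES)].to_numpy(dtype=float)
        return pd.DataFrame((vals - self.mean_) / self.std_,
                            index=X.index, columns=list(SCALAR_FEATURES))

    def to_dict(self) -> dict:
        return {"version": 1, "mean": self.mean_.tolist(),
                "std": self.std_.tolist(), "features": list(SCALAR_FEATURES)}

    @classmethod
    def from_dict(cls, d: dict) -> "AsymmetryZScorer":
        obj = cls()
        obj.mean_ = np.array(d["mean"])
        obj.std_ = np.array(d["std"])
        return obj


def fit_control_stats(control_asym: pd.DataFrame) -> AsymmetryZScorer:
    """Thin wrapper: fit the control-referenced z-scorer."""
    return AsymmetryZScorer().fit(control_asym)


def normalize_asymmetry(raw_asym: pd.DataFrame, stats: AsymmetryZScorer) -> pd.DataFrame:
    """Thin wrapper over :meth:`AsymmetryZScorer.transform`."""
    return stats.transform(raw_asym)
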