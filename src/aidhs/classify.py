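"""Detection and lateralization of hippocampal sclerosis from asymmetries.

A single multinomial logistic regression (lbfgs, balanced class weights)
maps the five normalized asymmetry features to scores over three classes,
``[S_LHS, S_RHS, S_noHS]``, which sum to 1.  Two decisions derive from the
scores:

    detection      = noHS  iff  S_noHS >= max(S_LHS, S_RHS), else HS
    lateralization = left  iff  S_LHS >= S_RHS, else right

Lateralization is defined for every subject regardless of the detection
outcome.  Evaluation uses leave-one-site-out cross-validation: one fold per
site, each fold refitting harmonization, control asymmetry statistics and
the classifier on the remaining sites only.  The fold models are averaged
(ensembled) into the final model applied to new subjects.  A univariate
logistic regression per feature supplies the interpretable left/right
abnormality thresholds shown in patient reports, and a volume-only
baseline with identical parametrization supports method comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .cohort_io import SCALAR_FEATURES
from .harmonize import (AsymmetryZScorer, CombatHarmonizer, WIDE_COLUMNS,
                        compute_asymmetry)

logger = logging.getLogger(__name__)

#: class order used everywhere: scores are [s_lhs, s_rhs, s_nohs]
CLASSES = ("left", "right", "none")
SCORE_COLUMNS = ("s_lhs", "s_rhs", "s_nohs")


class HSClassifier(ClassifierMixin, BaseEstimator):
    """Multinomial logistic classifier over the 5 normalized asymmetries.

    Multinomial loss, lbfgs solver, balanced class weights (inverse class
    frequency) to counter the unbalanced left/right/no-HS label mix; weak L2
    regularization (``C=1.0``) stabilizes small training folds and can be
    disabled with ``C=np.inf``.

    Attributes
    ----------
    coef_, intercept_ : fitted coefficient matrix and intercepts.
    classes_ : always ``("left", "right", "none")``.
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-6, max_iter: int = 1000):
        self.C = C
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if not np.isfinite(X).all():
            raise ValueError("non-finite asymmetry features")
        present = set(y)
        missing = set(CLASSES) - present
        if missing:
            raise ValueError(f"training labels missing classes: {sorted(missing)}")
        if present - set(CLASSES):
            raise ValueError(f"unknown labels: {sorted(present - set(CLASSES))}")
        self._lr = LogisticRegression(
            solver="lbfgs", class_weight="balanced", C=self.C,
            tol=self.tol, max_iter=self.max_iter)
        self._lr.fit(X, y)
        # reorder sklearn's alphabetical classes_ into (left, right, none)
        order = [list(self._lr.classes_).index(c) for c in CLASSES]
        self.coef_ = self._lr.coef_[order]
        self.intercept_ = self._lr.intercept_[order]
        self.classes_ = np.array(CLASSES, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Softmax scores ordered ``[s_lhs, s_rhs, s_nohs]``; rows sum to 1."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape}")
        logits = X @ self.coef_.T + self.intercept_
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        """Detection-aware class labels: 'left'/'right' when HS, else 'none'."""
        dec = decide_frame(self.predict_proba(X))
        out = np.where(dec["detection"] == "HS",
                       dec["lateralization"].to_numpy(), "none")
        return out.astype(object)

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {"version": 1, "C": self.C,
                "tol": self.tol, "max_iter": self.max_iter,
                "coef": self.coef_.tolist(), "intercept": self.intercept_.tolist(),
                "n_features_in": self.n_features_in_}

    @classmethod
    def from_dict(cls, d: dict) -> "HSClassifier":
        obj = cls(C=d["C"], tol=d["tol"], max_iter=d["max_iter"])
        obj.coef_ = np.array(d["coef"])
        obj.intercept_ = np.array(d["intercept"])
        obj.classes_ = np.array(CLASSES, dtype=object)
        obj.n_features_in_ = d["n_features_in"]
        return obj


def decide(s_lhs: float, s_rhs: float, s_nohs: float) -> tuple[str, str]:
    """Decision rules on one score triplet -> (detection, lateralization).

    Ties are resolved conservatively and logged: a subject whose no-HS score
    equals the best lateralized score is called noHS; equal left/right scores
    lateralize left.
    """
    if s_lhs == s_rhs:
        logger.warning("lateralization tie (s_lhs == s_rhs == %.6f); calling left", s_lhs)
    lat = "left" if s_lhs >= s_rhs else "right"
    det = "noHS" if s_nohs >= max(s_lhs, s_rhs) else "HS"
    return det, lat


def decide_frame(scores) -> pd.DataFrame:
    """Vectorized decision rules over an (n, 3) score array or DataFrame."""
    if isinstance(scores, pd.DataFrame):
        arr = scores[list(SCORE_COLUMNS)].to_numpy(dtype=float)
        index = scores.index
    else:
        arr = np.asarray(scores, dtype=float)
        index = None
    det = np.where(arr[:, 2] >= arr[:, :2].max(axis=1), "noHS", "HS")
    lat = np.where(arr[:, 0] >= arr[:, 1], "left", "right")
    return pd.DataFrame({"detection": det, "lateralization": lat}, index=index)


# -- abnormality thresholds --------------------------------------------------


def fit_abnormality_thresholds(z_asym: pd.DataFrame, labels) -> dict:
    """Per-feature left/right abnormality thresholds on the normalized axis.

    For each side, a univariate logistic regression separates patients of
    that side from all controls (healthy and disease); the threshold is the
    probability-0.5 boundary, ``-intercept / slope``.  Features without
    separation (|slope| ~ 0) get ``None`` and are flagged in the log.
    """
    labels = np.asarray(labels, dtype=object)
    out: dict[str, dict[str, float | None]] = {}
    for side in ("left", "right"):
        mask = (labels == side) | (labels == "none")
        y = (labels[mask] == side).astype(float)
        if len(np.unique(y)) < 2:
            logger.warning("no %s-HS patients; thresholds undefined", side)
            out[side] = {feat: None for feat in SCALAR_FEATURES}
            continue
        th = {}
        for feat in SCALAR_FEATURES:
            x = z_asym.loc[mask, feat].to_numpy(dtype=float)[:, None]
            lr = LogisticRegression(solver="lbfgs", C=1e6, max_iter=1000)
            lr.fit(x, y)
            slope = float(lr.coef_[0, 0])
            if abs(slope) < 1e-8:
                logger.warning("no separation for %s-HS on %s; threshold undefined",
                               side, feat)
                th[feat] = None
            else:
                th[feat] = float(-lr.intercept_[0] / slope)
        out[side] = th
    return out


# -- fold and ensemble models -------------------------------------------------


@dataclass
class FoldModel:
    """One LOSO fold: harmonization + control stats + classifier + thresholds.

    Each fold owns its preprocessing state so that applying the fold to a
    new subject reuses exactly the statistics estimated on its training
    sites (the held-out site never contributes).
    """

    classifier: HSClassifier
    harmonizer: CombatHarmonizer
    zscorer: AsymmetryZScorer
    thresholds: dict
    train_sites: list
    test_site: str | None = None
    feature_cols: list = field(default_factory=lambda: list(SCALAR_FEATURES))

    def transform(self, features_wide: pd.DataFrame) -> pd.DataFrame:
        """Raw wide features (+ demographics columns) -> normalized asymmetries."""
        harm = self.harmonizer.transform(features_wide)
        return self.zscorer.transform(compute_asymmetry(harm))

    def predict_scores(self, features_wide: pd.DataFrame) -> pd.DataFrame:
        z = self.transform(features_wide)
        proba = self.classifier.predict_proba(z[self.feature_cols].to_numpy())
        return pd.DataFrame(proba, index=features_wide.index,
                            columns=list(SCORE_COLUMNS))

    def to_dict(self) -> dict:
        return {"version": 1, "classifier": self.classifier.to_dict(),
                "harmonizer": self.harmonizer.to_dict(),
                "zscorer": self.zscorer.to_dict(), "thresholds": self.thresholds,
                "train_sites": list(self.train_sites), "test_site": self.test_site,
                "feature_cols": list(self.feature_cols)}

    @classmethod
    def from_dict(cls, d: dict) -> "FoldModel":
        return cls(HSClassifier.from_dict(d["classifier"]),
                   CombatHarmonizer.from_dict(d["harmonizer"]),
                   AsymmetryZScorer.from_dict(d["zscorer"]),
                   d["thresholds"], d["train_sites"], d["test_site"],
                   list(d.get("feature_cols", SCALAR_FEATURES)))


@dataclass
class AidHsEnsemble:
    """Ensemble of LOSO fold models: mean of fold probabilities, renormalized."""

    folds: list = field(default_factory=list)

    def predict_scores(self, features_wide: pd.DataFrame) -> pd.DataFrame:
        if not self.folds:
            raise ValueError("empty ensemble")
        acc = sum(f.predict_scores(features_wide).to_numpy() for f in self.folds)
        acc = acc / len(self.folds)
        acc = acc / acc.sum(axis=1, keepdims=True)
        return pd.DataFrame(acc, index=features_wide.index,
                            columns=list(SCORE_COLUMNS))

    def predict(self, features_wide: pd.DataFrame) -> pd.DataFrame:
        scores = self.predict_scores(features_wide)
        return pd.concat([scores, decide_frame(scores)], axis=1)

    @property
    def thresholds(self) -> dict:
        """Average the fold thresholds feature-wise (None propagates)."""
        out: dict[str, dict[str, float | None]] = {}
        for side in ("left", "right"):
            out[side] = {}
            for feat in SCALAR_FEATURES:
                vals = [f.thresholds[side][feat] for f in self.folds]
                out[side][feat] = (None if any(v is None for v in vals)
                                   else float(np.mean(vals)))
        return out

    def to_dict(self) -> dict:
        return {"version": 1, "folds": [f.to_dict() for f in self.folds]}

    @classmethod
    def from_dict(cls, d: dict) -> "AidHsEnsemble":
        return cls([FoldModel.from_dict(f) for f in d["folds"]])


# -- training ------------------------------------------------------------------


def _ensure_demo(fw: pd.DataFrame, demo: pd.DataFrame) -> pd.DataFrame:
    """Attach site/age/sex/group columns unless already present."""
    need = [c for c in ("site_id", "age_years", "sex", "group")
            if c not in fw.columns]
    return fw.join(demo[need]) if need else fw


def class_labels(demo: pd.DataFrame) -> np.ndarray:
    """Map demographics to classifier labels: patients by side, controls 'none'.

    Bilateral patients get the label 'bilateral' and must be excluded from
    training by the caller (they pass through prediction only).
    """
    lab = np.where(demo["group"] == "patient_HS",
                   demo["lateralization"].to_numpy(), "none")
    return lab.astype(object)


def fit_fold(features_wide: pd.DataFrame, demo: pd.DataFrame,
             harmonize: bool = True, test_site: str | None = None,
             feature_mode: str = "asymmetry", **clf_params) -> FoldModel:
    """Fit one fold on training rows only (bilateral patients dropped).

    ``feature_mode`` selects the classifier inputs: ``"asymmetry"`` (the five
    normalized asymmetries, the full model) or ``"volume"`` (the volume
    asymmetry only — the preprocessed volumetric baseline).
    """
    demo = demo.loc[features_wide.index]
    keep = demo["lateralization"] != "bilateral"
    fw, dm = features_wide[keep], demo[keep]
    harmonizer = CombatHarmonizer(enabled=harmonize, unseen_site="passthrough")
    merged = _ensure_demo(fw, dm)
    harm = harmonizer.fit(merged).transform(merged)
    asym = compute_asymmetry(harm)
    controls = asym[dm["group"] == "healthy_control"]
    zscorer = AsymmetryZScorer().fit(controls)
    z = zscorer.transform(asym)
    labels = class_labels(dm)
    thresholds = fit_abnormality_thresholds(z, labels)
    cols = list(SCALAR_FEATURES) if feature_mode == "asymmetry" else ["volume"]
    clf = HSClassifier(**clf_params).fit(z[cols].to_numpy(), labels)
    return FoldModel(clf, harmonizer, zscorer, thresholds,
                     sorted(dm["site_id"].unique()), test_site, cols)


def loso_cv(features_wide: pd.DataFrame, demo: pd.DataFrame,
            harmonize: bool = True, feature_mode: str = "asymmetry",
            **clf_params):
    """Leave-one-site-out cross-validation.

    Returns ``(predictions, ensemble)``: one out-of-fold score/decision row
    per subject (bilateral patients included, scored by the fold of their
    site) and the ensemble of fold models.  Per-fold harmonization and
    control asymmetry statistics are refit within each training fold; the
    held-out site's rows never enter fold fitting and are passed through
    harmonization unadjusted at prediction time.
    """
    demo = demo.loc[features_wide.index]
    sites = sorted(demo["site_id"].unique())
    if len(sites) < 2:
        raise ValueError("leave-one-site-out needs >= 2 sites")
    preds, folds = [], []
    for site in sites:
        train_ids = demo.index[demo["site_id"] != site]
        test_ids = demo.index[demo["site_id"] == site]
        tr_demo = demo.loc[train_ids]
        if not (tr_demo["group"] == "healthy_control").any():
            raise ValueError(f"fold excluding {site!r} has no healthy controls")
        fold = fit_fold(features_wide.loc[train_ids], tr_demo,
                        harmonize=harmonize, test_site=site,
                        feature_mode=feature_mode, **clf_params)
        folds.append(fold)
        test_merged = _ensure_demo(features_wide.loc[test_ids], demo.loc[test_ids])
        sc = fold.predict_scores(test_merged)
        preds.append(pd.concat([sc, decide_frame(sc)], axis=1))
    predictions = pd.concat(preds).loc[demo.index]
    return predictions, AidHsEnsemble(folds)


def fit_volume_baseline(features_wide: pd.DataFrame, demo: pd.DataFrame,
                        **kwargs):
    """Volume-only baseline under the identical LOSO protocol."""
    return loso_cv(features_wide, demo, feature_mode="volume", **kwargs)
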