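"""Classifier performance metrics and group-level statistics.

Detection sensitivity is the fraction of unilateral HS patients decided HS;
lateralization sensitivity the fraction of unilateral patients whose side is
called correctly (lateralization is evaluated for every patient, whatever the
detection outcome); specificity the fraction of controls decided noHS.
Performance is broken down by clinical strata, with a multivariable logistic
regression on per-subject correctness to test each factor.  Group contrasts
of normalized asymmetries use Shapiro-Wilk-gated Welch t or Mann-Whitney
tests with Holm correction, and the cohort-description sex-by-group
association uses a Pearson chi-square without continuity correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort_io import SCALAR_FEATURES

logger = logging.getLogger(__name__)

ADULT_AGE = 18.0  # adults >= 18 years, children < 18


def _is_unilateral(demo: pd.DataFrame) -> pd.Series:
    return (demo["group"] == "patient_HS") & demo["lateralization"].isin(
        ["left", "right"])


def performance(predictions: pd.DataFrame, demo: pd.DataFrame) -> dict:
    """Overall detection/lateralization sensitivity and specificity (%).

    ``predictions`` must carry ``detection`` and ``lateralization`` columns
    for every subject in ``demo``; a missing prediction is an error.
    """
    missing = [s for s in demo.index if s not in predictions.index]
    if missing:
        raise ValueError(f"subjects without predictions: {missing[:5]}")
    pred = predictions.loc[demo.index]
    uni = _is_unilateral(demo)
    ctrl = demo["group"] != "patient_HS"
    det = (pred.loc[uni, "detection"] == "HS").mean() * 100 if uni.any() else np.nan
    lat = (pred.loc[uni, "lateralization"]
           == demo.loc[uni, "lateralization"]).mean() * 100 if uni.any() else np.nan
    spec = (pred.loc[ctrl, "detection"] == "noHS").mean() * 100 if ctrl.any() else np.nan
    return {
        "n_patients": int(uni.sum()), "n_controls": int(ctrl.sum()),
        "detection_sensitivity_pct": float(det),
        "lateralization_sensitivity_pct": float(lat),
        "specificity_pct": float(spec),
    }


def performance_table(predictions: pd.DataFrame, demo: pd.DataFrame) -> pd.DataFrame:
    """Stratified breakdown of patient performance (age group, sex, MRI
    status, histology, outcome, isotropic resolution where available)."""
    pred = predictions.loc[demo.index]
    uni = _is_unilateral(demo)
    pat, pp = demo[uni], pred[uni]
    strata = {
        "age_group": np.where(pat["age_years"] >= ADULT_AGE, "adults", "children"),
        "sex": pat["sex"],
    }
    for col in ("mri_negative", "histology", "good_outcome", "isotropic"):
        if col in pat.columns and pat[col].notna().any():
            strata[col] = pat[col].astype(object).where(pat[col].notna(), "unknown")
    rows = []
    for factor, levels in strata.items():
        levels = pd.Series(np.asarray(levels, dtype=object), index=pat.index)
        for lev in pd.unique(levels):
            m = levels == lev
            rows.append({
                "factor": factor, "level": str(lev), "n": int(m.sum()),
                "detection_pct": float((pp.loc[m, "detection"] == "HS").mean() * 100),
                "lateralization_pct": float(
                    (pp.loc[m, "lateralization"]
                     == pat.loc[m, "lateralization"]).mean() * 100),
            })
    return pd.DataFrame(rows)


def stratified_regression(correct: pd.Series, factors: pd.DataFrame) -> pd.DataFrame:
    """Multivariable logistic regression of correctness on clinical factors.

    One column per factor; string/categorical factors are dummy-coded against
    their first (alphabetical) level.  Under complete separation or constant
    outcome the affected coefficients are reported as non-converged
    (``converged=False``, ``p_value=NaN``) rather than fabricated.
    """
    y = np.asarray(correct, dtype=float)
    X = pd.get_dummies(factors, drop_first=True, dtype=float)
    X = sm.add_constant(X, has_constant="add")
    if len(np.unique(y)) < 2:
        out = pd.DataFrame({"term": X.columns, "coef": np.nan, "p_value": np.nan,
                            "converged": False})
        logger.warning("constant correctness outcome; intercept-only model")
        return out
    try:
        res = sm.Logit(y, X.to_numpy(dtype=float)).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        coefs, pvals = res.params, res.pvalues
    except (PerfectSeparationError, np.linalg.LinAlgError):
        converged, coefs, pvals = False, np.full(X.shape[1], np.nan), np.full(X.shape[1], np.nan)
    # flag individual runaway coefficients (separation) without hiding them
    flagged = (not converged) or np.any(np.abs(coefs) > 20)
    if flagged:
        logger.warning("possible separation in stratified regression")
    return pd.DataFrame({"term": X.columns, "coef": coefs, "p_value": pvals,
                         "converged": converged})


def asymmetry_group_tests(z_asym: pd.DataFrame, demo: pd.DataFrame,
                          seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Ipsilateral patient asymmetries vs healthy and disease controls.

    The patient value per feature is the normalized asymmetry referenced to
    the ipsilateral hemisphere (the left-referenced index, sign-flipped for
    right-HS before z-scoring against the same control statistics); controls
    contribute one hemisphere each, drawn at random under ``seed``.  Each
    group pair per feature is tested with Welch's t when both samples pass
    Shapiro-Wilk normality (p >= 0.05), otherwise Mann-Whitney; p-values are
    Holm-corrected across all tests.
    """
    demo = demo.loc[z_asym.index]
    rng = np.random.default_rng(seed)

    def signed(rows: pd.DataFrame, signs: np.ndarray) -> pd.DataFrame:
        return rows.mul(signs, axis=0)

    uni = _is_unilateral(demo)
    pat_sign = np.where(demo.loc[uni, "lateralization"] == "left", 1.0, -1.0)
    groups = {"patients_ipsi": signed(z_asym[uni], pat_sign)}
    for gname, key in (("healthy_controls", "healthy_control"),
                       ("disease_controls", "disease_control")):
        m = demo["group"] == key
        signs = rng.choice([1.0, -1.0], size=int(m.sum()))
        groups[gname] = signed(z_asym[m], signs)
    for gname, g in groups.items():
        if len(g) < 3:
            raise ValueError(f"group {gname} has fewer than 3 subjects")

    pairs = [("patients_ipsi", "healthy_controls"),
             ("patients_ipsi", "disease_controls"),
             ("healthy_controls", "disease_controls")]
    rows = []
    for a, b in pairs:
        for feat in SCALAR_FEATURES:
            xa = groups[a][feat].to_numpy()
            xb = groups[b][feat].to_numpy()
            normal = (stats.shapiro(xa).pvalue >= alpha
                      and stats.shapiro(xb).pvalue >= alpha)
            if normal:
                test, p = "welch_t", stats.ttest_ind(xa, xb, equal_var=False).pvalue
            else:
                test, p = "mann_whitney", stats.mannwhitneyu(
                    xa, xb, alternative="two-sided").pvalue
            rows.append({"group_a": a, "group_b": b, "feature": feat,
                         "test": test, "p_raw": float(p),
                         "median_a": float(np.median(xa)),
                         "median_b": float(np.median(xb))})
    table = pd.DataFrame(rows)
    rej, p_adj, *_ = multipletests(table["p_raw"], alpha=alpha, method="holm")
    table["p_holm"] = p_adj
    table["significant"] = rej
    return table


def contingency_chisq(table: np.ndarray):
    """Pearson chi-square (no continuity correction) on an r x c count table.

    Returns ``(statistic, df, p_value)``; zero marginals are an error.
    """
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(table, correction=False)
    return float(res[0]), int(res[2]), float(res[1])


def sex_by_group_counts(demo: pd.DataFrame) -> pd.DataFrame:
    """3 x 2 sex-by-disease-status count table (patients/disease/healthy)."""
    order = ["patient_HS", "disease_control", "healthy_control"]
    tab = pd.crosstab(demo["group"], demo["sex"]).reindex(order)
    return tab[["M", "F"]]
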