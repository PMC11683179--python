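"""End-to-end orchestration: cohort -> features -> LOSO-trained model.

Thin glue over the stage modules so the CLI, tests and scripts share one
code path: preprocess vertex maps to per-hemisphere scalars, run the
leave-one-site-out evaluation, fit the deployment ensemble and the normative
growth charts (on the harmonized healthy controls of the whole cohort), and
bundle everything into one serializable model document.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .classify import AidHsEnsemble, loso_cv
from .cohort_io import Cohort
from .harmonize import CombatHarmonizer, to_long, to_wide
from .normative import NormativeGrowthChart
from .preprocess import SurfacePreprocessor
from .evaluate import performance

DEMO_COLS = ["site_id", "age_years", "sex", "group"]


def preprocess_to_wide(cohort: Cohort, **params) -> pd.DataFrame:
    """Vertex maps -> wide per-subject feature table merged with covariates."""
    long_df = SurfacePreprocessor(**params).fit_transform(cohort)
    wide = to_wide(long_df)
    return wide.join(cohort.subjects[DEMO_COLS])


def fit_normative_on_controls(wide_merged: pd.DataFrame, demo: pd.DataFrame,
                              harmonize: bool = True) -> NormativeGrowthChart:
    """Growth charts from the harmonized healthy controls (hemispheres pooled)."""
    harmonizer = CombatHarmonizer(enabled=harmonize, unseen_site="passthrough")
    harmonized = harmonizer.fit(wide_merged).transform(wide_merged)
    ctrl = harmonized[demo.loc[harmonized.index, "group"] == "healthy_control"]
    long = to_long(ctrl, stage="harmonized").set_index("subject_id")
    long = long.join(demo[["age_years", "sex"]])
    return NormativeGrowthChart().fit(long)


def train_aidhs(cohort: Cohort, harmonize: bool = True, **clf_params) -> dict:
    """Full training run on a cohort; returns models, predictions, metrics."""
    wide_merged = preprocess_to_wide(cohort)
    predictions, ensemble = loso_cv(wide_merged, cohort.subjects,
                                    harmonize=harmonize, **clf_params)
    normative = fit_normative_on_controls(wide_merged, cohort.subjects,
                                          harmonize=harmonize)
    perf = performance(predictions, cohort.subjects)
    return {
        "features": wide_merged,
        "predictions": predictions,
        "ensemble": ensemble,
        "normative": normative,
        "performance": perf,
    }


def save_model_bundle(path: str | Path, ensemble: AidHsEnsemble,
                      normative: NormativeGrowthChart) -> None:
    doc = {"version": 1, "ensemble": ensemble.to_dict(),
           "normative": normative.to_dict()}
    Path(path).write_text(json.dumps(doc))


def load_model_bundle(path: str | Path):
    doc = json.loads(Path(path).read_text())
    return (AidHsEnsemble.from_dict(doc["ensemble"]),
            NormativeGrowthChart.from_dict(doc["normative"]))
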