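"""Individualized, interpretable patient reports.

Each report combines four panels: segmentation QC (Dice per hemisphere with
the 0.7 review flag), normative placement (each feature of each hippocampus
against the 5/25/75/95 centile bands of the growth charts), asymmetry bars
against the left/right abnormality thresholds, and the classifier scores with
the detection/lateralization decisions (probabilities shown as percentages to
one decimal).  The report structure is a pure function of its inputs and is
written as a JSON sidecar plus a human-readable HTML page.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cohort_io import SCALAR_FEATURES
from .classify import AidHsEnsemble, decide
from .normative import NormativeGrowthChart

CENTILE_BANDS = (5, 25, 75, 95)
DICE_REVIEW_THRESHOLD = 0.7

FEATURE_LABELS = {
    "volume": "Volume (mm³)", "thickness": "Thickness (mm)",
    "gyrification": "Gyrification", "curv_mean": "Mean curvature (mm⁻¹)",
    "curv_intrinsic": "Intrinsic curvature (mm⁻²)",
}


def build_report(subject_id: str, demo_row: pd.Series, qc_row: pd.Series,
                 features_row: pd.DataFrame, normative: NormativeGrowthChart,
                 ensemble: AidHsEnsemble) -> dict:
    """Assemble the machine-readable report for one subject.

    ``features_row`` is the one-row wide feature table (raw stage) merged
    with the ``site_id``/``age_years``/``sex``/``group`` columns so each
    fold can apply its own harmonization state.  Raises ``KeyError`` naming
    the missing component if a model piece is absent.
    """
    for name, obj in (("normative model", normative), ("ensemble", ensemble)):
        if obj is None:
            raise KeyError(f"missing model component: {name}")
    if not ensemble.folds:
        raise KeyError("missing model component: ensemble folds")
    age = float(demo_row["age_years"])
    sex = str(demo_row["sex"])

    scores = ensemble.predict_scores(features_row).iloc[0]
    det, lat = decide(scores["s_lhs"], scores["s_rhs"], scores["s_nohs"])

    # fold-averaged normalized asymmetries (each fold owns its own stats)
    z = np.mean([f.transform(features_row).iloc[0].to_numpy()
                 for f in ensemble.folds], axis=0)
    z = pd.Series(z, index=list(SCALAR_FEATURES))
    thresholds = ensemble.thresholds

    normative_section = {}
    for feat in SCALAR_FEATURES:
        per_hemi = {}
        for hemi in ("left", "right"):
            val = float(features_row[f"{feat}_{hemi}"].iloc[0])
            pct = float(normative.percentile_score(feat, val, age, sex, clip=True))
            per_hemi[hemi] = {"value": val, "percentile": pct,
                              "band": _band_label(pct)}
        normative_section[feat] = per_hemi

    asym_section = {}
    for feat in SCALAR_FEATURES:
        thr_l = thresholds["left"][feat]
        thr_r = thresholds["right"][feat]
        asym_section[feat] = {
            "normalized_asymmetry": float(z[feat]),
            "threshold_left": thr_l, "threshold_right": thr_r,
            "flag": _asymmetry_flag(float(z[feat]), thr_l, thr_r),
        }

    dice_l, dice_r = float(qc_row["dice_left"]), float(qc_row["dice_right"])
    return {
        "version": 1,
        "subject_id": str(subject_id),
        "age_years": age,
        "sex": sex,
        "qc": {
            "dice_left": dice_l, "dice_right": dice_r,
            "passed": bool(qc_row.get("passed", True)),
            "below_threshold": bool(min(dice_l, dice_r) < DICE_REVIEW_THRESHOLD),
        },
        "normative": normative_section,
        "asymmetry": asym_section,
        "classifier": {
            "s_lhs_pct": round(float(scores["s_lhs"]) * 100, 1),
            "s_rhs_pct": round(float(scores["s_rhs"]) * 100, 1),
            "s_nohs_pct": round(float(scores["s_nohs"]) * 100, 1),
            "detection": det,
            "lateralization": lat,
        },
    }


def _band_label(pct: float) -> str:
    if pct < 5:
        return "<5th"
    if pct > 95:
        return ">95th"
    if pct < 25:
        return "5th-25th"
    if pct > 75:
        return "75th-95th"
    return "25th-75th"


def _asymmetry_flag(z: float, thr_l, thr_r) -> str:
    """Which side's abnormality threshold (if any) the asymmetry breaches."""
    def beyond(value, thr):
        if thr is None:
            return False
        return value <= thr if thr < 0 else value >= thr
    if beyond(z, thr_l):
        return "left"
    if beyond(z, thr_r):
        return "right"
    return "none"


# -- rendering ----------------------------------------------------------------


def render_report(report: dict, out_dir: str | Path, fmt: str = "both",
                  normative: NormativeGrowthChart | None = None) -> list:
    """Write ``<subject_id>_aidhs_report.{json,html}``; returns written paths.

    JSON rendering is byte-deterministic for a given report; the HTML page
    embeds one growth-chart SVG per feature plus asymmetry and score panels
    (centile bands are drawn when the fitted ``normative`` model is given).
    """
    if fmt not in ("json", "html", "both"):
        raise ValueError(f"unknown report format: {fmt!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = report["subject_id"]
    written = []
    if fmt in ("json", "both"):
        p = out / f"{sid}_aidhs_report.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(p)
    if fmt in ("html", "both"):
        p = out / f"{sid}_aidhs_report.html"
        p.write_text(_render_html(report, normative))
        written.append(p)
    return written


def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    with plt.rc_context({"svg.hashsalt": "aidhs"}):
        fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    svg = buf.getvalue()
    return svg[svg.index("<svg"):]


def _growth_chart_svg(report: dict, feat: str,
                      normative: NormativeGrowthChart | None) -> str:
    fig, ax = plt.subplots(figsize=(3.2, 2.4), dpi=80)
    sex = report["sex"]
    if normative is not None:
        grid = normative.age_grid_
        c = {p: normative.centile_curve(feat, sex, p)["value"].to_numpy()
             for p in (5, 25, 50, 75, 95)}
        ax.fill_between(grid, c[5], c[95], color="#c8e6c9", lw=0)
        ax.fill_between(grid, c[25], c[75], color="#81c784", lw=0)
        ax.plot(grid, c[50], color="#2e7d32", lw=1)
    for hemi, marker, color in (("left", "o", "#1565c0"), ("right", "s", "#c62828")):
        ax.plot([report["age_years"]], [report["normative"][feat][hemi]["value"]],
                marker, color=color, ms=5, label=hemi)
    ax.set_xlabel("age (years)", fontsize=7)
    ax.set_title(FEATURE_LABELS[feat], fontsize=8)
    ax.tick_params(labelsize=6)
    ax.legend(fontsize=6, frameon=False)
    fig.tight_layout()
    return _fig_to_svg(fig)


def _asymmetry_svg(report: dict) -> str:
    fig, ax = plt.subplots(figsize=(4.2, 2.6), dpi=80)
    feats = list(SCALAR_FEATURES)
    zs = [report["asymmetry"][f]["normalized_asymmetry"] for f in feats]
    ypos = np.arange(len(feats))
    ax.barh(ypos, zs, color=["#c62828" if report["asymmetry"][f]["flag"] != "none"
                             else "#90a4ae" for f in feats])
    for k, f in enumerate(feats):
        for key, color in (("threshold_left", "#1565c0"), ("threshold_right", "#ef6c00")):
            thr = report["asymmetry"][f][key]
            if thr is not None:
                ax.plot([thr, thr], [k - 0.4, k + 0.4], color=color, lw=1)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_yticks(ypos, feats, fontsize=6)
    ax.set_xlabel("normalized asymmetry (z)", fontsize=7)
    ax.tick_params(labelsize=6)
    fig.tight_layout()
    return _fig_to_svg(fig)


def _scores_svg(report: dict) -> str:
    fig, ax = plt.subplots(figsize=(3.2, 1.8), dpi=80)
    cls = report["classifier"]
    names = ["left HS", "right HS", "no HS"]
    vals = [cls["s_lhs_pct"], cls["s_rhs_pct"], cls["s_nohs_pct"]]
    ax.barh(range(3), vals, color=["#1565c0", "#ef6c00", "#607d8b"])
    for k, v in enumerate(vals):
        ax.text(v + 1, k, f"{v:.1f}%", fontsize=7, va="center")
    ax.set_yticks(range(3), names, fontsize=7)
    ax.set_xlim(0, 115)
    ax.set_xticks([0, 50, 100])
    ax.tick_params(labelsize=6)
    fig.tight_layout()
    return _fig_to_svg(fig)


def _render_html(report: dict, normative: NormativeGrowthChart | None = None) -> str:
    qc = report["qc"]
    cls = report["classifier"]
    qc_flag = (" — below 0.7, visual review required"
               if qc["below_threshold"] else "")
    charts = "\n".join(
        f'<div class="chart" id="chart-{feat}">{_growth_chart_svg(report, feat, normative)}</div>'
        for feat in SCALAR_FEATURES)
    rows = "\n".join(
        "<tr><td>{f}</td><td>{lv:.4g}</td><td>{lp:.1f}</td><td>{lb}</td>"
        "<td>{rv:.4g}</td><td>{rp:.1f}</td><td>{rb}</td></tr>".format(
            f=FEATURE_LABELS[f],
            lv=report["normative"][f]["left"]["value"],
            lp=report["normative"][f]["left"]["percentile"],
            lb=report["normative"][f]["left"]["band"],
            rv=report["normative"][f]["right"]["value"],
            rp=report["normative"][f]["right"]["percentile"],
            rb=report["normative"][f]["right"]["band"])
        for f in SCALAR_FEATURES)
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8">
<title>AID-HS report — {report['subject_id']}</title>
<style>body{{font-family:sans-serif;margin:2em}} .chart{{display:inline-block}}
table{{border-collapse:collapse}} td,th{{border:1px solid #ccc;padding:2px 8px;font-size:12px}}</style>
</head><body>
<h1>Hippocampal report — {report['subject_id']}</h1>
<p>Age {report['age_years']:.1f} y, sex {report['sex']}</p>
<h2>Segmentation quality</h2>
<p>Dice left {qc['dice_left']:.2f}, right {qc['dice_right']:.2f}{qc_flag}</p>
<h2>Normative placement</h2>
<table><tr><th>feature</th><th>left</th><th>centile</th><th>band</th>
<th>right</th><th>centile</th><th>band</th></tr>
{rows}</table>
{charts}
<h2>Asymmetries vs abnormality thresholds</h2>
<div class="chart" id="chart-asymmetry">{_asymmetry_svg(report)}</div>
<h2>Classifier scores</h2>
<div class="chart" id="chart-scores">{_scores_svg(report)}</div>
<p>Detection: <b>{cls['detection']}</b> — lateralization: <b>{cls['lateralization']}</b>
(left HS {cls['s_lhs_pct']:.1f}%, right HS {cls['s_rhs_pct']:.1f}%, no HS {cls['s_nohs_pct']:.1f}%)</p>
</body></html>
"""
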