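"""Cohort data model, readers/writers and segmentation quality control.

The pipeline consumes the outputs of a hippocampal surface-segmentation tool:
per-vertex metric maps (thickness, gyrification, mean and intrinsic curvature)
on a fixed-topology mid-thickness surface with an anterior-posterior (AP)
coordinate, per-hemisphere total volumes, per-hemisphere Dice segmentation-QC
scores, and a demographics table.  Everything here is deliberately format-thin:
demographics/volumes/QC travel as CSV, surfaces and vertex metrics either as
GIFTI (``.surf.gii`` / ``.shape.gii``, the upstream tool's native dialect) or
as wide CSV tables (one row per subject, one column per vertex).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

#: surface-based features carried per vertex
VERTEX_FEATURES = ("thickness", "gyrification", "curv_mean", "curv_intrinsic")
#: the five per-hemisphere scalar features used by the classifier
SCALAR_FEATURES = ("volume", "thickness", "gyrification", "curv_mean", "curv_intrinsic")
HEMISPHERES = ("left", "right")

GROUPS = ("patient_HS", "disease_control", "healthy_control")
LATERALIZATIONS = ("left", "right", "bilateral", "none")
MIN_AGE_YEARS = 3.0  # cohort inclusion: participants older than 3 years

DEMOGRAPHICS_COLUMNS = [
    "subject_id", "site_id", "group", "lateralization", "age_years", "sex",
    "mri_negative", "histology", "good_outcome", "icv_mm3", "scan_field",
    "isotropic",
]
REQUIRED_DEMOGRAPHICS = DEMOGRAPHICS_COLUMNS[:6]


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class FormatError(ValueError):
    """A data file is inconsistent with the reference surface topology."""


@dataclass
class HippSurface:
    """Fixed-topology hippocampal mid-thickness mesh.

    Parameters
    ----------
    coords : (n_vertices, 3) float array, mm
    faces : (n_faces, 3) int array of triangle vertex indices
    ap_coord : (n_vertices,) float array in [0, 1], anterior -> posterior
        position of each vertex in the unfolded coordinate system.
    """

    coords: np.ndarray
    faces: np.ndarray
    ap_coord: np.ndarray
    _adjacency: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.ap_coord = np.asarray(self.ap_coord, dtype=float)
        n = self.n_vertices
        if self.ap_coord.shape != (n,):
            raise FormatError("ap_coord length does not match vertex count")
        referenced = np.unique(self.faces)
        if referenced.size != n or referenced.min() != 0 or referenced.max() != n - 1:
            raise FormatError("every vertex must be referenced by at least one face")
        if self.ap_coord.min() < 0 or self.ap_coord.max() > 1:
            raise FormatError("ap_coord must lie in [0, 1]")

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (n_edges, 2) index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [0, 2]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def adjacency(self) -> sparse.csr_matrix:
        """Sparse symmetric 1-ring adjacency with edge lengths as weights."""
        if self._adjacency is None:
            e = self.edges()
            d = np.linalg.norm(self.coords[e[:, 0]] - self.coords[e[:, 1]], axis=1)
            n = self.n_vertices
            m = sparse.coo_matrix(
                (np.r_[d, d], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
                shape=(n, n))
            self._adjacency = m.tocsr()
        return self._adjacency

    def save(self, path: str | Path) -> None:
        """Write as a GIFTI surface with the AP coordinate as a shape array."""
        img = nib.gifti.GiftiImage()
        img.add_gifti_data_array(nib.gifti.GiftiDataArray(
            self.coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"))
        img.add_gifti_data_array(nib.gifti.GiftiDataArray(
            self.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"))
        img.add_gifti_data_array(nib.gifti.GiftiDataArray(
            self.ap_coord.astype(np.float32), intent="NIFTI_INTENT_SHAPE"))
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "HippSurface":
        img = nib.load(str(path))
        coords = faces = ap = None
        for da in img.darrays:
            if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                coords = np.asarray(da.data, dtype=float)
            elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = np.asarray(da.data, dtype=int)
            elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_SHAPE"]:
                ap = np.asarray(da.data, dtype=float)
        if coords is None or faces is None or ap is None:
            raise FormatError(f"{path}: missing pointset/triangle/shape array")
        return cls(coords, faces, ap)


@dataclass
class Cohort:
    """In-memory cohort: demographics, surface, vertex maps, volumes, QC.

    ``subjects`` is indexed by subject id with the demographics columns;
    ``vertex_data[(hemisphere, feature)]`` is an (n_subjects, n_vertices)
    array row-aligned with ``subjects``; ``volumes`` has columns ``left`` and
    ``right`` (mm^3); ``qc`` has ``dice_left``, ``dice_right``, ``passed``.
    """

    subjects: pd.DataFrame
    surface: HippSurface
    vertex_data: dict
    volumes: pd.DataFrame
    qc: pd.DataFrame

    @property
    def subject_ids(self) -> list:
        return list(self.subjects.index)

    def __len__(self) -> int:
        return len(self.subjects)

    def subset(self, ids) -> "Cohort":
        """Row-subset every table to ``ids`` (order preserved)."""
        ids = list(ids)
        pos = [self.subjects.index.get_loc(i) for i in ids]
        vd = {k: v[pos] for k, v in self.vertex_data.items()}
        return Cohort(self.subjects.loc[ids].copy(), self.surface, vd,
                      self.volumes.loc[ids].copy(), self.qc.loc[ids].copy())


def validate_subjects(df: pd.DataFrame) -> None:
    """Check the demographics invariants; raise ``SchemaError`` on violation."""
    for col in REQUIRED_DEMOGRAPHICS:
        if col != "subject_id" and col not in df.columns:
            raise SchemaError(f"demographics missing required column: {col!r}")
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise SchemaError(f"unknown group values: {sorted(bad_group)}")
    bad_lat = set(df["lateralization"]) - set(LATERALIZATIONS)
    if bad_lat:
        raise SchemaError(f"unknown lateralization values: {sorted(bad_lat)}")
    if (df["age_years"] <= MIN_AGE_YEARS).any():
        bad = df.index[df["age_years"] <= MIN_AGE_YEARS].tolist()
        raise SchemaError(
            f"subjects {bad} violate the inclusion rule age > {MIN_AGE_YEARS} years")
    if not df["sex"].isin(["M", "F"]).all():
        raise SchemaError("sex must be coded 'M'/'F'")
    is_pat = df["group"] == "patient_HS"
    if (df.loc[~is_pat, "lateralization"] != "none").any():
        raise SchemaError("lateralization must be 'none' for non-patients")
    if (df.loc[is_pat, "lateralization"] == "none").any():
        raise SchemaError("HS patients must carry a lateralization label")


def save_cohort(cohort: Cohort, out_dir: str | Path, metric_format: str = "table") -> None:
    """Write a cohort to ``out_dir`` in the dialect ``load_cohort`` reads.

    ``metric_format`` selects ``"table"`` (wide CSV per hemisphere/feature) or
    ``"gifti"`` (one ``.shape.gii`` per subject/hemisphere/feature).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.subjects.reset_index(names="subject_id").to_csv(
        out / "demographics.csv", index=False, float_format="%.17g")
    cohort.volumes.reset_index(names="subject_id").to_csv(
        out / "volumes.csv", index=False, float_format="%.17g")
    cohort.qc.reset_index(names="subject_id").to_csv(
        out / "qc.csv", index=False, float_format="%.17g")
    cohort.surface.save(out / "surface.surf.gii")
    if metric_format == "table":
        for (hemi, feat), arr in cohort.vertex_data.items():
            df = pd.DataFrame(arr, index=cohort.subjects.index)
            df.index.name = "subject_id"
            df.to_csv(out / f"metric_{hemi}_{feat}.csv", float_format="%.17g")
    elif metric_format == "gifti":
        mdir = out / "metrics"
        mdir.mkdir(exist_ok=True)
        for (hemi, feat), arr in cohort.vertex_data.items():
            for i, sid in enumerate(cohort.subjects.index):
                img = nib.gifti.GiftiImage()
                # GIFTI's conforming float type is float32 (full float64
                # precision requires the table dialect)
                img.add_gifti_data_array(nib.gifti.GiftiDataArray(
                    arr[i].astype(np.float32), intent="NIFTI_INTENT_SHAPE"))
                nib.save(img, str(mdir / f"{sid}_{hemi}_{feat}.shape.gii"))
    else:
        raise ValueError(f"unknown metric_format {metric_format!r}")


def load_cohort(data_dir: str | Path) -> Cohort:
    """Load a cohort directory written by :func:`save_cohort` (either dialect).

    Subjects with missing metric files are reported in the raised error, never
    silently dropped; a vertex-count mismatch against the reference surface
    raises :class:`FormatError`.
    """
    d = Path(data_dir)
    demo = pd.read_csv(d / "demographics.csv", float_precision="round_trip")
    if "subject_id" not in demo.columns:
        raise SchemaError("demographics missing required column: 'subject_id'")
    demo = demo.set_index("subject_id")
    validate_subjects(demo)
    surface = HippSurface.load(d / "surface.surf.gii")
    volumes = pd.read_csv(d / "volumes.csv",
                          float_precision="round_trip").set_index("subject_id")
    qc = pd.read_csv(d / "qc.csv", float_precision="round_trip").set_index("subject_id")

    vertex_data = {}
    missing: list[str] = []
    if (d / "metrics").is_dir():  # GIFTI dialect
        for hemi in HEMISPHERES:
            for feat in VERTEX_FEATURES:
                rows = []
                for sid in demo.index:
                    p = d / "metrics" / f"{sid}_{hemi}_{feat}.shape.gii"
                    if not p.exists():
                        missing.append(str(p.name))
                        continue
                    vals = np.asarray(nib.load(str(p)).darrays[0].data, dtype=float)
                    rows.append(vals)
                if missing:
                    continue
                arr = np.vstack(rows)
                vertex_data[(hemi, feat)] = arr
    else:
        for hemi in HEMISPHERES:
            for feat in VERTEX_FEATURES:
                p = d / f"metric_{hemi}_{feat}.csv"
                if not p.exists():
                    missing.append(p.name)
                    continue
                df = pd.read_csv(p, float_precision="round_trip").set_index("subject_id")
                lost = [s for s in demo.index if s not in df.index]
                if lost:
                    missing.extend(f"{p.name}:{s}" for s in lost)
                    continue
                vertex_data[(hemi, feat)] = df.loc[demo.index].to_numpy(dtype=float)
    if missing:
        raise FormatError(f"missing metric data for: {missing[:10]}"
                          + ("..." if len(missing) > 10 else ""))
    for key, arr in vertex_data.items():
        if arr.shape[1] != surface.n_vertices:
            raise FormatError(
                f"metric {key} has {arr.shape[1]} vertices; reference surface "
                f"has {surface.n_vertices}")
    lost = [s for s in demo.index if s not in volumes.index or s not in qc.index]
    if lost:
        raise FormatError(f"subjects missing volume/QC rows: {lost}")
    return Cohort(demo, surface, vertex_data,
                  volumes.loc[demo.index], qc.loc[demo.index])


def qc_filter(cohort: Cohort, dice_threshold: float = 0.7):
    """Flag subjects whose worse-hemisphere Dice falls below ``dice_threshold``.

    Mirrors the segmentation-QC gate: any hippocampus with Dice overlap below
    0.7 is suspect (the threshold is strict "below"; exactly 0.7 is retained).
    Manual visual review is replaced by the flag plus the ``passed`` override
    column: a subject whose ``passed`` entry is True is retained regardless.

    Returns ``(retained, excluded, log)`` where retained/excluded are cohorts
    partitioning the input and ``log`` is a DataFrame of exclusion reasons.
    """
    dice_min = cohort.qc[["dice_left", "dice_right"]].min(axis=1)
    flagged = dice_min < dice_threshold
    override = cohort.qc["passed"].fillna(False).astype(bool) & flagged
    excluded_mask = flagged & ~override
    keep_ids = cohort.subjects.index[~excluded_mask]
    drop_ids = cohort.subjects.index[excluded_mask]
    log = pd.DataFrame({
        "subject_id": drop_ids,
        "dice_min": dice_min[excluded_mask].values,
        "reason": [f"min Dice {v:.3f} < {dice_threshold}"
                   for v in dice_min[excluded_mask]],
    })
    for sid in drop_ids:
        logger.info("QC exclusion: %s (min Dice %.3f)", sid, dice_min[sid])
    return cohort.subset(keep_ids), cohort.subset(drop_ids), log
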