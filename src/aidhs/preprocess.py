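"""Vertex-level preprocessing and per-hemisphere feature aggregation.

Surface-based maps pass through three steps before any statistics:

1. iterative outlier replacement — vertices beyond ``n_sd`` standard
   deviations of the map's mean are replaced by the mean of their non-outlier
   neighbors, re-estimating mean/SD each sweep until a fixed point;
2. geodesic Gaussian smoothing at a given FWHM (1 mm by default);
3. a trimmed mean over the anterior-posterior axis, dropping the vertices in
   the outer ``trim_frac`` AP-coordinate quantiles at each extreme (the
   hippocampal head and tail are the least reliable parts of the fit).

Total volume is already a per-hemisphere scalar and passes through untouched.
The result is one row of five scalar features per hippocampus (stage "raw"),
ready for harmonization.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from sklearn.base import BaseEstimator

from .cohort_io import Cohort, HippSurface, SCALAR_FEATURES, VERTEX_FEATURES, HEMISPHERES

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


def replace_outlier_vertices(values: np.ndarray, surface: HippSurface,
                             n_sd: float = 5.0, max_iter: int = 10) -> np.ndarray:
    """Iteratively replace vertices outside ``mean +- n_sd * SD``.

    Each sweep recomputes the mean and SD of the current map, flags vertices
    outside the band, and replaces every flagged vertex with the mean of its
    1-ring neighbors that are not themselves flagged (falling back to breadth-
    first search for the nearest non-outlier values when the whole 1-ring is
    flagged).  Stops when no vertex is flagged or after ``max_iter`` sweeps.

    ``values`` may be 1-D (one map) or 2-D ``(n_maps, n_vertices)``; maps are
    processed independently.  Non-outlier vertices are never modified.
    """
    if n_sd <= 0:
        raise ValueError("n_sd must be positive")
    vals = np.array(values, dtype=float)
    single = vals.ndim == 1
    if single:
        vals = vals[None, :]
    adj = surface.adjacency()
    if vals.shape[1] != surface.n_vertices:
        raise ValueError("metric length does not match surface vertex count")
    neighbor_lists = np.split(adj.indices, adj.indptr[1:-1])
    for row in range(vals.shape[0]):
        v = vals[row]
        for _ in range(max_iter):
            mu, sd = v.mean(), v.std()
            if sd == 0:
                break
            out = np.abs(v - mu) > n_sd * sd
            if not out.any():
                break
            if out.all():
                raise ValueError("all vertices flagged as outliers; degenerate map")
            new = v.copy()
            for idx in np.flatnonzero(out):
                nb = neighbor_lists[idx]
                good = nb[~out[nb]]
                if good.size == 0:
                    good = _nearest_non_outliers(neighbor_lists, out, idx)
                new[idx] = v[good].mean()
            v = new
        else:
            logger.warning("outlier replacement reached max_iter=%d", max_iter)
        vals[row] = v
    return vals[0] if single else vals


def _nearest_non_outliers(neighbor_lists, out_mask, start):
    """BFS outward from ``start`` until non-outlier vertices are found."""
    seen = {start}
    frontier = list(neighbor_lists[start])
    while frontier:
        good = [i for i in frontier if not out_mask[i]]
        if good:
            return np.array(good)
        nxt = set()
        for i in frontier:
            seen.add(i)
            nxt.update(j for j in neighbor_lists[i] if j not in seen)
        frontier = sorted(nxt)
    raise ValueError("no non-outlier vertex reachable")


def smoothing_operator(surface: HippSurface, fwhm_mm: float = 1.0,
                       truncate: float = 4.0) -> sparse.csr_matrix:
    """Row-stochastic geodesic Gaussian smoothing matrix for ``surface``.

    Weights are ``exp(-d^2 / 2 sigma^2)`` on graph geodesic distances along
    mesh edges (sigma = FWHM / 2.3548), truncated at ``truncate * sigma`` and
    normalized per vertex, so constant maps are preserved exactly and every
    weight is non-negative.  ``fwhm_mm = 0`` returns the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    n = surface.n_vertices
    if fwhm_mm == 0:
        return sparse.identity(n, format="csr")
    sigma = fwhm_mm * FWHM_TO_SIGMA
    dist = dijkstra(surface.adjacency(), directed=False, limit=truncate * sigma)
    finite = np.isfinite(dist)
    w = np.zeros_like(dist)
    w[finite] = np.exp(-dist[finite] ** 2 / (2 * sigma ** 2))
    w /= w.sum(axis=1, keepdims=True)
    return sparse.csr_matrix(w)


def smooth_metric(values: np.ndarray, surface: HippSurface, fwhm_mm: float = 1.0,
                  operator: sparse.csr_matrix | None = None) -> np.ndarray:
    """Smooth one or more vertex maps; precomputed ``operator`` is reused."""
    op = smoothing_operator(surface, fwhm_mm) if operator is None else operator
    vals = np.asarray(values, dtype=float)
    return (op @ vals.T).T if vals.ndim == 2 else op @ vals


def ap_trim_mask(ap_coord: np.ndarray, trim_frac: float = 0.01) -> np.ndarray:
    """Boolean mask of vertices retained after trimming the AP extremes."""
    if not 0 <= trim_frac < 0.5:
        raise ValueError("trim_frac must be in [0, 0.5)")
    lo = np.quantile(ap_coord, trim_frac)
    hi = np.quantile(ap_coord, 1 - trim_frac)
    mask = (ap_coord >= lo) & (ap_coord <= hi)
    if not mask.any():
        raise ValueError("trimming retained no vertices")
    return mask


def trimmed_mean(values: np.ndarray, surface: HippSurface,
                 trim_frac: float = 0.01) -> float | np.ndarray:
    """Mean over vertices inside the central AP-quantile band."""
    mask = ap_trim_mask(surface.ap_coord, trim_frac)
    vals = np.asarray(values, dtype=float)
    return vals[..., mask].mean(axis=-1)


class SurfacePreprocessor(BaseEstimator):
    """Outlier replacement -> smoothing -> AP-trimmed mean, per hippocampus.

    sklearn-style transformer over a :class:`~aidhs.cohort_io.Cohort`:
    ``fit`` precomputes the smoothing operator and trim mask for the cohort's
    shared surface; ``transform`` returns the per-hemisphere scalar feature
    table (stage "raw").  Volume bypasses the vertex pipeline.

    Parameters
    ----------
    n_sd : outlier band half-width in SDs (default 5).
    max_iter : maximum outlier-replacement sweeps (default 10).
    fwhm_mm : Gaussian smoothing kernel FWHM in mm (default 1.0).
    trim_frac : AP-quantile fraction trimmed at each extreme (default 0.01).
    """

    def __init__(self, n_sd: float = 5.0, max_iter: int = 10,
                 fwhm_mm: float = 1.0, trim_frac: float = 0.01):
        self.n_sd = n_sd
        self.max_iter = max_iter
        self.fwhm_mm = fwhm_mm
        self.trim_frac = trim_frac

    def fit(self, cohort: Cohort, y=None):
        self.operator_ = smoothing_operator(cohort.surface, self.fwhm_mm)
        self.trim_mask_ = ap_trim_mask(cohort.surface.ap_coord, self.trim_frac)
        return self

    def transform(self, cohort: Cohort) -> pd.DataFrame:
        """Return a long table (subject_id, hemisphere, 5 features, stage)."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "operator_")
        rows = []
        for hemi in HEMISPHERES:
            feats = {}
            for feat in VERTEX_FEATURES:
                if (hemi, feat) not in cohort.vertex_data:
                    raise ValueError(f"missing vertex data for {hemi}/{feat}")
                arr = replace_outlier_vertices(
                    cohort.vertex_data[(hemi, feat)], cohort.surface,
                    self.n_sd, self.max_iter)
                arr = smooth_metric(arr, cohort.surface, operator=self.operator_)
                feats[feat] = arr[:, self.trim_mask_].mean(axis=1)
            if hemi not in cohort.volumes.columns:
                raise ValueError(f"missing {hemi} hemisphere volume")
            df = pd.DataFrame({
                "subject_id": cohort.subjects.index,
                "hemisphere": hemi,
                "volume": cohort.volumes[hemi].to_numpy(dtype=float),
                **feats,
            })
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        out["stage"] = "raw"
        if not np.isfinite(out[list(SCALAR_FEATURES)].to_numpy()).all():
            raise ValueError("non-finite feature after preprocessing")
        return out

    def fit_transform(self, cohort: Cohort, y=None) -> pd.DataFrame:
        return self.fit(cohort).transform(cohort)


def aggregate_subject(cohort: Cohort, subject_id) -> pd.DataFrame:
    """Convenience wrapper: preprocess a single subject's two hippocampi."""
    sub = cohort.subset([subject_id])
    return SurfacePreprocessor().fit_transform(sub)


def preprocess_cohort(cohort: Cohort, **params) -> pd.DataFrame:
    """Preprocess every subject; thin wrapper over SurfacePreprocessor."""
    return SurfacePreprocessor(**params).fit_transform(cohort)
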