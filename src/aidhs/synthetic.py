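"""Seeded synthetic cohorts emulating hippocampal segmentation-tool outputs.

No public imaging accession accompanies this problem, so every pipeline stage
is exercised on simulated data shaped like the upstream tool's outputs: a
fixed-topology folded surface with an anterior-posterior coordinate, per-vertex
feature maps, per-hemisphere volumes, Dice QC scores and a demographics table.

The generative model per subject, hemisphere and feature is

    value = [a + b (1 - exp(-age / tau))  (saturating growth)
             + sex_offset + hemisphere_offset
             + subject effect            ~ N(0, sd_subject^2), shared L/R
             + hemisphere residual       ~ N(0, sd_hemi^2), independent L/R
             + site_shift] * site_scale

with the ipsilateral hemisphere of an HS patient multiplied by a per-feature
effect factor (< 1 for volume/thickness/gyrification, > 1 for the curvatures;
bilateral patients affected on both sides), jittered per patient.  Vertex maps
add a zero-mean spatial profile and spatially smooth noise around the scalar
target; volumes are scalar-only.  Default effect sizes were chosen once so
that ipsilateral volume falls below the healthy 5th centile in roughly 90% of
simulated patients, matching the qualitative severity the method is designed
to detect; absolute feature magnitudes are plausible but arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .cohort_io import (Cohort, HippSurface, SCALAR_FEATURES, VERTEX_FEATURES,
                        HEMISPHERES)
from .preprocess import smoothing_operator


def make_surface(grid_n_ap: int = 32, grid_n_pd: int = 16,
                 spacing_mm: float = 0.5) -> HippSurface:
    """Curved half-tube surface triangulated from an unfolded grid.

    The unfolded space is a ``grid_n_ap x grid_n_pd`` rectangle with vertex
    spacing ``spacing_mm``; it is folded into a half-cylinder bent along a
    gentle arc so that mesh distances are non-trivial while edge lengths stay
    within [0.5, 2] x spacing.  ``ap_coord`` is the normalized row index.
    """
    if grid_n_ap < 4 or grid_n_pd < 4:
        raise ValueError("grid dimensions must be >= 4")
    L = (grid_n_ap - 1) * spacing_mm
    r = spacing_mm * (grid_n_pd - 1) / np.pi   # half-circle cross-section
    R = 4.0 * L                                # bend radius of the axis
    i = np.arange(grid_n_ap)
    j = np.arange(grid_n_pd)
    phi = (i * spacing_mm) / R
    theta = np.pi * j / (grid_n_pd - 1)
    coords = np.empty((grid_n_ap, grid_n_pd, 3))
    for ii in range(grid_n_ap):
        axis = np.array([R * np.sin(phi[ii]), 0.0, R * (1 - np.cos(phi[ii]))])
        normal = np.array([-np.sin(phi[ii]), 0.0, np.cos(phi[ii])])
        ydir = np.array([0.0, 1.0, 0.0])
        for jj in range(grid_n_pd):
            coords[ii, jj] = (axis + r * np.cos(theta[jj]) * ydir
                              + r * np.sin(theta[jj]) * normal)
    coords = coords.reshape(-1, 3)
    idx = np.arange(grid_n_ap * grid_n_pd).reshape(grid_n_ap, grid_n_pd)
    faces = []
    for ii in range(grid_n_ap - 1):
        for jj in range(grid_n_pd - 1):
            a, b = idx[ii, jj], idx[ii, jj + 1]
            c, d = idx[ii + 1, jj], idx[ii + 1, jj + 1]
            faces.append([a, b, c])
            faces.append([b, d, c])
    ap = np.repeat(i / (grid_n_ap - 1), grid_n_pd)
    return HippSurface(coords, np.array(faces), ap)


@dataclass
class FeatureParams:
    """Generative parameters of one feature (units are the feature's own)."""
    baseline: float          # a: value approached from at age 0
    growth: float            # b: saturating growth amplitude
    tau: float               # years to ~63% of the growth
    sex_offset: float        # added for males
    hemi_offset: float       # added to the right hemisphere
    sd_subject: float        # between-subject SD (shared across hemispheres)
    sd_hemi: float           # independent per-hemisphere residual SD
    vertex_noise_sd: float   # SD of the smooth spatial noise (0 = scalar only)
    hs_multiplier: float     # ipsilateral effect factor
    hs_jitter: float         # SD of the per-patient multiplier jitter


#: default study conditions; volume in mm^3, thickness mm, gyrification
#: unitless, mean curvature mm^-1, intrinsic curvature mm^-2
#: HS multipliers are calibrated (once, against the normative model's control
#: residual SD under these same conditions) so that the fraction of simulated
#: patients whose ipsilateral features breach the healthy 5th/95th centiles
#: approximates the published deviation profile (volume ~90% below the 5th,
#: thickness ~63%, gyrification ~88%; curvatures ~67%/~70% above the 95th)
DEFAULT_FEATURES: dict[str, FeatureParams] = {
    "volume":         FeatureParams(2400, 800, 10, 150, 30, 250, 80, 0.0, 0.70, 0.06),
    "thickness":      FeatureParams(1.30, 0.40, 8, 0.05, 0.00, 0.08, 0.03, 0.15, 0.89, 0.04),
    "gyrification":   FeatureParams(2.70, 0.40, 12, 0.00, 0.05, 0.15, 0.05, 0.30, 0.82, 0.04),
    "curv_mean":      FeatureParams(0.150, 0.000, 10, 0.005, 0.000, 0.010, 0.004, 0.020, 1.16, 0.05),
    "curv_intrinsic": FeatureParams(0.028, 0.006, 15, 0.000, 0.001, 0.003, 0.0012, 0.006, 1.27, 0.07),
}

#: per-site additive shifts (in units of sd_subject) and scale factors
DEFAULT_SITE_SHIFTS = {"siteA": 0.0, "siteB": 1.0, "siteC": -0.7, "siteD": 0.4}
DEFAULT_SITE_SCALES = {"siteA": 1.0, "siteB": 1.08, "siteC": 0.93, "siteD": 1.02}


@dataclass
class SimulationConfig:
    """Full specification of a synthetic cohort; the seed is mandatory."""

    seed: int
    n_hs_left: int = 50            # per site
    n_hs_right: int = 50
    n_healthy: int = 50
    n_disease: int = 50
    n_bilateral: int = 0
    sites: tuple = tuple(DEFAULT_SITE_SHIFTS)
    site_shifts: dict = field(default_factory=lambda: dict(DEFAULT_SITE_SHIFTS))
    site_scales: dict = field(default_factory=lambda: dict(DEFAULT_SITE_SCALES))
    features: dict = field(default_factory=lambda: dict(DEFAULT_FEATURES))
    age_range: tuple = (7.0, 60.0)
    p_male: float = 0.5
    grid_n_ap: int = 32
    grid_n_pd: int = 16
    spacing_mm: float = 0.5
    noise_smooth_fwhm_mm: float = 1.5
    outlier_rate: float = 0.002    # fraction of vertices spiked per map
    outlier_n_sd: float = 8.0
    dice_mean: float = 0.95
    dice_sd: float = 0.02
    qc_failure_rate: float = 0.0   # injected segmentation failures

    def validate(self) -> None:
        for f, p in self.features.items():
            for name in ("sd_subject", "sd_hemi", "vertex_noise_sd", "hs_jitter"):
                if getattr(p, name) < 0:
                    raise ValueError(f"{f}.{name} must be >= 0")
        for f in ("volume", "thickness", "gyrification"):
            if self.features[f].hs_multiplier >= 1:
                raise ValueError(f"{f} HS multiplier must be < 1 (atrophy)")
        for f in ("curv_mean", "curv_intrinsic"):
            if self.features[f].hs_multiplier <= 1:
                raise ValueError(f"{f} HS multiplier must be > 1")
        for f, p in self.features.items():
            floor = (p.baseline - 5 * (p.sd_subject + p.sd_hemi)
                     + min(0.0, min(self.site_shifts.values()) * p.sd_subject))
            if floor * min(self.site_scales.values()) <= 0:
                raise ValueError(
                    f"config implies non-positive {f} values; reduce SDs/shifts")


def null_config(seed: int, **overrides) -> SimulationConfig:
    """Config with all HS effects removed (patients exchangeable with controls).

    Multipliers are nudged infinitesimally off 1 to satisfy the direction
    constraints while being biologically null.
    """
    feats = {f: replace(p, hs_multiplier=(1 - 1e-12 if p.hs_multiplier < 1
                                          else 1 + 1e-12), hs_jitter=0.0)
             for f, p in DEFAULT_FEATURES.items()}
    return SimulationConfig(seed=seed, features=feats, **overrides)


def _trajectory(p: FeatureParams, age, male, right):
    return (p.baseline + p.growth * (1 - np.exp(-np.asarray(age) / p.tau))
            + p.sex_offset * np.asarray(male, dtype=float)
            + p.hemi_offset * float(right))


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full cohort; identical config + seed -> identical cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    surface = make_surface(config.grid_n_ap, config.grid_n_pd, config.spacing_mm)
    nv = surface.n_vertices
    smooth_op = smoothing_operator(surface, config.noise_smooth_fwhm_mm)

    rows = []
    for site in config.sites:
        specs = ([("patient_HS", "left")] * config.n_hs_left
                 + [("patient_HS", "right")] * config.n_hs_right
                 + [("patient_HS", "bilateral")] * config.n_bilateral
                 + [("healthy_control", "none")] * config.n_healthy
                 + [("disease_control", "none")] * config.n_disease)
        for group, lat in specs:
            rows.append({"site_id": site, "group": group, "lateralization": lat})
    demo = pd.DataFrame(rows)
    n = len(demo)
    demo.index = pd.Index([f"sub-{k:04d}" for k in range(n)], name="subject_id")
    demo["age_years"] = rng.uniform(*config.age_range, n)
    demo["sex"] = np.where(rng.random(n) < config.p_male, "M", "F")
    is_pat = demo["group"] == "patient_HS"
    demo["mri_negative"] = np.where(is_pat, rng.random(n) < 0.15, np.nan)
    demo["histology"] = np.where(
        is_pat, rng.choice(["HS1", "HS2", "HS3", "nonspecified"],
                           size=n, p=[0.40, 0.19, 0.05, 0.36]), "NA")
    demo["good_outcome"] = np.where(is_pat, rng.random(n) < 0.72, np.nan)
    demo["icv_mm3"] = rng.normal(1.45e6, 1.2e5, n)
    demo["scan_field"] = "3T"
    demo["isotropic"] = rng.random(n) < 0.65

    male = (demo["sex"] == "M").to_numpy()
    age = demo["age_years"].to_numpy()
    shift_u = demo["site_id"].map(config.site_shifts).to_numpy(dtype=float)
    scale = demo["site_id"].map(config.site_scales).to_numpy(dtype=float)

    # ipsilateral effect multipliers per subject x hemisphere x feature
    mult = {(h, f): np.ones(n) for h in HEMISPHERES for f in SCALAR_FEATURES}
    for f, p in config.features.items():
        jit = rng.normal(0.0, p.hs_jitter, n)
        for h in HEMISPHERES:
            affected = (is_pat & ((demo["lateralization"] == h)
                                  | (demo["lateralization"] == "bilateral"))).to_numpy()
            m = np.clip(p.hs_multiplier + jit, 0.05, None)
            mult[(h, f)] = np.where(affected, m, 1.0)

    scalars = {}   # (hemi, feature) -> per-subject scalar target
    for f, p in config.features.items():
        u = rng.normal(0.0, p.sd_subject, n)      # shared across hemispheres
        for h in HEMISPHERES:
            e = rng.normal(0.0, p.sd_hemi, n)
            base = _trajectory(p, age, male, h == "right") + u + e
            base = base * mult[(h, f)]
            scalars[(h, f)] = (base + shift_u * p.sd_subject) * scale

    profile = np.sin(2 * np.pi * surface.ap_coord)
    profile = profile - profile.mean()
    vertex_data = {}
    for h in HEMISPHERES:
        for f in VERTEX_FEATURES:
            p = config.features[f]
            white = rng.normal(0.0, 1.0, (n, nv))
            smooth = (smooth_op @ white.T).T
            sd_now = smooth.std()
            noise = smooth * (p.vertex_noise_sd / sd_now if sd_now > 0 else 0.0)
            maps = scalars[(h, f)][:, None] + 0.5 * p.vertex_noise_sd * profile + noise
            if config.outlier_rate > 0:
                spikes = rng.random((n, nv)) < config.outlier_rate
                signs = rng.choice([-1.0, 1.0], (n, nv))
                maps = np.where(
                    spikes,
                    maps + signs * config.outlier_n_sd * max(p.vertex_noise_sd,
                                                             1e-3 * p.baseline),
                    maps)
            vertex_data[(h, f)] = maps

    volumes = pd.DataFrame({h: scalars[(h, "volume")] for h in HEMISPHERES},
                           index=demo.index)
    dice = rng.normal(config.dice_mean, config.dice_sd, (n, 2)).clip(0, 1)
    fails = rng.random(n) < config.qc_failure_rate
    dice[fails, 0] = rng.uniform(0.4, 0.69, int(fails.sum()))
    qc = pd.DataFrame({"dice_left": dice[:, 0], "dice_right": dice[:, 1]},
                      index=demo.index)
    qc["passed"] = qc[["dice_left", "dice_right"]].min(axis=1) >= 0.7
    return Cohort(demo, surface, vertex_data, volumes, qc)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["features"] = {f: asdict(p) if not isinstance(p, dict) else p
                     for f, p in d["features"].items()}
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["features"] = {f: FeatureParams(**p) for f, p in d["features"].items()}
    d["sites"] = tuple(d["sites"])
    d["age_range"] = tuple(d["age_range"])
    return SimulationConfig(**d)
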