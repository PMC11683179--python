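"""ComBat harmonization, asymmetry index algebra and control z-scoring."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aidhs.harmonize import (AsymmetryZScorer, CombatHarmonizer, SingleSiteError,
                             WIDE_COLUMNS, compute_asymmetry, fit_combat,
                             _design_matrices, to_wide, to_long)
from aidhs.cohort_io import SCALAR_FEATURES


def synthetic_sites(seed=0, n_per_site=200, shift_sd=1.0, age_slope=10.0,
                    scale_b=1.0):
    """Two-site scalar table with a known additive shift and age slope."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_site
    # identical covariate distributions in both sites: the batch effect is
    # purely the injected shift/scale
    ages = rng.uniform(7, 60, n_per_site)
    sexes = rng.choice(["M", "F"], n_per_site)
    grp = rng.choice(["healthy_control", "disease_control", "patient_HS"],
                     n_per_site)
    demo = pd.DataFrame({
        "site_id": ["s1"] * n_per_site + ["s2"] * n_per_site,
        "age_years": np.tile(ages, 2),
        "sex": np.tile(sexes, 2),
        "group": np.tile(grp, 2),
    }, index=[f"p{i}" for i in range(n)])
    within_sd = 25.0
    base = 1000.0 + age_slope * demo["age_years"].to_numpy()
    X = pd.DataFrame(index=demo.index)
    for col in WIDE_COLUMNS:
        noise = rng.normal(0, within_sd, n)
        shift = np.where(demo["site_id"] == "s2", shift_sd * within_sd, 0.0)
        scale = np.where(demo["site_id"] == "s2", scale_b, 1.0)
        X[col] = (base + noise + shift) * scale
    return pd.concat([X, demo], axis=1), within_sd


class TestCombat:
    def test_additive_shift_removed(self):
        """A pure 1-SD site shift shrinks to <5% of the injected gap.

        The between-site mean gap is pooled over the feature columns: a
        single column's residual gap is dominated by the sampling noise of
        two site means (se ~ sd/sqrt(n/2)), which no harmonization can beat.
        """
        X, sd = synthetic_sites(seed=1, shift_sd=1.0)
        model, harm = fit_combat(X)
        s2 = X.site_id == "s2"
        injected = 1.0 * sd
        gap_after = np.mean([harm.loc[s2, c].mean() - harm.loc[~s2, c].mean()
                             for c in WIDE_COLUMNS])
        gap_before = np.mean([X.loc[s2, c].mean() - X.loc[~s2, c].mean()
                              for c in WIDE_COLUMNS])
        assert abs(gap_before) > 0.8 * injected  # shift visible pre-harmonization
        assert abs(gap_after) < 0.05 * injected

    def test_null_batch_effect_nearly_identity(self):
        """Relabelling identical data into two sites barely changes it."""
        X, sd = synthetic_sites(seed=2, shift_sd=0.0, scale_b=1.0)
        _, harm = fit_combat(X)
        resid = (harm[WIDE_COLUMNS] - X[WIDE_COLUMNS]).abs().to_numpy()
        assert resid.mean() < 0.15 * sd  # EB shrinkage noise only

    def test_age_slope_preserved(self):
        """The common biological age slope survives harmonization."""
        X, _ = synthetic_sites(seed=3, age_slope=10.0)
        _, harm = fit_combat(X)
        col = WIDE_COLUMNS[0]
        slope = np.polyfit(X["age_years"], harm[col], 1)[0]
        assert slope == pytest.approx(10.0, rel=0.10)

    def test_training_rows_reproduce_stored_values(self):
        X, _ = synthetic_sites(seed=4)
        model, harm = fit_combat(X)
        again = model.transform(X)
        np.testing.assert_array_equal(again[WIDE_COLUMNS].to_numpy(),
                                      harm[WIDE_COLUMNS].to_numpy())

    def test_unseen_site_errors_and_passthrough(self):
        X, _ = synthetic_sites(seed=5)
        model, _ = fit_combat(X)
        Xn = X.copy()
        Xn["site_id"] = "elsewhere"
        with pytest.raises(ValueError, match="elsewhere"):
            model.transform(Xn)
        soft = CombatHarmonizer(unseen_site="passthrough").fit(X)
        out = soft.transform(Xn)
        np.testing.assert_array_equal(out[WIDE_COLUMNS].to_numpy(),
                                      Xn[WIDE_COLUMNS].to_numpy())

    def test_single_site_error_mentions_noop_mode(self):
        X, _ = synthetic_sites(seed=6)
        X["site_id"] = "only"
        with pytest.raises(SingleSiteError, match="without harmonization"):
            CombatHarmonizer().fit(X)

    def test_small_site_named_in_error(self):
        X, _ = synthetic_sites(seed=7)
        X = X[~((X.site_id == "s2") & (np.arange(len(X)) >= 210))]
        with pytest.raises(ValueError, match="s2"):
            CombatHarmonizer().fit(X)

    def test_zero_variance_feature_named(self):
        X, _ = synthetic_sites(seed=8)
        X[WIDE_COLUMNS[2]] = 5.0
        with pytest.raises(ValueError, match=WIDE_COLUMNS[2]):
            CombatHarmonizer().fit(X)

    def test_disabled_mode_is_identity(self):
        X, _ = synthetic_sites(seed=9)
        model = CombatHarmonizer(enabled=False).fit(X)
        out = model.transform(X)
        np.testing.assert_array_equal(out[WIDE_COLUMNS].to_numpy(),
                                      X[WIDE_COLUMNS].to_numpy())

    def test_serialization_round_trip(self):
        X, _ = synthetic_sites(seed=10)
        model, harm = fit_combat(X)
        back = CombatHarmonizer.from_dict(model.to_dict())
        np.testing.assert_allclose(back.transform(X)[WIDE_COLUMNS].to_numpy(),
                                   harm[WIDE_COLUMNS].to_numpy(), rtol=1e-12)

    def test_matches_reference_combat(self, tmp_path):
        """Independent oracle: Bioconductor sva::ComBat on the same matrix."""
        X, _ = synthetic_sites(seed=11, n_per_site=60)
        model, harm = fit_combat(X)
        Y = X[WIDE_COLUMNS].to_numpy()
        C, _ = _design_matrices(X)
        np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
        np.savetxt(tmp_path / "C.csv", C, delimiter=",")
        X["site_id"].to_csv(tmp_path / "batch.csv", index=False)
        r_script = tmp_path / "combat.R"
        r_script.write_text(
            'suppressMessages(library(sva))\n'
            f'setwd("{tmp_path}")\n'
            'Y <- as.matrix(read.csv("Y.csv", header=FALSE))\n'
            'C <- as.matrix(read.csv("C.csv", header=FALSE))\n'
            'batch <- read.csv("batch.csv")$site_id\n'
            'mod <- model.matrix(~., data=as.data.frame(C))\n'
            'res <- ComBat(dat=t(Y), batch=batch, mod=mod)\n'
            'write.csv(t(res), "r_harm.csv", row.names=FALSE)\n')
        subprocess.run(["Rscript", str(r_script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "r_harm.csv").to_numpy()
        np.testing.assert_allclose(harm[WIDE_COLUMNS].to_numpy(), ref,
                                   rtol=1e-6)


class TestAsymmetry:
    def wide(self, l, r):
        data = {}
        for f in SCALAR_FEATURES:
            data[f"{f}_left"] = [l]
            data[f"{f}_right"] = [r]
        return pd.DataFrame(data, index=["s"])

    def test_symmetric_is_zero(self):
        np.testing.assert_array_equal(
            compute_asymmetry(self.wide(2.0, 2.0)).to_numpy(), 0.0)

    def test_direct_values(self):
        """AI = 2(l-r)/(l+r): (3,1) -> 1 and (1,3) -> -1."""
        assert compute_asymmetry(self.wide(3.0, 1.0)).iloc[0, 0] == 1.0
        assert compute_asymmetry(self.wide(1.0, 3.0)).iloc[0, 0] == -1.0

    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4))
    def test_antisymmetry_and_bounds(self, l, r):
        a = compute_asymmetry(self.wide(l, r)).iloc[0, 0]
        b = compute_asymmetry(self.wide(r, l)).iloc[0, 0]
        assert a == pytest.approx(-b, abs=1e-12)
        assert -2 < a < 2

    def test_nonpositive_denominator_named(self):
        with pytest.raises(ValueError, match="volume.*'s'"):
            compute_asymmetry(self.wide(-3.0, 1.0))


class TestZScorer:
    def make_asym(self, n, mean, sd, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({f: mean + sd * rng.standard_normal(n)
                             for f in SCALAR_FEATURES})

    def test_known_stats_recovered(self):
        df = self.make_asym(5000, 0.01, 0.05)
        z = AsymmetryZScorer().fit(df)
        np.testing.assert_allclose(z.mean_, df.mean(axis=0), rtol=1e-12)
        np.testing.assert_allclose(z.std_, df.std(axis=0, ddof=1), rtol=1e-12)

    def test_self_normalization_exact(self):
        """Controls passed through their own stats: mean 0, SD 1 exactly."""
        df = self.make_asym(100, 0.02, 0.04, seed=1)
        out = AsymmetryZScorer().fit(df).transform(df)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, rtol=1e-12)

    def test_two_sd_maps_to_two(self):
        df = self.make_asym(500, 0.0, 0.05, seed=2)
        z = AsymmetryZScorer().fit(df)
        probe = pd.DataFrame({f: [z.mean_[i] + 2 * z.std_[i]]
                              for i, f in enumerate(SCALAR_FEATURES)})
        np.testing.assert_allclose(z.transform(probe).to_numpy(), 2.0,
                                   rtol=1e-12)

    def test_identical_controls_error(self):
        df = pd.DataFrame({f: [0.1, 0.1, 0.1] for f in SCALAR_FEATURES})
        with pytest.raises(ValueError, match="zero"):
            AsymmetryZScorer().fit(df)

def test_wide_long_round_trip():
    rng = np.random.default_rng(5)
    long = pd.DataFrame({
        "subject_id": np.repeat([f"s{i}" for i in range(4)], 2),
        "hemisphere": ["left", "right"] * 4,
        **{f: rng.normal(size=8) for f in SCALAR_FEATURES},
    })
    wide = to_wide(long)
    back = to_long(wide, stage="raw").sort_values(
        ["subject_id", "hemisphere"]).reset_index(drop=True)
    orig = long.sort_values(["subject_id", "hemisphere"]).reset_index(drop=True)
    for f in SCALAR_FEATURES:
        np.testing.assert_array_equal(back[f].to_numpy(), orig[f].to_numpy())
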