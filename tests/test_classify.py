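"""Multinomial classifier, decision rules, LOSO protocol, thresholds."""

import numpy as np
import pandas as pd
import pytest

from aidhs import (HSClassifier, decide, decide_frame, loso_cv,
                   fit_abnormality_thresholds, AidHsEnsemble,
                   fit_volume_baseline, compute_asymmetry, AsymmetryZScorer)
from aidhs.classify import CLASSES, SCORE_COLUMNS, fit_fold, class_labels
from aidhs.cohort_io import SCALAR_FEATURES
from aidhs.harmonize import WIDE_COLUMNS
from aidhs.pipeline import preprocess_to_wide


def separable_data(n=300, seed=0, scale=0.3):
    """Three Gaussian blobs on the asymmetry axes: left at -3 on the
    atrophy features, right at +3, controls at 0."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for label, center in (("left", -3.0), ("right", 3.0), ("none", 0.0)):
        pts = rng.normal(0, scale, (n // 3, 5))
        pts[:, :3] += center          # volume/thickness/gyrification axes
        pts[:, 3:] -= center / 3      # curvature axes move the other way
        X.append(pts)
        y += [label] * (n // 3)
    return np.vstack(X), np.array(y, dtype=object)


class TestHSClassifier:
    def test_separable_training_accuracy(self):
        X, y = separable_data()
        clf = HSClassifier().fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.99

    def test_scores_sum_to_one(self):
        X, y = separable_data(seed=1)
        clf = HSClassifier().fit(X, y)
        proba = clf.predict_proba(np.random.default_rng(2).normal(size=(1000, 5)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert (proba >= 0).all()

    def test_missing_class_errors(self):
        X, y = separable_data()
        with pytest.raises(ValueError, match="missing classes"):
            HSClassifier().fit(X[y != "left"], y[y != "left"])

    def test_nonfinite_feature_errors(self):
        X, y = separable_data()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            HSClassifier().fit(X, y)

    def test_dimension_mismatch_errors(self):
        X, y = separable_data()
        clf = HSClassifier().fit(X, y)
        with pytest.raises(ValueError, match="features"):
            clf.predict_proba(X[:, :3])

    def test_balanced_weights_majority_duplication_invariant(self):
        """Duplicating the majority class barely moves the balanced fit."""
        X, y = separable_data(seed=3, scale=0.8)
        Xd = np.vstack([X, X[y == "none"]])
        yd = np.concatenate([y, y[y == "none"]])
        c1 = HSClassifier(C=np.inf).fit(X, y)
        c2 = HSClassifier(C=np.inf).fit(Xd, yd)
        np.testing.assert_allclose(c1.coef_, c2.coef_, rtol=0.15, atol=0.15)

    def test_label_permutation_near_chance(self):
        """Shuffled labels leave nothing to learn: held-out accuracy ~ 1/3."""
        X, y = separable_data(n=600, seed=4)
        rng = np.random.default_rng(5)
        ys = rng.permutation(y)
        clf = HSClassifier().fit(X[:400], ys[:400])
        acc = (clf.predict(X[400:]) == ys[400:]).mean()
        assert abs(acc - 1 / 3) < 0.12

    def test_serialization_round_trip(self):
        X, y = separable_data(seed=6)
        clf = HSClassifier().fit(X, y)
        back = HSClassifier.from_dict(clf.to_dict())
        np.testing.assert_array_equal(back.predict_proba(X), clf.predict_proba(X))


class TestDecide:
    @pytest.mark.parametrize("scores,expected", [
        ((0.2, 0.1, 0.7), ("noHS", "left")),
        ((0.6, 0.3, 0.1), ("HS", "left")),
        ((0.1, 0.6, 0.3), ("HS", "right")),
    ])
    def test_forced_cases(self, scores, expected):
        assert decide(*scores) == expected

    def test_matches_argmax_oracle_10k(self):
        """Decisions equal brute-force argmax on 10^4 random triplets."""
        rng = np.random.default_rng(7)
        p = rng.dirichlet([1, 1, 1], size=10_000)
        dec = decide_frame(p)
        for i in range(10_000):
            s_lhs, s_rhs, s_nohs = p[i]
            det = "noHS" if np.argmax([max(s_lhs, s_rhs), s_nohs]) == 1 else "HS"
            lat = ("left", "right")[int(np.argmax([s_lhs, s_rhs]))]
            assert dec.iloc[i]["detection"] == det
            assert dec.iloc[i]["lateralization"] == lat

    def test_tie_handling(self):
        """Equal left/right scores lateralize left; a no-HS tie with the
        best lateralized score is called noHS (conservative)."""
        assert decide(0.4, 0.4, 0.2) == ("HS", "left")
        assert decide(0.4, 0.2, 0.4) == ("noHS", "left")
        assert decide(1 / 3, 1 / 3, 1 / 3) == ("noHS", "left")


class TestThresholds:
    def test_midpoint_of_separated_gaussians(self):
        """Equal-variance blobs at -3 (left HS) and 0 (controls) put the
        0.5 boundary near -1.5; the mirrored right side near +1.5."""
        rng = np.random.default_rng(8)
        n = 400
        z = pd.DataFrame(rng.normal(0, 0.5, (3 * n, 5)),
                         columns=list(SCALAR_FEATURES))
        labels = np.array(["left"] * n + ["right"] * n + ["none"] * n,
                          dtype=object)
        z.iloc[:n] -= 3.0
        z.iloc[n:2 * n] += 3.0
        th = fit_abnormality_thresholds(z, labels)
        for f in SCALAR_FEATURES:
            assert th["left"][f] == pytest.approx(-1.5, abs=0.25)
            assert th["right"][f] == pytest.approx(1.5, abs=0.25)

    def test_threshold_reproduces_logistic_rule(self):
        """The scalar threshold classifies exactly like the 0.5 rule."""
        from sklearn.linear_model import LogisticRegression
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(-2, 1, 150), rng.normal(0, 1, 150)])
        labels = np.array(["left"] * 150 + ["none"] * 150, dtype=object)
        z = pd.DataFrame({f: x for f in SCALAR_FEATURES})
        th = fit_abnormality_thresholds(z, labels)["left"]["volume"]
        lr = LogisticRegression(C=1e6, max_iter=1000).fit(
            x[:, None], (labels == "left").astype(float))
        np.testing.assert_array_equal(x < th, lr.predict_proba(x[:, None])[:, 1] > 0.5)


class TestEnsemble:
    def _fold_like(self, clf):
        class Dummy:
            def __init__(self, c):
                self.classifier = c
                self.feature_cols = list(SCALAR_FEATURES)
            def predict_scores(self, fw):
                proba = self.classifier.predict_proba(
                    fw[self.feature_cols].to_numpy())
                return pd.DataFrame(proba, index=fw.index,
                                    columns=list(SCORE_COLUMNS))
            def transform(self, fw):
                return fw
        return Dummy(clf)

    def test_identical_folds_equal_single(self):
        X, y = separable_data(seed=10)
        clf = HSClassifier().fit(X, y)
        fw = pd.DataFrame(X[:20], columns=list(SCALAR_FEATURES))
        ens = AidHsEnsemble([self._fold_like(clf)] * 4)
        np.testing.assert_allclose(ens.predict_scores(fw).to_numpy(),
                                   clf.predict_proba(X[:20]), atol=1e-12)

    def test_mean_of_two_extremes(self):
        class Const:
            def __init__(self, vec):
                self.vec = np.array(vec)
            def predict_scores(self, fw):
                return pd.DataFrame(np.tile(self.vec, (len(fw), 1)),
                                    index=fw.index, columns=list(SCORE_COLUMNS))
        ens = AidHsEnsemble([Const([1, 0, 0]), Const([0, 1, 0])])
        fw = pd.DataFrame(np.zeros((3, 5)), columns=list(SCALAR_FEATURES))
        np.testing.assert_allclose(ens.predict_scores(fw).to_numpy(),
                                   [[0.5, 0.5, 0.0]] * 3)

    def test_empty_ensemble_errors(self):
        with pytest.raises(ValueError, match="empty"):
            AidHsEnsemble([]).predict_scores(
                pd.DataFrame(np.zeros((1, 5)), columns=list(SCALAR_FEATURES)))


class TestLOSO:
    def test_partition_contract(self, small_cohort, trained):
        """4 sites -> 4 folds; each fold's training sites exclude its test
        site; out-of-fold predictions cover the cohort exactly once."""
        ens = trained["ensemble"]
        preds = trained["predictions"]
        assert len(ens.folds) == 4
        for fold in ens.folds:
            assert fold.test_site not in fold.train_sites
        assert sorted(preds.index) == sorted(small_cohort.subjects.index)
        assert not preds.index.duplicated().any()

    def test_fold_zscorer_uses_training_healthy_controls_only(self, small_cohort,
                                                              trained):
        """Control asymmetry stats come from the fold's training healthy
        controls, not disease controls nor held-out-site subjects."""
        fold = trained["ensemble"].folds[0]
        demo = small_cohort.subjects
        wide = trained["features"]
        train = demo.index[(demo.site_id != fold.test_site)]
        harm = fold.harmonizer.transform(wide.loc[train])
        asym = compute_asymmetry(harm)
        hc = asym[demo.loc[train, "group"] == "healthy_control"]
        expected = AsymmetryZScorer().fit(hc)
        np.testing.assert_allclose(fold.zscorer.mean_, expected.mean_, rtol=1e-12)
        np.testing.assert_allclose(fold.zscorer.std_, expected.std_, rtol=1e-12)

    def test_leakage_deleting_heldout_rows_is_bit_identical(self, small_cohort,
                                                            trained):
        """Fold models are unchanged when the held-out site's rows are
        physically absent during training."""
        wide = trained["features"]
        demo = small_cohort.subjects
        for fold in trained["ensemble"].folds:
            train_ids = demo.index[demo.site_id != fold.test_site]
            refit = fit_fold(wide.loc[train_ids].copy(deep=True),
                             demo.loc[train_ids].copy(deep=True),
                             harmonize=True, test_site=fold.test_site)
            np.testing.assert_array_equal(refit.classifier.coef_,
                                          fold.classifier.coef_)
            np.testing.assert_array_equal(refit.classifier.intercept_,
                                          fold.classifier.intercept_)
            np.testing.assert_array_equal(refit.zscorer.mean_, fold.zscorer.mean_)

    def test_sign_mirror_property(self, small_cohort, trained):
        """Negating every asymmetry feature and swapping left/right labels
        yields mirrored decisions."""
        demo = small_cohort.subjects
        wide = trained["features"]
        fold = trained["ensemble"].folds[0]
        train_ids = demo.index[demo.site_id != fold.test_site]
        z = fold.transform(wide.loc[train_ids])
        labels = class_labels(demo.loc[train_ids])
        keep = labels != "bilateral"
        z, labels = z[keep], labels[keep]
        clf = HSClassifier().fit(z.to_numpy(), labels)
        swap = {"left": "right", "right": "left", "none": "none"}
        labels_m = np.array([swap[l] for l in labels], dtype=object)
        clf_m = HSClassifier().fit(-z.to_numpy(), labels_m)
        p = clf.predict_proba(z.to_numpy())
        pm = clf_m.predict_proba(-z.to_numpy())
        np.testing.assert_allclose(p[:, 0], pm[:, 1], atol=1e-4)
        np.testing.assert_allclose(p[:, 2], pm[:, 2], atol=1e-4)

    def test_site_without_controls_errors(self, small_cohort):
        demo = small_cohort.subjects.copy()
        wide = preprocess_to_wide(small_cohort)
        # reduce to 2 sites; strip all healthy controls from the survivor
        keep = demo.site_id.isin(["siteA", "siteB"])
        demo = demo[keep]
        wide = wide.loc[demo.index]
        drop = (demo.site_id == "siteB") & (demo.group == "healthy_control")
        with pytest.raises(ValueError, match="healthy controls"):
            loso_cv(wide.loc[~drop.to_numpy()], demo[~drop])


class TestVolumeBaseline:
    def test_baseline_matches_full_when_only_volume_informative(self, small_cohort):
        """With the asymmetry signal confined to volume, the volume-only
        baseline performs on par with the full model."""
        from aidhs.evaluate import performance
        wide = preprocess_to_wide(small_cohort).copy()
        demo = small_cohort.subjects
        rng = np.random.default_rng(11)
        for f in ("thickness", "gyrification", "curv_mean", "curv_intrinsic"):
            for h in ("left", "right"):
                wide[f"{f}_{h}"] = rng.normal(100, 1, len(wide))
        full, _ = loso_cv(wide, demo)
        base, ensb = fit_volume_baseline(wide, demo)
        pf = performance(full, demo)
        pb = performance(base, demo)
        assert abs(pf["detection_sensitivity_pct"]
                   - pb["detection_sensitivity_pct"]) <= 5.0
        for fold in ensb.folds:
            assert fold.test_site not in fold.train_sites

    def test_full_beats_baseline_with_curvature_only_signal(self, small_cohort):
        """Signal in curvature only: the 5-feature model must outperform
        the volume-only baseline."""
        from aidhs.evaluate import performance
        wide = preprocess_to_wide(small_cohort).copy()
        demo = small_cohort.subjects
        rng = np.random.default_rng(12)
        for h in ("left", "right"):
            wide[f"volume_{h}"] = rng.normal(3000, 100, len(wide))
        full, _ = loso_cv(wide, demo)
        base, _ = fit_volume_baseline(wide, demo)
        pf = performance(full, demo)
        pb = performance(base, demo)
        assert (pf["detection_sensitivity_pct"]
                > pb["detection_sensitivity_pct"] + 20)
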