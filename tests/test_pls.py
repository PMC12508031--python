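"""PLS feature construction, fitting, CV selection, cross-cohort validation,
component scores and covariate effects."""

import numpy as np
import pandas as pd
import pytest

import hemiasym as ha
from hemiasym import (
    build_feature_matrix,
    component_scores,
    cross_cohort_validate,
    fit_pls,
    score_covariate_effects,
    select_components_cv,
)
from hemiasym.vocab import EPOCHS, MAJOR_NETWORKS
from tests.conftest import make_subject_table


class TestFeatureMatrix:
    def test_153_predictors(self, small_matrices):
        nem_a, _ = small_matrices
        X = build_feature_matrix(nem_a)
        assert X.shape[1] == 153
        assert list(X.columns.get_level_values("network").unique()) == list(MAJOR_NETWORKS)
        # network-major, epoch-minor ordering
        assert X.columns[0] == ("VIS1", "faces")
        assert X.columns[16] == ("VIS1", "2bk")
        assert X.columns[17] == ("VIS2", "faces")
        # minor networks excluded
        assert "ORA" not in X.columns.get_level_values("network")

    def test_restricted_layout(self, small_matrices):
        nem_a, _ = small_matrices
        X = build_feature_matrix(nem_a, networks=["LAN", "DMN"],
                                 epochs=["story", "math", "2bk"])
        assert X.shape[1] == 6
        assert list(X.columns) == [
            ("LAN", "story"), ("LAN", "math"), ("LAN", "2bk"),
            ("DMN", "story"), ("DMN", "math"), ("DMN", "2bk"),
        ]

    def test_column_is_identity_view(self, small_matrices):
        nem_a, _ = small_matrices
        X = build_feature_matrix(nem_a)
        np.testing.assert_array_equal(
            X[("LAN", "story")].to_numpy(), nem_a.cell("LAN", "story")
        )

    def test_missing_network_raises(self, small_matrices):
        nem_a, _ = small_matrices
        sub = ha.NetworkEpochMatrix(
            nem_a.values.drop(columns=["LAN"], level="network"), "amplitude"
        )
        with pytest.raises(ValueError, match="LAN"):
            build_feature_matrix(sub)


class TestFitPLS:
    def test_exact_linear_recovery(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=50)})
        Y = 2.0 * X.to_numpy()
        model = fit_pls(X, Y, n_components=1)
        Xnew = pd.DataFrame({"x": rng.normal(size=20)})
        np.testing.assert_allclose(model.predict(Xnew), 2.0 * Xnew.to_numpy(), atol=1e-8)

    def test_saturated_limit_matches_ols(self, rng):
        """Full-rank PLS predictions equal least-squares predictions."""
        n, p = 300, 10
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n, 3))
        model = fit_pls(X, Y, n_components=p)
        X1 = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(X1, Y, rcond=None)
        np.testing.assert_allclose(model.predict(X), X1 @ beta, atol=1e-6)

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(80, 12))
        Y = X @ rng.normal(size=(12, 4)) + rng.normal(size=(80, 4))
        model = fit_pls(X, Y, n_components=6)
        T = model.x_scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_explained_variance_monotone_and_bounded(self, rng):
        X = rng.normal(size=(60, 10))
        Y = X[:, :2] @ rng.normal(size=(2, 3)) + 0.1 * rng.normal(size=(60, 3))
        model = fit_pls(X, Y, n_components=5)
        cum = model.cumulative_explained_variance_x
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[-1] <= 1.0 + 1e-12

    def test_prediction_invariant_to_column_rescaling(self, rng):
        """Centering/unit-scaling absorbs affine predictor rescaling."""
        X = rng.normal(size=(100, 5))
        Y = X @ rng.normal(size=(5, 2)) + rng.normal(size=(100, 2))
        Xs = X * np.array([10.0, 0.1, 3.0, 1.0, 100.0]) + np.arange(5)
        m1 = fit_pls(X, Y, n_components=3)
        m2 = fit_pls(Xs, Y, n_components=3)
        np.testing.assert_allclose(m1.predict(X), m2.predict(Xs), atol=1e-8)

    def test_infeasible_rank_rejected(self, rng):
        with pytest.raises(ValueError, match="feasible rank"):
            fit_pls(rng.normal(size=(10, 5)), rng.normal(size=(10, 2)), n_components=8)


class TestSelectComponentsCV:
    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(60, 8))
        Y = X[:, :3] @ rng.normal(size=(3, 2)) + rng.normal(size=(60, 2))
        n1, c1 = select_components_cv(X, Y, k=5, max_components=6, seed=4)
        n2, c2 = select_components_cv(X, Y, k=5, max_components=6, seed=4)
        assert n1 == n2
        pd.testing.assert_frame_equal(c1, c2)

    def test_pure_noise_selects_few(self):
        """With no X→Y signal, CV error favors very few components."""
        small = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(80, 10))
            Y = r.normal(size=(80, 3))
            n, _ = select_components_cv(X, Y, k=5, max_components=8, seed=seed)
            small += int(n <= 2)
        assert small >= 16  # >= 80%

    def test_planted_factors_recovered(self):
        r = np.random.default_rng(7)
        n = 500
        F = r.normal(size=(n, 3))
        X = F @ r.normal(size=(3, 20)) + 0.05 * r.normal(size=(n, 20))
        Y = F @ r.normal(size=(3, 5)) + 0.05 * r.normal(size=(n, 5))
        ncomp, _ = select_components_cv(X, Y, k=10, max_components=8, seed=0)
        assert ncomp >= 3

    def test_too_many_folds_rejected(self, rng):
        with pytest.raises(ValueError, match="folds"):
            select_components_cv(rng.normal(size=(5, 3)), rng.normal(size=(5, 1)), k=10)


class TestCrossCohort:
    def test_identical_cohorts_train_equals_test(self, rng):
        X = rng.normal(size=(60, 8))
        Y = X @ rng.normal(size=(8, 3)) + rng.normal(size=(60, 3))
        res = cross_cohort_validate(X, Y, X, Y, n_components=4)
        for direction in res.values():
            np.testing.assert_allclose(
                direction["train"].r.to_numpy(), direction["test"].r.to_numpy()
            )

    def test_overlapping_cohorts_rejected(self, small_matrices):
        nem_a, nem_d = small_matrices
        X = build_feature_matrix(nem_a)
        Y = build_feature_matrix(nem_d)
        with pytest.raises(ValueError, match="overlap"):
            cross_cohort_validate(X, Y, X.iloc[:10], Y.iloc[:10], n_components=3)

    def test_bonferroni_mask_consistent(self, rng):
        X1, X2 = rng.normal(size=(100, 10)), rng.normal(size=(100, 10))
        Y1 = X1 @ rng.normal(size=(10, 6)) + rng.normal(size=(100, 6))
        Y2 = X2 @ rng.normal(size=(10, 6)) + rng.normal(size=(100, 6))
        res = cross_cohort_validate(X1, Y1, X2, Y2, n_components=5)
        hm = res["discovery_to_replication"]["test"]
        assert hm.family_size == 6
        np.testing.assert_array_equal(
            hm.mask.to_numpy(), (hm.p < 0.05 / 6).to_numpy()
        )


class TestComponentScores:
    def _toy_model(self, loadings):
        """A 1-network × 2-epoch, 1-component model with forced loadings."""
        r = np.random.default_rng(0)
        cols = pd.MultiIndex.from_product([["LAN"], ["story", "math"]],
                                          names=["network", "epoch"])
        X = pd.DataFrame(r.normal(size=(30, 2)), columns=cols)
        model = fit_pls(X, r.normal(size=(30, 1)), n_components=1)
        model.estimator.x_loadings_ = np.asarray(loadings, float).reshape(2, 1)
        return model

    def test_hand_weighted_sum(self):
        model = self._toy_model([0.5, 0.25])
        A = pd.DataFrame([[1.0, 2.0]], index=["LAN"], columns=["story", "math"])
        scores = component_scores(A, model)
        assert scores.loc["LAN", "PC1"] == pytest.approx(1.0)  # 1·0.5 + 2·0.25

    def test_zero_loadings_zero_scores(self):
        model = self._toy_model([0.0, 0.0])
        A = pd.DataFrame([[5.0, -3.0]], index=["LAN"], columns=["story", "math"])
        assert (component_scores(A, model) == 0).all().all()

    def test_bilinearity(self, small_matrices):
        nem_a, nem_d = small_matrices
        X, Y = build_feature_matrix(nem_a), build_feature_matrix(nem_d)
        model = fit_pls(X, Y, n_components=3)
        A = nem_a.cohort_mean().loc[list(MAJOR_NETWORKS)]
        np.testing.assert_allclose(
            component_scores(2.0 * A, model).to_numpy(),
            2.0 * component_scores(A, model).to_numpy(),
        )

    def test_matches_double_loop_oracle(self, small_matrices):
        nem_a, nem_d = small_matrices
        X, Y = build_feature_matrix(nem_a), build_feature_matrix(nem_d)
        model = fit_pls(X, Y, n_components=4)
        A = nem_a.cohort_mean().loc[list(MAJOR_NETWORKS), list(EPOCHS)]
        scores = component_scores(A, model)
        omega = model.loadings_tensor
        for i, net in enumerate(MAJOR_NETWORKS):
            for n in range(4):
                expected = sum(
                    A.loc[net, e] * omega[i, j, n] for j, e in enumerate(EPOCHS)
                )
                assert scores.loc[net, f"PC{n+1}"] == pytest.approx(expected, rel=1e-8)

    def test_axis_mismatch_rejected(self, small_matrices):
        nem_a, nem_d = small_matrices
        model = fit_pls(build_feature_matrix(nem_a), build_feature_matrix(nem_d),
                        n_components=2)
        bad = pd.DataFrame(np.ones((2, 3)), index=["LAN", "DMN"],
                           columns=["story", "math", "nope"])
        with pytest.raises(ValueError, match="axes"):
            component_scores(bad, model)


class TestCovariateEffects:
    def test_planted_sex_offset_detected(self):
        r = np.random.default_rng(3)
        tbl = make_subject_table(500, seed=3)
        scores = r.normal(size=(500, 3))
        scores[:, 1] += 0.8 * (tbl["sex"] == "M").to_numpy()
        out = score_covariate_effects(scores, tbl)
        assert out.loc[2, "p_sex"] < 1e-6
        assert out.loc[2, "t_sex_MvsF"] > 0

    def test_null_scores_mostly_nonsignificant(self):
        hits = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            tbl = make_subject_table(100, seed=seed)
            out = score_covariate_effects(r.normal(size=(100, 4)), tbl)
            hits += int((out["p_sex"] < 0.05).sum() + (out["p_age"] < 0.05).sum())
        assert hits < 30 * 8 * 0.15  # ~5% nominal, generous cap

    def test_identical_groups_t_zero(self):
        tbl = make_subject_table(8, seed=1)
        tbl["sex"] = ["F", "M"] * 4
        scores = np.tile(np.arange(4.0), 2)[:, None]
        scores = np.sort(scores, axis=0)  # same values in both groups
        scores = np.array([[0.0], [0.0], [1.0], [1.0], [2.0], [2.0], [3.0], [3.0]])
        out = score_covariate_effects(scores, tbl)
        assert out.loc[1, "t_sex_MvsF"] == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        tbl = make_subject_table(10, seed=2)
        tbl["sex"] = "F"
        with pytest.raises(ValueError, match="sex"):
            score_covariate_effects(np.zeros((10, 1)), tbl)
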