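"""Accuracy-brain associations and accuracy-prediction orchestration."""

import numpy as np
import pandas as pd
import pytest

import hemiasym as ha
from hemiasym import (
    accuracy_correlations,
    boxplot_stats,
    build_feature_matrix,
    extract_accuracy,
    run_accuracy_prediction,
)
from hemiasym.synthetic import _network_epoch_frame, default_accuracy_coefs
from hemiasym.vocab import ACCURACY_EPOCHS, CONTROL_EPOCHS, TASK_EPOCHS


def test_extract_accuracy_is_12_nonmotor_epochs(small_cohort):
    acc = extract_accuracy(small_cohort.subjects)
    assert acc.shape == (small_cohort.n_subjects, 12)
    assert list(acc.columns) == list(ACCURACY_EPOCHS)


class TestAccuracyCorrelations:
    def test_accuracy_equal_to_amplitude_gives_r_one(self, small_matrices, small_cohort):
        nem_a, nem_d = small_matrices
        subjects = small_cohort.subjects.copy()
        subjects["accuracy_story"] = nem_a.cell("LAN", "story")
        res = accuracy_correlations(nem_a, nem_d, subjects)
        assert res.cell("LAN", "story", "amplitude")["r"] == pytest.approx(1.0)

    def test_planted_asymmetry_association_recovered(self):
        """Accuracy built as 0.5 + 0.3·standardized LAN story asymmetry plus
        noise is detected with r within ±0.1 of the planted correlation."""
        cohort = ha.generate_cohort(ha.CohortConfig(n_subjects=500, n_vertices=24, seed=31))
        nem_a = ha.aggregate_cohort_arrays(
            cohort.amplitude(), cohort.partition, cohort.subject_ids, cohort.epochs, "amplitude")
        nem_d = ha.aggregate_cohort_arrays(
            cohort.asymmetry(), cohort.partition, cohort.subject_ids, cohort.epochs, "asymmetry")
        rng = np.random.default_rng(0)
        z = nem_d.cell("LAN", "story")
        z = (z - z.mean()) / z.std()
        noise_sd = 0.3  # planted r = 0.3/sqrt(0.09 + 0.09) ≈ 0.707
        subjects = cohort.subjects.copy()
        subjects["accuracy_story"] = 0.5 + 0.3 * z + rng.normal(0, noise_sd, 500)
        res = accuracy_correlations(nem_a, nem_d, subjects)
        cell = res.cell("LAN", "story", "asymmetry")
        planted_r = 0.3 / np.sqrt(0.3**2 + noise_sd**2)
        assert cell["r"] == pytest.approx(planted_r, abs=0.1)
        assert cell["significant_bonferroni"]

    def test_null_calibration(self, small_matrices):
        """Accuracy independent of brain measures: ~5% uncorrected hits."""
        nem_a, nem_d = small_matrices
        rng = np.random.default_rng(1)
        n = len(nem_a.values)
        subjects = pd.DataFrame({"subject_id": nem_a.values.index})
        for e in ACCURACY_EPOCHS:
            subjects[f"accuracy_{e}"] = rng.normal(0.8, 0.05, n)
        res = accuracy_correlations(nem_a, nem_d, subjects)
        frac = (res.table["p"] < 0.05).mean()
        assert frac < 0.15

    def test_r2_equals_r_squared_and_roles(self, small_matrices, small_cohort):
        nem_a, nem_d = small_matrices
        res = accuracy_correlations(nem_a, nem_d, small_cohort.subjects)
        t = res.table.dropna(subset=["r"])
        np.testing.assert_allclose(t["r2"], t["r"] ** 2, rtol=1e-12)
        assert set(t.loc[t.epoch.isin(TASK_EPOCHS), "epoch_role"]) == {"task"}
        assert set(t.loc[t.epoch.isin(CONTROL_EPOCHS), "epoch_role"]) == {"control"}
        assert res.family_size == 9 * 12

    def test_ceiling_epoch_flagged_not_errored(self, small_matrices, small_cohort):
        nem_a, nem_d = small_matrices
        subjects = small_cohort.subjects.copy()
        subjects["accuracy_faces"] = 1.0  # ceiling: zero variance
        res = accuracy_correlations(nem_a, nem_d, subjects)
        faces = res.table[res.table.epoch == "faces"]
        assert faces["r"].isna().all()
        assert res.n_undefined == len(faces)


class TestAccuracyPrediction:
    def _setup(self, seed, asym_weight=None, beta=None, n=200):
        coefs = default_accuracy_coefs()
        if asym_weight is not None:
            coefs["asym_weight"] = asym_weight
        kwargs = {}
        if beta is not None:
            kwargs["beta_coupling"] = beta
        cohort = ha.generate_cohort(
            ha.CohortConfig(n_subjects=n, n_vertices=24, seed=seed,
                            accuracy_coefs=coefs, **kwargs))
        nem_a = ha.aggregate_cohort_arrays(
            cohort.amplitude(), cohort.partition, cohort.subject_ids, cohort.epochs, "amplitude")
        nem_d = ha.aggregate_cohort_arrays(
            cohort.asymmetry(), cohort.partition, cohort.subject_ids, cohort.epochs, "asymmetry")
        split = ha.split_matched(cohort.subjects, seed=seed)
        X = {"amplitude": build_feature_matrix(nem_a),
             "asymmetry": build_feature_matrix(nem_d)}
        acc = extract_accuracy(cohort.subjects)
        halves = (("discovery", split.discovery_ids), ("replication", split.replication_ids))
        features = {name: {m: X[m].loc[ids] for m in X} for name, ids in halves}
        accur = {name: acc.loc[ids] for name, ids in halves}
        return features, accur

    def test_amplitude_driven_accuracy_favors_amplitude_model(self):
        features, accur = self._setup(
            seed=41, asym_weight=0.0, beta=_network_epoch_frame(0.0), n=300)
        res = run_accuracy_prediction(features, accur,
                                      measures=("amplitude", "asymmetry"), seed=0)
        s = res["summary"]
        assert s.loc["amplitude", "mean_test_r"] > s.loc["asymmetry", "mean_test_r"]

    def test_combined_not_better_when_asymmetry_redundant(self):
        """When asymmetry carries no independent accuracy signal the
        combined model does not beat amplitude-only beyond noise."""
        diffs = []
        for seed in range(5):
            features, accur = self._setup(
                seed=50 + seed, asym_weight=0.0, beta=_network_epoch_frame(0.0), n=300)
            res = run_accuracy_prediction(features, accur,
                                          measures=("amplitude", "both"), seed=seed)
            s = res["summary"]
            diffs.append(s.loc["both", "mean_test_r"] - s.loc["amplitude", "mean_test_r"])
        assert np.mean(diffs) < 0.05

    def test_zero_noise_linear_map_recovered(self, rng):
        """A noise-free linear map from features to responses gives
        held-out correlations approaching 1."""
        X1 = pd.DataFrame(rng.normal(size=(100, 12)),
                          index=[f"d{i}" for i in range(100)])
        X2 = pd.DataFrame(rng.normal(size=(100, 12)),
                          index=[f"r{i}" for i in range(100)])
        W = rng.normal(size=(12, 12))
        cols = list(ACCURACY_EPOCHS)
        acc = {"discovery": pd.DataFrame(X1.to_numpy() @ W, index=X1.index, columns=cols),
               "replication": pd.DataFrame(X2.to_numpy() @ W, index=X2.index, columns=cols)}
        features = {"discovery": {"amplitude": X1}, "replication": {"amplitude": X2}}
        res = run_accuracy_prediction(features, acc, measures=("amplitude",),
                                      n_components=12, seed=0)
        for d in ("discovery_to_replication", "replication_to_discovery"):
            assert res["amplitude"][d]["test"].r.min() > 0.99


class TestBoxplotStats:
    def test_matches_order_statistics_oracle(self, rng):
        v = rng.normal(size=501)
        out = boxplot_stats(v)
        s = np.sort(v)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        assert out["median"] == pytest.approx(med)
        assert out["q1"] == pytest.approx(q1)
        assert out["q3"] == pytest.approx(q3)
        iqr = q3 - q1
        inside = s[(s >= q1 - 1.5 * iqr) & (s <= q3 + 1.5 * iqr)]
        assert out["whisker_low"] == pytest.approx(inside[0])
        assert out["whisker_high"] == pytest.approx(inside[-1])
        assert out["n_outliers"] == v.size - inside.size

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_stats(np.array([]))
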