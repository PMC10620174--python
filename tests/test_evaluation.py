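"""Evaluation procedures: bootstrap accuracy, paired tests, representations,
repeated-split Cox concordance, report tables."""

import numpy as np
import pandas as pd
import pytest

from cloudharmony import (
    SimulationConfig,
    SurvivalTable,
    generate_cohort,
    standardize,
)
from cloudharmony.evaluation import (
    AccuracyDistribution,
    ConcordanceReport,
    RepresentationSet,
    build_representation,
    confounder_accuracy,
    experiment_report,
    paired_accuracy_test,
    paired_concordance_test,
    prognostic_eval,
)


class TestConfounderAccuracy:
    def test_independent_features_score_near_prevalence(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((400, 5))
        labels = np.array(["a", "b"] * 200)
        acc = confounder_accuracy(x, labels, n_trials=100, seed=0)
        assert abs(acc.mean - 0.5) < 0.05

    def test_leaked_label_scores_perfectly(self):
        rng = np.random.default_rng(1)
        labels = np.array(["a", "b"] * 100)
        x = np.column_stack([rng.standard_normal(200), (labels == "a").astype(float)])
        acc = confounder_accuracy(x, labels, n_trials=20, seed=0)
        assert acc.mean >= 0.99

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((100, 3))
        labels = np.array(["a", "b"] * 50)
        a = confounder_accuracy(x, labels, n_trials=10, seed=7)
        b = confounder_accuracy(x, labels, n_trials=10, seed=7)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_class_size_preconditions(self):
        x = np.zeros((10, 2))
        with pytest.raises(ValueError):
            confounder_accuracy(x, np.array(["a"] * 10), n_trials=5)
        with pytest.raises(ValueError):
            confounder_accuracy(x, np.array(["a"] * 8 + ["b"] * 2), n_trials=5)


class TestPairedTests:
    def test_identical_vectors_give_p_one(self):
        a = AccuracyDistribution("m1", "center", np.full(20, 0.8))
        b = AccuracyDistribution("m2", "center", np.full(20, 0.8))
        assert paired_accuracy_test(a, b) == 1.0

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(3)
        base = 0.8 + 0.001 * rng.standard_normal(50)
        a = AccuracyDistribution("m1", "center", base)
        b = AccuracyDistribution("m2", "center", base - 0.2)
        assert paired_accuracy_test(a, b) < 1e-6

    def test_two_sided_consistent_with_one_sided(self):
        rng = np.random.default_rng(4)
        a = AccuracyDistribution("m1", "c", 0.7 + 0.01 * rng.standard_normal(30))
        b = AccuracyDistribution("m2", "c", 0.69 + 0.01 * rng.standard_normal(30))
        two = paired_accuracy_test(a, b, "two-sided")
        one = paired_accuracy_test(a, b, "greater")
        assert two == pytest.approx(2 * min(one, 1 - one), rel=1e-9)

    def test_unequal_lengths_rejected(self):
        a = AccuracyDistribution("m1", "c", np.zeros(5))
        b = AccuracyDistribution("m2", "c", np.zeros(6))
        with pytest.raises(ValueError):
            paired_accuracy_test(a, b)

    def test_concordance_direction_symmetry(self):
        rng = np.random.default_rng(5)
        x = 0.7 + 0.01 * rng.standard_normal(20)
        a = ConcordanceReport("m1", "centroid", x, x + 0.05 + 0.001 * rng.standard_normal(20))
        b = ConcordanceReport("m2", "centroid", x, x)
        p_ab = paired_concordance_test(a, b, "greater")
        p_ba = paired_concordance_test(b, a, "greater")
        assert p_ab < 0.05
        assert p_ab + p_ba == pytest.approx(1.0, abs=1e-9)


class TestRepresentations:
    def test_centroid_hand_example(self):
        reps = build_representation(
            np.array(["p", "p"]), np.array([[0.0, 0.0], [2.0, 2.0]]), "centroid"
        )
        assert np.allclose(reps.matrix, [[1.0, 1.0]])

    def test_cloud_description_hand_example(self):
        # 1-D lesions at 0, 1, 2: pairwise distances {1,1,2}, centroid 1,
        # centroid distances {1,0,1}; population sds
        reps = build_representation(
            np.array(["p"] * 3), np.array([[0.0], [1.0], [2.0]]), "cloud-description"
        )
        mean_pair, sd_pair, mean_cent, sd_cent = reps.matrix[0]
        assert mean_pair == pytest.approx(4 / 3)
        assert sd_pair == pytest.approx(np.sqrt(2) / 3)
        assert mean_cent == pytest.approx(2 / 3)
        assert sd_cent == pytest.approx(np.sqrt(2) / 3)

    def test_combined_concatenates(self):
        pts = np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]])
        pids = np.array(["p"] * 3)
        cen = build_representation(pids, pts, "centroid").matrix
        cld = build_representation(pids, pts, "cloud-description").matrix
        comb = build_representation(pids, pts, "combined").matrix
        assert np.allclose(comb, np.hstack([cen, cld]))

    def test_single_lesion_patient_flagged_with_zero_indexes(self):
        reps = build_representation(
            np.array(["p", "q", "q"]),
            np.array([[1.0, 2.0], [0.0, 0.0], [2.0, 2.0]]),
            "cloud-description",
        )
        assert reps.degenerate == ["p"]
        row_p = reps.matrix[reps.patients.index("p")]
        assert np.all(row_p == 0.0)

    def test_permutation_invariance_within_patient(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((6, 4))
        pids = np.array(["a"] * 3 + ["b"] * 3)
        perm = np.array([2, 0, 1, 5, 3, 4])
        for kind in ("centroid", "cloud-description", "combined"):
            a = build_representation(pids, pts, kind)
            b = build_representation(pids[perm], pts[perm], kind)
            assert np.allclose(a.matrix, b.matrix)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_representation(np.array([]), np.zeros((0, 3)), "centroid")


def make_survival(patients, times, events):
    return SurvivalTable(
        pd.DataFrame({"patient_id": patients, "time": times, "event": events})
    )


class TestPrognosticEval:
    def test_null_signal_concordance_near_half(self):
        rng = np.random.default_rng(7)
        patients = [f"p{i}" for i in range(150)]
        reps = RepresentationSet("centroid", patients, rng.standard_normal((150, 4)))
        surv = make_survival(patients, rng.exponential(10, 150) + 0.1, np.ones(150, int))
        report = prognostic_eval(reps, surv, n_splits=20, seed=0)
        assert abs(report.mean_test - 0.5) < 0.07

    def test_generating_risk_score_ranks_training_set(self):
        rng = np.random.default_rng(8)
        patients = [f"p{i}" for i in range(120)]
        risk = rng.standard_normal(120)
        times = np.exp(-5.0 * risk) * rng.exponential(1.0, 120) + 1e-3
        reps = RepresentationSet("centroid", patients, risk[:, None])
        surv = make_survival(patients, times, np.ones(120, int))
        report = prognostic_eval(reps, surv, n_splits=5, seed=1)
        assert report.mean_train >= 0.9

    def test_splits_paired_across_modalities(self):
        rng = np.random.default_rng(9)
        patients = [f"p{i}" for i in range(60)]
        surv = make_survival(patients, rng.exponential(5, 60) + 0.1, np.ones(60, int))
        m = rng.standard_normal((60, 3))
        a = prognostic_eval(RepresentationSet("centroid", patients, m), surv, n_splits=4, seed=5)
        b = prognostic_eval(RepresentationSet("centroid", patients, m.copy()), surv, n_splits=4, seed=5)
        assert np.array_equal(a.test_ci, b.test_ci)

    def test_missing_survival_records_rejected(self):
        reps = RepresentationSet("centroid", ["a", "b"], np.zeros((2, 2)))
        surv = make_survival(["a"], [1.0], [1])
        with pytest.raises(ValueError, match="missing"):
            prognostic_eval(reps, surv)


class TestExperimentReport:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        cfg = SimulationConfig(
            seed=17, n_patients_per_center=(25, 20), lesion_mean=4, censoring_fraction=0.5
        )
        _, confounded, survival, _ = generate_cohort(cfg)
        std, _ = standardize(confounded)
        return std, survival

    def test_tables_have_expected_structure(self, small_cohort):
        std, survival = small_cohort
        ids = std.df[["lesion_id", "patient_id", "center", "scanner"]]
        modalities = {"radiomics": std.features, "dual_adae": std.features[:, :16]}
        report = experiment_report(
            modalities, ids, survival, n_trials=8, n_splits=4, seed=0
        )
        acc = report["accuracy_table"]
        assert set(acc["modality"]) == {"radiomics", "dual_adae"}
        assert {"center_mean", "center_sd", "scanner_mean"} <= set(acc.columns)
        conc = report["concordance_table"]
        assert {"centroid_test_mean", "cloud-description_p_test"} <= set(conc.columns)

    def test_identical_modalities_not_flagged_significant(self, small_cohort):
        std, survival = small_cohort
        ids = std.df[["lesion_id", "patient_id", "center", "scanner"]]
        modalities = {"radiomics": std.features, "copy": std.features.copy()}
        report = experiment_report(modalities, ids, None, n_trials=6, seed=0)
        acc = report["accuracy_table"].set_index("modality")
        assert not acc.loc["copy", "center_significant"]
        assert acc.loc["copy", "center_p_vs_radiomics"] == 1.0

    def test_misaligned_modalities_rejected(self, small_cohort):
        std, _ = small_cohort
        ids = std.df[["lesion_id", "patient_id", "center", "scanner"]]
        with pytest.raises(ValueError, match="aligned"):
            experiment_report({"radiomics": std.features[:-1]}, ids, None, n_trials=5, seed=0)

    def test_tables_round_trip_through_csv(self, small_cohort, tmp_path):
        std, survival = small_cohort
        ids = std.df[["lesion_id", "patient_id", "center", "scanner"]]
        report = experiment_report({"radiomics": std.features}, ids, None, n_trials=5, seed=0)
        path = tmp_path / "table1.csv"
        report["accuracy_table"].to_csv(path, index=False)
        again = pd.read_csv(path)
        assert again.shape == report["accuracy_table"].shape
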