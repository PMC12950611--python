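"""Patient-aware validation machinery on controlled synthetic features.

These tests build small Gaussian feature sets directly (no waveforms), so
the statistical properties of the validation protocol can be checked
quickly and exactly.
"""

import numpy as np
import pandas as pd
import pytest

from flimcore.classify import (
    BINARY_TASKS,
    ClassifierSpec,
    bootstrap_ci,
    class_costs,
    compare_classifiers,
    make_lopo_folds,
    naive_kfold_auc,
    run_binary_task,
    run_three_class,
    train_predict_fold,
    weighted_roc_auc,
)
from flimcore.errors import InvalidParameterError, UndefinedAUCError

BANDS = ("band390", "band470", "band542", "band629")


def synth_features(
    n_patients=8,
    points_per_patient=60,
    class_means=None,
    patient_sd=0.3,
    point_sd=0.3,
    seed=0,
    labels=("benign", "GP3", "GP4+"),
):
    """Gaussian per-band lifetime features with patient random effects."""
    if class_means is None:
        class_means = {"benign": 4.4, "GP3": 3.5, "GP4+": 2.8}
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        pid = f"P{p:02d}"
        offset = rng.normal(0, patient_sd)
        for i in range(points_per_patient):
            lbl = labels[(p + i) % len(labels)]
            base = class_means[lbl] + offset
            row = {
                "patient_id": pid,
                "core_id": f"{pid}C0",
                "position_mm": i * 0.0217,
                "pass_index": 0,
                "label": lbl,
            }
            for k, b in enumerate(BANDS):
                contrast = 1.0 if b == "band470" else 0.3
                row[f"{b}_lt"] = contrast * base + rng.normal(0, point_sd) + k
            rows.append(row)
    return pd.DataFrame(rows)


FAST = ClassifierSpec(train_stride=1)


class TestLOPOFolds:
    def test_twenty_patients(self):
        ids = [f"P{i}" for i in range(20) for _ in range(5)]
        folds = make_lopo_folds(ids)
        assert len(folds) == 20
        for p, train in folds.items():
            assert p not in train
            assert len(train) == 19

    def test_two_patients_complementary(self):
        folds = make_lopo_folds(["A", "B", "A"])
        assert folds == {"A": ["B"], "B": ["A"]}

    def test_record_order_invariance(self):
        a = make_lopo_folds(["B", "A", "C"])
        b = make_lopo_folds(["C", "C", "A", "B"])
        assert a == b

    def test_single_patient_error(self):
        with pytest.raises(InvalidParameterError):
            make_lopo_folds(["A", "A"])


class TestClassCosts:
    def test_balanced(self):
        costs = class_costs(["a"] * 50 + ["b"] * 50)
        assert costs == {"a": pytest.approx(1.0), "b": pytest.approx(1.0)}

    def test_90_10_split(self):
        costs = class_costs(["a"] * 90 + ["b"] * 10)
        assert costs["a"] == pytest.approx(0.2)
        assert costs["b"] == pytest.approx(1.8)

    def test_count_invariance(self):
        c1 = class_costs(["a"] * 9 + ["b"])
        c2 = class_costs(["a"] * 900 + ["b"] * 100)
        assert c1["a"] == pytest.approx(c2["a"])

    def test_single_class_error(self):
        with pytest.raises(InvalidParameterError):
            class_costs(["a", "a"])


def pairwise_weighted_auc(scores, y, weights):
    """Exhaustive weighted Mann-Whitney over all +/- pairs (oracle)."""
    pos = np.nonzero(y)[0]
    neg = np.nonzero(~y)[0]
    num = 0.0
    den = 0.0
    for i in pos:
        for j in neg:
            w = weights[i] * weights[j]
            den += w
            if scores[i] > scores[j]:
                num += w
            elif scores[i] == scores[j]:
                num += 0.5 * w
    return num / den


class TestWeightedROC:
    def test_matches_pair_enumeration_oracle(self, rng):
        """Weighted trapezoidal ROC-AUC equals the exhaustive weighted
        pair statistic, including tied scores."""
        for trial in range(5):
            n = 150
            y = rng.random(n) < 0.4
            scores = np.round(rng.random(n), 2)  # force ties
            patients = rng.choice([f"P{i}" for i in range(6)], n)
            res = weighted_roc_auc(scores, y, patients)
            counts = pd.Series(patients).value_counts()
            w = np.array([1.0 / counts[p] for p in patients])
            assert res["auc"] == pytest.approx(
                pairwise_weighted_auc(scores, y, w), abs=1e-10
            )
            assert res["auc_unweighted"] == pytest.approx(
                pairwise_weighted_auc(scores, y, np.ones(n)), abs=1e-10
            )

    def test_perfect_separation(self):
        y = np.array([True] * 5 + [False] * 5)
        s = np.array([0.9] * 5 + [0.1] * 5)
        patients = ["A"] * 3 + ["B"] * 7
        assert weighted_roc_auc(s, y, patients)["auc"] == 1.0

    def test_single_patient_equals_unweighted(self, rng):
        y = rng.random(50) < 0.5
        y[0], y[1] = True, False
        s = rng.random(50)
        res = weighted_roc_auc(s, y, ["A"] * 50)
        assert res["auc"] == pytest.approx(res["auc_unweighted"])

    def test_hand_example_two_patients(self):
        """Patient A: (0.9,+), (0.1,-); patient B: (0.8,+), (0.2,-),
        (0.7,+), (0.3,-): all pairs are concordant, so AUC = 1."""
        s = np.array([0.9, 0.1, 0.8, 0.2, 0.7, 0.3])
        y = np.array([True, False, True, False, True, False])
        patients = ["A", "A", "B", "B", "B", "B"]
        res = weighted_roc_auc(s, y, patients)
        w = np.array([1 / 2, 1 / 2, 1 / 4, 1 / 4, 1 / 4, 1 / 4])
        assert res["auc"] == pytest.approx(pairwise_weighted_auc(s, y, w))
        assert res["auc"] == 1.0

    def test_one_class_missing(self):
        with pytest.raises(UndefinedAUCError):
            weighted_roc_auc(np.ones(5), np.ones(5, bool), ["A"] * 5)


class TestTrainPredictFold:
    def test_separable_blobs_perfect(self):
        df = synth_features(point_sd=0.01, patient_sd=0.0, seed=1)
        train = df[df["patient_id"] != "P00"]
        test = df[df["patient_id"] == "P00"]
        scores = train_predict_fold(train, test, FAST, ["benign", "GP3", "GP4+"])
        pred = np.array(["benign", "GP3", "GP4+"])[scores.argmax(axis=1)]
        assert (pred == test["label"].to_numpy()).mean() == 1.0

    def test_label_permutation_null(self):
        """Training on permuted labels yields chance-level AUC."""
        df = synth_features(n_patients=6, points_per_patient=40, seed=2,
                            patient_sd=0.0)
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            perm = df.copy()
            perm["label"] = rng.permutation(perm["label"].to_numpy())
            res = run_binary_task(perm, "gp4_vs_rest", FAST, rng_seed=seed)
            aucs.append(res.per_class["GP4+"].auc_weighted)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_duplicating_training_points_is_neutral(self):
        """Class frequencies and inverse-frequency costs cancel, so
        duplicating every training row leaves scores unchanged."""
        df = synth_features(n_patients=4, points_per_patient=30, seed=3)
        train = df[df["patient_id"] != "P00"]
        test = df[df["patient_id"] == "P00"]
        classes = ["benign", "GP3", "GP4+"]
        s1 = train_predict_fold(train, test, FAST, classes)
        s2 = train_predict_fold(
            pd.concat([train, train], ignore_index=True), test, FAST, classes
        )
        np.testing.assert_allclose(s1, s2, atol=2e-3)  # libsvm tol is 1e-3

    def test_zero_variance_feature_dropped(self, caplog):
        df = synth_features(n_patients=4, points_per_patient=30, seed=4)
        df["band390_lt"] = 5.0
        train = df[df["patient_id"] != "P00"]
        test = df[df["patient_id"] == "P00"]
        with caplog.at_level("WARNING"):
            scores = train_predict_fold(train, test, FAST, ["benign", "GP3", "GP4+"])
        assert np.isfinite(scores).all()
        assert "zero-variance" in caplog.text


class TestThreeClass:
    def test_well_separated_cohort_high_auc(self):
        df = synth_features(point_sd=0.05, patient_sd=0.02, seed=5)
        res = run_three_class(df, FAST, rng_seed=0)
        for cls, m in res.per_class.items():
            assert m is not None
            assert m.auc_weighted > 0.95, cls

    def test_intermediate_class_harder(self):
        """GP3 lies between benign and GP4+, so its one-vs-rest AUC trails
        the GP4+ AUC."""
        df = synth_features(point_sd=0.5, patient_sd=0.2, seed=6,
                            points_per_patient=90)
        res = run_three_class(df, FAST, rng_seed=0)
        assert res.per_class["GP4+"].auc_weighted > res.per_class["GP3"].auc_weighted

    def test_out_of_fold_coverage(self):
        df = synth_features(seed=7)
        res = run_three_class(df, FAST, rng_seed=0)
        for c in res.classes:
            assert res.scores[f"score_{c}"].notna().all()
        assert len(res.scores) == len(df)

    def test_more_information_does_not_hurt(self):
        """Four lifetime bands beat a single band on the same cohort."""
        df = synth_features(seed=8, point_sd=0.6, patient_sd=0.1,
                            points_per_patient=90)
        res4 = run_three_class(df, FAST, rng_seed=0)
        single = df.drop(columns=[f"{b}_lt" for b in BANDS if b != "band470"])
        res1 = run_three_class(single, FAST, rng_seed=0)
        assert (
            res4.per_class["GP4+"].auc_weighted
            >= res1.per_class["GP4+"].auc_weighted - 0.01
        )

    def test_class_in_single_patient_undefined(self):
        df = synth_features(n_patients=4, seed=9)
        df.loc[(df["label"] == "GP3") & (df["patient_id"] != "P01"), "label"] = "benign"
        res = run_three_class(df, FAST, rng_seed=0)
        assert res.per_class["GP3"] is None
        assert res.per_class["GP4+"] is not None


class TestNaiveKFold:
    def test_leakage_inflates_auc_with_patient_effects(self):
        df = synth_features(patient_sd=1.2, point_sd=0.5, seed=10,
                            n_patients=10, points_per_patient=80)
        naive = naive_kfold_auc(df, "gp4_vs_rest", FAST, rng_seed=0)
        lopo = run_binary_task(df, "gp4_vs_rest", FAST, rng_seed=0)
        assert naive["auc"] >= lopo.per_class["GP4+"].auc_weighted

    def test_exchangeable_when_no_patient_effect(self):
        df = synth_features(patient_sd=0.0, point_sd=0.5, seed=11,
                            n_patients=10, points_per_patient=80)
        naive = naive_kfold_auc(df, "gp4_vs_rest", FAST, rng_seed=0)
        lopo = run_binary_task(df, "gp4_vs_rest", FAST, rng_seed=0)
        assert abs(naive["auc"] - lopo.per_class["GP4+"].auc_weighted) < 0.03

    def test_leave_one_out_runs(self):
        df = synth_features(n_patients=2, points_per_patient=12, seed=12)
        res = naive_kfold_auc(df, "gp4_vs_rest", FAST, k=len(df), rng_seed=0)
        assert 0.0 <= res["auc"] <= 1.0


class TestBootstrap:
    def test_fixed_seed_reproducible(self):
        df = synth_features(seed=13)
        base = run_three_class(df, FAST, rng_seed=0)
        b1 = bootstrap_ci(df, FAST, B=30, rng_seed=5, base_result=base)
        b2 = bootstrap_ci(df, FAST, B=30, rng_seed=5, base_result=base)
        assert b1["ci"] == b2["ci"]
        assert b1["replicates"] == b2["replicates"]

    def test_degenerate_scores_zero_width(self):
        df = synth_features(seed=14)
        base = run_three_class(df, FAST, rng_seed=0)
        for c in base.classes:
            base.scores[f"score_{c}"] = 0.5
        b = bootstrap_ci(df, FAST, B=20, rng_seed=1, base_result=base)
        for c in base.classes:
            lo, hi = b["ci"][c]
            assert lo == hi == 0.5

    def test_wider_overlap_widens_ci(self):
        widths = []
        for point_sd in (0.1, 1.2):
            df = synth_features(seed=15, point_sd=point_sd, patient_sd=0.3,
                                n_patients=10)
            base = run_three_class(df, FAST, rng_seed=0)
            b = bootstrap_ci(df, FAST, B=40, rng_seed=2, base_result=base)
            lo, hi = b["ci"]["GP4+"]
            widths.append(hi - lo)
        assert widths[0] < widths[1]

    def test_refit_mode_runs_and_differs_per_copy(self):
        df = synth_features(n_patients=6, points_per_patient=24, seed=16)
        b = bootstrap_ci(df, FAST, B=3, rng_seed=3, mode="refit")
        for c, ci in b["ci"].items():
            if ci is not None:
                assert ci[0] <= ci[1]

    def test_too_few_patients(self):
        df = synth_features(n_patients=3, seed=17)
        with pytest.raises(InvalidParameterError):
            bootstrap_ci(df, FAST, B=5, rng_seed=0)


class TestCompareClassifiers:
    def test_table_shape_and_sanity(self):
        df = synth_features(point_sd=0.05, patient_sd=0.02, seed=18)
        table = compare_classifiers(df, spec=FAST, rng_seed=0)
        assert list(table.index) == ["svm_rbf", "lda", "qda", "logistic", "tree"]
        assert list(table.columns) == ["benign", "GP3", "GP4+"]
        assert (table > 0.9).all().all()

    def test_subset_of_families(self):
        df = synth_features(seed=19, n_patients=4, points_per_patient=30)
        table = compare_classifiers(df, families=("lda", "tree"), spec=FAST,
                                    rng_seed=0)
        assert len(table) == 2


class TestBinaryTasks:
    def test_task_definitions(self):
        assert set(BINARY_TASKS) == {"two_class", "gp4_vs_rest"}

    def test_unknown_task(self):
        with pytest.raises(InvalidParameterError):
            run_binary_task(synth_features(seed=20), "bogus")
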