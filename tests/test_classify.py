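"""Feature selection, SVM cut-off training, classification, evaluation."""

import numpy as np
import pandas as pd
import pytest

import epitarget.classify as cl


def _toy(n_control=30, n_case=60, sep=20.0, sd=5.0, n_noise=3, seed=0):
    """Controls ~N(92, sd), cases ~N(92-sep, sd) on one informative feature,
    plus pure-noise features."""
    rng = np.random.default_rng(seed)
    n = n_control + n_case
    data = {"signal": np.concatenate([
        rng.normal(92.0, sd, n_control),
        rng.normal(92.0 - sep, sd, n_case),
    ])}
    for j in range(n_noise):
        data[f"noise{j}"] = rng.normal(70.0, sd, n)
    matrix = pd.DataFrame(data, index=[f"s{i}" for i in range(n)])
    labels = pd.Series(
        [cl.CONTROL_LABEL] * n_control + [cl.CASE_LABEL] * n_case,
        index=matrix.index,
    )
    return matrix, labels


class TestSplit:
    def test_stratified_70_30_counts(self):
        matrix, labels = _toy()
        tr_x, te_x, tr_y, te_y = cl.split_train_test(matrix, labels, 0.7, seed=0)
        assert (tr_y == cl.CONTROL_LABEL).sum() == 21
        assert (tr_y == cl.CASE_LABEL).sum() == 42
        assert (te_y == cl.CONTROL_LABEL).sum() == 9
        assert (te_y == cl.CASE_LABEL).sum() == 18
        assert set(tr_x.index) | set(te_x.index) == set(matrix.index)

    def test_deterministic_under_seed(self):
        matrix, labels = _toy()
        a = cl.split_train_test(matrix, labels, 0.7, seed=5)
        b = cl.split_train_test(matrix, labels, 0.7, seed=5)
        assert list(a[0].index) == list(b[0].index)

    def test_degenerate_ratios_rejected(self):
        matrix, labels = _toy()
        for ratio in (0.0, 1.0):
            with pytest.raises(ValueError):
                cl.split_train_test(matrix, labels, ratio, seed=0)

    def test_single_class_rejected(self):
        matrix, labels = _toy()
        with pytest.raises(ValueError):
            cl.split_train_test(matrix, labels[labels == cl.CASE_LABEL].pipe(
                lambda s: s.reindex(matrix.index, fill_value=cl.CASE_LABEL)
            ), 0.7, seed=0)


class TestImpute:
    def test_all_missing_feature_dropped(self):
        train = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        filled, _, info = cl.impute_missing(train)
        assert info["dropped_features"] == ["b"]
        assert list(filled.columns) == ["a"]

    def test_single_gap_filled_with_train_median(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0, np.nan]})
        test = pd.DataFrame({"a": [np.nan]})
        filled, test_f, _ = cl.impute_missing(train, test)
        assert filled["a"].iloc[3] == 2.0
        assert test_f["a"].iloc[0] == 2.0  # test uses the training median

    def test_complete_data_identity(self):
        train = pd.DataFrame({"a": [1.0, 2.0]})
        filled, _, info = cl.impute_missing(train)
        pd.testing.assert_frame_equal(filled, train)
        assert info["dropped_features"] == []


class TestShadowSelect:
    def test_separated_feature_important_noise_rejected(self):
        matrix, labels = _toy(sep=20.0, sd=5.0, n_noise=4, seed=1)
        out = cl.shadow_feature_select(matrix, labels, n_iter=30, seed=1)
        assert out["signal"] == "important"
        assert sum(v == "rejected" for k, v in out.items() if k != "signal") >= 3

    def test_shuffled_labels_select_nothing(self):
        matrix, labels = _toy(seed=2)
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            shuffled = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            out = cl.shadow_feature_select(
                matrix, shuffled, n_iter=25, alpha=0.01, seed=seed
            )
            hits += sum(v == "important" for v in out.values())
        assert hits == 0

    def test_requires_imputed_input(self):
        matrix, labels = _toy()
        matrix.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            cl.shadow_feature_select(matrix, labels)


class TestCompareCombinations:
    def test_row_count_and_ranking(self):
        matrix, labels = _toy(n_noise=2, seed=3)
        table = cl.compare_combinations(
            matrix, labels, list(matrix.columns), max_k=1, cv_folds=5
        )
        assert len(table) == 3
        assert table.iloc[0]["features"] == "signal"

    def test_parsimony_breaks_ties_between_duplicates(self):
        matrix, labels = _toy(n_noise=0, seed=4)
        matrix["signal_copy"] = matrix["signal"]
        table = cl.compare_combinations(
            matrix, labels, ["signal", "signal_copy"], max_k=2, cv_folds=5
        )
        assert table.iloc[0]["n_features"] == 1


class TestTrainCutoff:
    def test_noise_free_cutoff_between_class_centres(self):
        matrix, labels = _toy(sd=0.0, n_noise=0)
        matrix["signal"] += np.linspace(0, 1e-6, len(matrix))  # avoid sd=0
        model = cl.train_cutoff_model(matrix, labels, ["signal"])
        assert 72.0 < model.cutoff_raw_percent < 92.0
        assert model.case_side == "below"

    def test_label_swap_flips_side_keeps_cutoff(self):
        matrix, labels = _toy(seed=5)
        swapped = labels.map(
            {cl.CASE_LABEL: cl.CONTROL_LABEL, cl.CONTROL_LABEL: cl.CASE_LABEL}
        )
        m1 = cl.train_cutoff_model(matrix, labels, ["signal"])
        m2 = cl.train_cutoff_model(matrix, swapped, ["signal"])
        assert m1.cutoff_raw_percent == pytest.approx(m2.cutoff_raw_percent, abs=1e-6)
        assert m1.case_side == "below" and m2.case_side == "above"

    def test_z_round_trip_identity(self):
        matrix, labels = _toy(seed=6)
        model = cl.train_cutoff_model(matrix, labels, ["signal"])
        f = "signal"
        z = (model.cutoff_raw_percent - model.z_mean[f]) / model.z_sd[f]
        assert z == pytest.approx(model.cutoff_z, abs=1e-12)

    def test_z_block_is_standardised(self):
        matrix, labels = _toy(seed=7)
        model = cl.train_cutoff_model(matrix, labels, ["signal"])
        z = model.z_transform(matrix)["signal"]
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1.0) < 1e-9

    def test_one_class_training_rejected(self):
        matrix, labels = _toy()
        with pytest.raises(ValueError):
            cl.train_cutoff_model(
                matrix, pd.Series(cl.CASE_LABEL, index=matrix.index), ["signal"]
            )

    def test_affine_rescaling_invariance(self):
        """Z-scoring makes the rule covariant: classifications are identical
        after any positive affine rescaling of the raw feature, and the
        cut-off transforms with the same map."""
        matrix, labels = _toy(seed=8)
        m1 = cl.train_cutoff_model(matrix, labels, ["signal"])
        scaled = matrix.copy()
        a, b = 0.37, 12.0
        scaled["signal"] = a * scaled["signal"] + b
        m2 = cl.train_cutoff_model(scaled, labels, ["signal"])
        assert m2.cutoff_raw_percent == pytest.approx(
            a * m1.cutoff_raw_percent + b, rel=1e-9
        )
        p1 = cl.classify(m1, matrix)["label"]
        p2 = cl.classify(m2, scaled)["label"]
        assert (p1 == p2).all()

    def test_model_json_round_trip(self, tmp_path):
        matrix, labels = _toy(seed=9)
        model = cl.train_cutoff_model(matrix, labels, ["signal"])
        path = tmp_path / "model.json"
        model.to_json(path)
        back = cl.ClassifierModel.from_json(path)
        assert back == model


class TestClassifyAndEvaluate:
    def test_value_at_cutoff_goes_to_control_side_flagged(self):
        matrix, labels = _toy(seed=10)
        model = cl.train_cutoff_model(matrix, labels, ["signal"])
        probe = pd.DataFrame({"signal": [model.cutoff_raw_percent]}, index=["p"])
        for col in matrix.columns:
            if col != "signal":
                probe[col] = 0.0
        out = cl.classify(model, probe)
        assert out.loc["p", "label"] == cl.CONTROL_LABEL
        assert bool(out.loc["p", "borderline"])

    def test_missing_value_unclassifiable(self):
        matrix, labels = _toy(seed=11)
        model = cl.train_cutoff_model(matrix, labels, ["signal"])
        probe = pd.DataFrame({"signal": [np.nan]}, index=["p"])
        out = cl.classify(model, probe)
        assert bool(out.loc["p", "unclassifiable"])
        assert pd.isna(out.loc["p", "label"])

    def test_perfect_separation_scores_ones(self):
        matrix, labels = _toy(sd=0.5, sep=30.0, seed=12)
        model = cl.train_cutoff_model(matrix, labels, ["signal"])
        report = cl.evaluate(model, matrix, labels, cv_folds=5)
        assert report.sensitivity == report.specificity == report.accuracy == 1.0
        assert report.auc == 1.0
        assert report.cv_accuracy and np.mean(report.cv_accuracy) == 1.0

    def test_confusion_arithmetic(self):
        report = cl.EvalReport(
            sensitivity=58 / 60,
            specificity=29 / 30,
            accuracy=87 / 90,
            auc=0.99,
            tp=58, fn=2, tn=29, fp=1,
        )
        assert report.sensitivity == pytest.approx(58 / 60)
        with pytest.raises(ValueError):
            cl.EvalReport(
                sensitivity=1.0, specificity=1.0, accuracy=0.5, auc=1.0,
                tp=10, fn=0, tn=10, fp=0,
            )

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(13)
        aucs = []
        for seed in range(10):
            matrix, labels = _toy(n_control=45, n_case=45, sep=0.0, seed=seed)
            model = cl.train_cutoff_model(matrix, labels, ["signal"], seed=seed)
            report = cl.evaluate(model, matrix, labels, cv_folds=0)
            aucs.append(report.auc)
        assert abs(np.median(aucs) - 0.5) <= 0.1

    def test_roc_is_monotone(self):
        matrix, labels = _toy(seed=14)
        model = cl.train_cutoff_model(matrix, labels, ["signal"])
        report = cl.evaluate(model, matrix, labels, cv_folds=0)
        fpr = [p[0] for p in report.roc_points]
        tpr = [p[1] for p in report.roc_points]
        assert fpr == sorted(fpr)
        assert tpr == sorted(tpr)
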