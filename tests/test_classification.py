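"""AUC computation, cross-validation, training, and average-rank comparison."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from netortho.classification import (
    ALGORITHMS,
    auc,
    average_rank,
    build_model,
    cross_validate,
    evaluate_methods,
    train_classifier,
)
from netortho.features import FEATURE_COLUMNS

from oracles import auc_by_pair_counting


def make_table(blast_pos, blast_neg, rng=None):
    """Feature table whose non-blast features are noise."""
    rng = rng or np.random.default_rng(0)
    n = len(blast_pos) + len(blast_neg)
    data = {col: rng.uniform(0, 1, size=n) for col in FEATURE_COLUMNS}
    data["blast"] = np.concatenate([blast_pos, blast_neg])
    table = pd.DataFrame(data)
    table.insert(0, "node_a", [f"a{i}" for i in range(n)])
    table.insert(1, "node_b", [f"b{i}" for i in range(n)])
    table["label"] = ["ortholog"] * len(blast_pos) + ["non-ortholog"] * len(blast_neg)
    return table


class TestAuc:
    def test_perfect_and_reversed_ordering(self):
        assert auc([3, 2, 1, 0], [1, 1, 0, 0]) == 100.0
        assert auc([0, 1, 2, 3], [1, 1, 0, 0]) == 0.0

    def test_three_point_example(self):
        # both positives outscore the single negative
        assert auc([3, 1, 2], [1, 0, 1]) == 100.0

    def test_ties_count_half(self):
        assert auc([1, 1], [1, 0]) == 50.0

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            auc([1, 2], [1, 1])

    def test_matches_exhaustive_pair_counting_and_sklearn(self):
        rng = np.random.default_rng(51)
        for _ in range(50):
            n = int(rng.integers(4, 51))
            scores = rng.integers(0, 10, size=n).astype(float)  # ties likely
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            expected = auc_by_pair_counting(scores, labels)
            assert auc(scores, labels) == pytest.approx(expected, abs=1e-9)
            assert auc(scores, labels) == pytest.approx(
                100.0 * roc_auc_score(labels, scores), abs=1e-9
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(53)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40).astype(bool)
        labels[0], labels[1] = True, False
        assert auc(scores, labels) == pytest.approx(
            auc(np.exp(scores) * 3 + 1, labels)
        )


class TestTrainClassifier:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_training_auc_is_100(self, algorithm):
        table = make_table([900.0] * 8, [10.0] * 8)
        model = train_classifier(table, algorithm, seed=0, features=("blast",))
        proba = model.predict_proba(table[["blast"]].to_numpy(float))[:, 1]
        assert auc(proba, table["label"] == "ortholog") == 100.0

    def test_logistic_boundary_between_two_points(self):
        table = make_table([900.0, 850.0], [10.0, 20.0])
        model = train_classifier(table, "logistic", features=("blast",))
        proba = model.predict_proba(np.array([[900.0], [455.0], [10.0]]))[:, 1]
        assert proba[0] > 0.5 > proba[2]

    def test_ensemble_is_mean_of_member_probabilities(self):
        rng = np.random.default_rng(57)
        table = make_table(rng.normal(500, 80, 12), rng.normal(300, 80, 12), rng)
        X = table[FEATURE_COLUMNS].to_numpy(float)
        y = (table["label"] == "ortholog").to_numpy(int)
        ensemble = build_model("ensemble", seed=3).fit(X, y)
        members = [
            build_model(name, seed=3).fit(X, y)
            for name in ("boosted_tree", "naive_bayes", "svm", "logistic")
        ]
        expected = np.mean([m.predict_proba(X) for m in members], axis=0)
        assert np.allclose(ensemble.predict_proba(X), expected, atol=1e-12)

    def test_single_class_rejected(self):
        table = make_table([900.0] * 4, [])
        with pytest.raises(ValueError, match="single class"):
            train_classifier(table, "logistic")


class TestCrossValidate:
    def test_separable_data_reaches_100(self):
        table = make_table([900.0] * 30, [10.0] * 30)
        assert cross_validate(table, "logistic", folds=10, seed=0) == 100.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(61)
        table = make_table(rng.normal(500, 50, 250), rng.normal(500, 50, 250), rng)
        value = cross_validate(table, "logistic", folds=10, seed=0)
        assert 43.0 <= value <= 57.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(63)
        table = make_table(rng.normal(500, 150, 30), rng.normal(420, 150, 30), rng)
        a = cross_validate(table, "ensemble", folds=5, seed=9)
        b = cross_validate(table, "ensemble", folds=5, seed=9)
        assert a == b

    def test_too_few_positives_advises_fewer_folds(self):
        table = make_table([900.0] * 3, [10.0] * 30)
        with pytest.raises(ValueError, match="fewer folds"):
            cross_validate(table, "logistic", folds=10)


class TestAverageRank:
    def test_always_best_method_ranks_first(self):
        grid = pd.DataFrame(
            {"m1": [90, 91, 92], "m2": [80, 81, 82], "m3": [70, 71, 72]},
            index=["d1", "d2", "d3"],
        )
        ranks = average_rank(grid)
        assert ranks["m1"] == 1.0
        assert ranks["m3"] == 3.0

    def test_ties_share_average_rank(self):
        grid = pd.DataFrame({"m1": [90, 80], "m2": [90, 80]}, index=["d1", "d2"])
        ranks = average_rank(grid)
        assert ranks["m1"] == ranks["m2"] == 1.5

    def test_evaluate_methods_report_layout(self, tmp_path):
        rng = np.random.default_rng(67)
        tables = {
            "ds1": make_table(rng.normal(600, 40, 12), rng.normal(200, 40, 12), rng),
        }
        report = evaluate_methods(tables, algorithms=("logistic", "naive_bayes"),
                                  folds=3, seed=0)
        assert list(report.aucs.columns) == ["logistic", "naive_bayes"]
        out = tmp_path / "report.tsv"
        report.to_tsv(out)
        content = out.read_text().splitlines()
        assert content[-1].startswith("Average Rank")
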