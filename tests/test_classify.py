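"""Classifier decision rules, the one-against-one vote and the LOPO driver."""

import numpy as np
import pytest

from wmtier.classify import (
    ClassifierSpec,
    compute_gamma,
    knn_predict,
    lda_train_predict,
    lopo_evaluate,
    lr_grid_train_predict,
    oao_vote,
    svm_train_predict,
)


class TestLda:
    def test_hand_computed_decision_value(self):
        # pooled covariance is exactly the identity by construction:
        # class scatters of +-a with a = sqrt(6/8), pooled over n-2 = 6
        a = np.sqrt(6 / 8)
        XA = np.array([[a, a], [-a, -a], [a, -a], [-a, a]])
        XB = XA + np.array([2.0, 0.0])
        X = np.vstack([XA, XB])
        y = np.array(["A"] * 4 + ["B"] * 4)
        labels, dec = lda_train_predict(X, y, np.array([[1.1, 5.0]]))
        # D(x) = (mu1-mu2)' x - 1/2 (mu1-mu2)'(mu1+mu2) = -2*1.1 + 2 = -0.2
        assert dec[0] == pytest.approx(-0.2, rel=1e-9)
        assert labels[0] == "B"

    def test_separated_gaussians_classified_at_their_means(self, rng):
        X = np.vstack([rng.standard_normal((10, 3)),
                       rng.standard_normal((10, 3)) + 6.0])
        y = np.array(["A"] * 10 + ["B"] * 10)
        labels, _ = lda_train_predict(X, y, np.array([[0.0, 0.0, 0.0], [6.0, 6.0, 6.0]]))
        assert list(labels) == ["A", "B"]

    def test_zero_decision_goes_to_negative_class(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array(["A", "A", "B", "B"])
        # symmetric point: decision exactly 0 -> negative (second sorted) class
        _, dec = lda_train_predict(X, y, np.array([[1.5]]))
        assert dec[0] == pytest.approx(0.0, abs=1e-12)
        labels, _ = lda_train_predict(X, y, np.array([[1.5]]))
        assert labels[0] == "B"

    def test_predictions_agree_with_sklearn(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        for s in range(5):
            r = np.random.default_rng(s)
            X = r.standard_normal((20, 4))
            X[:10] += 0.8
            y = np.array(["A"] * 10 + ["B"] * 10)
            Xt = r.standard_normal((30, 4))
            mine, _ = lda_train_predict(X, y, Xt)
            sk = LinearDiscriminantAnalysis().fit(X, y).predict(Xt)
            assert list(mine) == list(sk)

    def test_priors_shift_the_boundary(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array(["A", "A", "B", "B"])
        _, d_eq = lda_train_predict(X, y, np.array([[1.5]]), priors=(0.5, 0.5))
        _, d_sk = lda_train_predict(X, y, np.array([[1.5]]), priors=(0.9, 0.1))
        assert d_sk[0] > d_eq[0]


class TestSvm:
    def test_xor_solved_by_gaussian_kernel(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array(["A", "A", "B", "B"])
        labels, _ = svm_train_predict(X, y, X, C=100.0, gamma=1.0)
        assert list(labels) == list(y)

    def test_training_point_recovers_own_label(self):
        X = np.array([[0.0, 0.0], [4.0, 4.0]])
        y = np.array(["A", "B"])
        labels, _ = svm_train_predict(X, y, X[1:2], C=100.0)
        assert labels[0] == "B"

    def test_gamma_rule_arithmetic(self):
        # per-feature population variances exactly {1, 3}, d = 2
        X = np.array([[1.0, np.sqrt(3)], [-1.0, -np.sqrt(3)],
                      [1.0, np.sqrt(3)], [-1.0, -np.sqrt(3)]])
        assert compute_gamma(X) == pytest.approx(1 / (2 * 2.0))


class TestKnn:
    def test_single_class_neighbourhood(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        y = np.array(["A", "A", "A", "B", "B", "B"])
        assert knn_predict(X, y, np.array([[0.05]]))[0] == "A"

    def test_two_to_one_majority(self):
        X = np.array([[0.0], [0.2], [0.3], [10.0]])
        y = np.array(["A", "B", "B", "A"])
        assert knn_predict(X, y, np.array([[0.1]]))[0] == "B"

    def test_distance_tie_at_kth_neighbour_prefers_lower_index(self):
        # neighbours at distances {0, 1, 1, 1}: the two K-slots after the
        # nearest go to the earliest-indexed equidistant points
        X = np.array([[0.0], [1.0], [-1.0], [1.0]])
        y = np.array(["A", "B", "A", "C"])
        # k=3 neighbourhood: index 0 (A), then ties 1,2 -> B, A -> majority A
        assert knn_predict(X, y, np.array([[0.0]]))[0] == "A"

    def test_three_way_tie_resolves_to_nearest(self):
        X = np.array([[0.1], [0.2], [0.3]])
        y = np.array(["C", "B", "A"])
        assert knn_predict(X, y, np.array([[0.0]]))[0] == "C"


class TestLrGrid:
    def test_separable_data_classified(self):
        X = np.array([[0.0], [0.2], [0.1], [2.0], [2.1], [2.2]])
        y = np.array(["A", "A", "A", "B", "B", "B"])
        labels, chosen = lr_grid_train_predict(X, y, np.array([[0.05], [2.05]]))
        assert list(labels) == ["A", "B"]
        assert chosen in {(p, c) for p in ("l1", "l2")
                          for c in (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)}

    def test_accuracy_tie_prefers_smaller_c_then_l2(self):
        # every grid point below achieves inner accuracy 1.0 on this margin
        X = np.array([[-2.0], [-2.1], [-1.9], [2.0], [2.1], [1.9]])
        y = np.array(["A"] * 3 + ["B"] * 3)
        _, chosen = lr_grid_train_predict(
            X, y, np.array([[0.5]]),
            grid=(("l1", 1.0), ("l2", 10.0), ("l2", 1.0)))
        assert chosen == ("l2", 1.0)


class TestOaoVote:
    def test_majority_wins(self):
        assert oao_vote(["AD", "AD", "MCI"], [0.2, 0.4, 0.9]) == "AD"

    def test_three_way_tie_uses_decision_magnitude(self):
        assert oao_vote(["AD", "HC", "MCI"], [0.9, 0.1, 0.2]) == "AD"
        assert oao_vote(["AD", "HC", "MCI"], [0.1, 0.8, 0.2]) == "HC"

    def test_agreement_on_mci(self):
        assert oao_vote(["MCI", "MCI", "MCI"], None) == "MCI"

    def test_residual_tie_uses_fixed_class_order(self):
        assert oao_vote(["HC", "MCI", "AD"], [0.5, 0.5, 0.5]) == "AD"


class TestLopoEvaluate:
    def test_separable_four_participants_perfect(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = np.array(["A", "A", "B", "B"])
        rep = lopo_evaluate(X, y, ClassifierSpec("KNN", k=1))
        assert rep.accuracy == 1.0

    def test_fold_count_equals_n(self, rng):
        X = rng.standard_normal((9, 2))
        y = np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        rep = lopo_evaluate(X, y, ClassifierSpec("KNN"))
        assert rep.n == 9 and len(rep.predictions) == 9
        assert rep.confusion.sum() == 9

    def test_three_class_oao_runs_with_lda_and_svm(self, rng):
        X = np.vstack([rng.standard_normal((5, 2)),
                       rng.standard_normal((5, 2)) + 5,
                       rng.standard_normal((5, 2)) + np.array([5.0, -5.0])])
        y = np.array(["AD"] * 5 + ["MCI"] * 5 + ["HC"] * 5)
        for kind in ("LDA", "SVM"):
            rep = lopo_evaluate(X, y, ClassifierSpec(kind))
            assert rep.accuracy == 1.0

    def test_null_three_class_accuracy_near_chance(self):
        accs = []
        for s in range(200):
            r = np.random.default_rng(1000 + s)
            X = r.standard_normal((30, 3))
            y = np.array(["AD"] * 10 + ["MCI"] * 10 + ["HC"] * 10)
            accs.append(lopo_evaluate(X, y, ClassifierSpec("KNN")).accuracy)
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.05)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            lopo_evaluate(np.zeros((2, 1)), ["A", "B"], ClassifierSpec("KNN"))
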