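import numpy as np
import pandas as pd
import pytest

from noduleclick import (
    BeedClassifier,
    BinaryMask,
    compute_weights,
    confusion_metrics,
    equalized_downsample,
    mask_metrics,
    member_aucs,
    pairwise_auc,
    predict,
    train_beed,
)
from noduleclick.beed import auc_score
from noduleclick.phantom import TableSpec, make_feature_table
from conftest import brute_force_auc


class TestEqualizedDownsample:
    def test_reference_class_sizes_give_five_subsets(self):
        subsets = equalized_downsample(range(160), range(1000, 1030), seed=0)
        assert len(subsets) == 5
        used_major = set()
        for sub in subsets:
            major = [i for i in sub if i < 1000]
            minor = [i for i in sub if i >= 1000]
            assert len(major) == 30 and len(minor) == 30
            assert set(minor) == set(range(1000, 1030))
            used_major |= set(major)
        assert len(used_major) == 150  # 10 majority ids discarded

    def test_blocks_are_disjoint(self):
        subsets = equalized_downsample(range(8), range(100, 104), seed=1)
        blocks = [frozenset(i for i in s if i < 100) for s in subsets]
        assert len(blocks) == 2
        assert not (blocks[0] & blocks[1])

    def test_equal_sizes_single_subset(self):
        subsets = equalized_downsample(range(5), range(10, 15), seed=2)
        assert len(subsets) == 1
        assert len(subsets[0]) == 10

    def test_minority_larger_warns_single_subset(self):
        with pytest.warns(UserWarning):
            subsets = equalized_downsample(range(2), range(10, 15))
        assert len(subsets) == 1

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            equalized_downsample([], range(3))

    def test_conservation_on_random_sizes(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m, n = int(rng.integers(5, 200)), int(rng.integers(1, 50))
            if m < n:
                m, n = n, m
            subsets = equalized_downsample(range(m), range(10_000, 10_000 + n), seed=4)
            assert len(subsets) == m // n
            for s in subsets:
                assert sum(1 for i in s if i < 10_000) == n
                assert sum(1 for i in s if i >= 10_000) == n


class TestAuc:
    def test_perfect_ranking(self):
        assert auc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_half(self):
        assert auc_score([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                y[0], y[1] = 0, 1
            s = np.round(rng.random(n), 2)  # coarse scores force ties
            assert auc_score(y, s) == pytest.approx(brute_force_auc(y, s))
            assert pairwise_auc(y, s) == pytest.approx(brute_force_auc(y, s))


class TestWeights:
    @pytest.mark.parametrize(
        "aucs, expected",
        [
            ([0.6, 0.7, 0.8], [0.0, 0.5, 1.0]),
            ([0.5, 0.9], [0.0, 1.0]),
            ([0.75, 0.75, 0.75], [1.0, 1.0, 1.0]),
            ([0.9], [1.0]),
        ],
    )
    def test_min_max_normalisation(self, aucs, expected):
        assert compute_weights(aucs) == pytest.approx(expected)

    def test_weight_order_matches_auc_order(self):
        rng = np.random.default_rng(9)
        aucs = rng.uniform(0.4, 1.0, size=6)
        w = compute_weights(aucs)
        assert np.all(np.argsort(w) == np.argsort(aucs))
        assert max(w) == 1.0 and min(w) == 0.0


class TestMemberAucs:
    class _ByLabel:
        """Scores every sample by its true label (perfect member)."""
        classes_ = np.array([0, 1])

        def __init__(self, y):
            self.y = y

        def predict_proba(self, X):
            p = self.y[X[:, 0].astype(int)]
            return np.column_stack([1 - p, p])

    def test_perfect_member_auc_one(self):
        y = np.array([1, 1, 1, 1, 0, 0])
        X = np.arange(6, dtype=float)[:, None]  # column 0 is the row id
        subsets = [[0, 1, 4, 5], [2, 3, 4, 5]]
        members = [self._ByLabel(y), self._ByLabel(y)]
        assert member_aucs(subsets, members, X, y) == [1.0, 1.0]

    def test_single_member_skips_auc(self):
        assert member_aucs([[0, 1]], ["anything"], np.zeros((2, 1)), [0, 1]) == [1.0]

    def test_minority_deduplicated_in_evaluation(self):
        # both subsets share minority rows 4,5; the eval set of member 0 is
        # {2,3,4,5} (deduplicated), which a constant scorer ties at AUC 0.5
        class Const:
            classes_ = np.array([0, 1])

            def predict_proba(self, X):
                return np.full((len(X), 2), 0.5)

        y = np.array([1, 1, 1, 1, 0, 0])
        X = np.zeros((6, 1))
        aucs = member_aucs([[0, 1, 4, 5], [2, 3, 4, 5]], [Const(), Const()], X, y)
        assert aucs == [0.5, 0.5]


class TestBeedClassifier:
    def test_reference_shape_gives_five_members(self):
        table = make_feature_table(TableSpec(seed=0))
        model = train_beed(table, base_kind="LDA", seed=0)
        assert len(model.members_) == 5
        assert len(model.weights_) == 5
        assert all(0 <= w <= 1 for w in model.weights_)
        assert max(model.weights_) == 1.0

    def test_separable_table_all_weights_one(self):
        table = make_feature_table(TableSpec(n_majority=40, n_minority=10,
                                             delta=12.0, seed=1))
        model = train_beed(table, base_kind="LDA", seed=1)
        assert model.aucs_ == pytest.approx([1.0] * len(model.aucs_))
        assert model.weights_ == pytest.approx([1.0] * len(model.weights_))

    def test_same_seed_same_subsets(self):
        table = make_feature_table(TableSpec(seed=2))
        m1 = train_beed(table, base_kind="LDA", seed=5)
        m2 = train_beed(table, base_kind="LDA", seed=5)
        assert m1.subsets_ == m2.subsets_
        assert m1.weights_ == pytest.approx(m2.weights_)

    def test_feature_selection_restricts_inputs(self):
        table = make_feature_table(TableSpec(seed=3))
        model = train_beed(table, base_kind="LDA", feature_method="anova_f", k=4, seed=0)
        assert len(model.selected_features_) == 4
        # informative features dominate the selection
        assert set(model.selected_features_) <= {f"f{j}" for j in range(10)}

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        model = BeedClassifier(base_kind="LDA", k=3, random_state=1)
        params = model.get_params()
        assert params["base_kind"] == "LDA" and params["k"] == 3
        clone(model)  # must not raise
        table = make_feature_table(TableSpec(seed=4))
        X, y = table.drop(columns=["label"]), table["label"]
        fitted = model.fit(X, y)
        assert hasattr(fitted, "members_") and list(fitted.classes_) == [0, 1]
        proba = fitted.predict_proba(X)
        assert proba.shape == (len(X), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_missing_features_rejected(self):
        table = make_feature_table(TableSpec(seed=4))
        model = train_beed(table, base_kind="LDA", seed=0)
        with pytest.raises(ValueError, match="missing"):
            model.predict(pd.DataFrame({"f0": [0.0]}))


class TestVoting:
    def _fixed_model(self, weights, votes):
        class FixedVote:
            classes_ = np.array([0, 1])

            def __init__(self, v):
                self.v = v

            def predict(self, X):
                return np.full(len(X), self.v)

        model = BeedClassifier()
        model.members_ = [FixedVote(v) for v in votes]
        model.weights_ = list(weights)
        model.aucs_ = [0.5] * len(votes)
        model.subsets_ = [[0]] * len(votes)
        model.selected_features_ = ["f0"]
        model.classes_ = np.array([0, 1])
        return model

    def test_unanimous_positive(self):
        model = self._fixed_model([1, 1, 1], [1, 1, 1])
        X = pd.DataFrame({"f0": [0.0]})
        labels, scores = predict(model, X)
        assert labels[0] == 1 and scores[0] == 1.0

    def test_weighted_fraction_two_thirds(self):
        model = self._fixed_model([0.0, 0.5, 1.0], [1, 0, 1])
        X = pd.DataFrame({"f0": [0.0]})
        labels, scores = predict(model, X)
        assert scores[0] == pytest.approx(2 / 3)
        assert labels[0] == 1

    def test_exact_criterion_is_negative(self):
        model = self._fixed_model([1.0, 1.0], [1, 0])  # fraction exactly 0.5
        X = pd.DataFrame({"f0": [0.0]})
        labels, scores = predict(model, X)
        assert scores[0] == 0.5 and labels[0] == 0

    def test_zero_weights_fall_back_to_majority(self):
        model = self._fixed_model([0.0, 0.0, 0.0], [1, 1, 0])
        X = pd.DataFrame({"f0": [0.0]})
        labels, scores = predict(model, X)
        assert scores[0] == pytest.approx(2 / 3) and labels[0] == 1


class TestMetrics:
    def test_perfect_prediction(self):
        m = confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert (m.accuracy, m.sensitivity, m.specificity, m.dice) == (1, 1, 1, 1)

    def test_hand_computed_counts(self):
        # TP=2, FP=1, FN=1, TN=6
        y_true = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 0, 1, 0, 0, 0, 0, 0, 0]
        m = confusion_metrics(y_true, y_pred)
        assert (m.tp, m.fp, m.fn, m.tn) == (2, 1, 1, 6)
        assert m.accuracy == pytest.approx(0.8)
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.specificity == pytest.approx(6 / 7)

    def test_disjoint_masks_all_zero(self):
        a = np.zeros((6, 6), dtype=bool)
        b = np.zeros((6, 6), dtype=bool)
        a[:2, :2] = True
        b[4:, 4:] = True
        m = mask_metrics(BinaryMask(a), BinaryMask(b))
        assert m.dice == 0 and m.precision == 0 and m.recall == 0 and m.f_measure == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])


class TestImbalanceProperty:
    def test_beed_lifts_specificity_small_scale(self):
        """On overlapping imbalanced tables the balanced ensemble recovers
        minority (negative) accuracy a single majority-fit model loses."""
        from noduleclick.beed import make_base_classifier

        spec_b, spec_i = [], []
        for rep in range(5):
            tr = make_feature_table(TableSpec(seed=300 + rep))
            te = make_feature_table(TableSpec(seed=800 + rep))
            Xtr, ytr = tr.drop(columns=["label"]), tr["label"].to_numpy()
            Xte, yte = te.drop(columns=["label"]), te["label"].to_numpy()
            beed = BeedClassifier(base_kind="RF", random_state=rep).fit(Xtr, ytr)
            spec_b.append(confusion_metrics(yte, beed.predict(Xte)).specificity)
            rf = make_base_classifier("RF", random_state=rep).fit(Xtr.to_numpy(), ytr)
            spec_i.append(confusion_metrics(yte, rf.predict(Xte.to_numpy())).specificity)
        assert np.mean(spec_b) > np.mean(spec_i)
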