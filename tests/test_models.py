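import numpy as np
import pandas as pd
import pytest

from traitpred import models as md
from traitpred.synthetic import SimulationConfig, simulate_evolution


def make_committee(weight_rows, biases=None, families=None, phen="p"):
    families = families or [f"F{j}" for j in range(len(weight_rows[0]))]
    biases = biases if biases is not None else [0.0] * 5
    members = [
        md.LinearModel(weights=np.asarray(w, float), bias=b, C=1.0, cv_score=0.9)
        for w, b in zip(weight_rows, biases)
    ]
    return md.CommitteeModel(phenotype_id=phen, members=members, family_ids=families)


class TestTrainSvm:
    def test_separable_toy_reaches_training_accuracy_one(self):
        X = np.array([[1.0], [0.0], [1.0], [0.0]])
        y = np.array([1, 0, 1, 0])
        model = md.train_svm(X, y, C=1.0)
        pred = (model.decision(X) > 0).astype(int)
        assert (pred == y).all()

    def test_tiny_C_fully_regularises_weights_to_zero(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(30, 10)).astype(float)
        y = rng.integers(0, 2, size=30)
        model = md.train_svm(X, y, C=1e-6)
        assert np.all(model.weights == 0)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            md.train_svm(np.ones((4, 2)), np.ones(4), C=1.0)

    def test_row_duplication_equals_doubled_C(self):
        """Duplicating every row doubles the loss term, i.e. trains as 2C."""
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(40, 15)).astype(float)
        y = (X[:, 0] + rng.random(40) * 0.5 > 0.7).astype(int)
        dup = md.train_svm(np.vstack([X, X]), np.concatenate([y, y]), C=0.1)
        doubled = md.train_svm(X, y, C=0.2)
        np.testing.assert_allclose(dup.weights, doubled.weights, atol=1e-3)


class TestPredict:
    def test_vote_semantics(self):
        # 3 members fire on F0, 2 never fire -> positive for an F0 carrier
        committee = make_committee(
            [[1, 0], [1, 0], [1, 0], [0, 0], [0, 0]], biases=[-0.5] * 3 + [-0.5] * 2
        )
        profile = pd.Series({"F0": 1, "F1": 0})
        call = md.predict(committee, profile, sample_id="s")
        assert (call.positive_votes, call.call) == (3, "positive")

    @pytest.mark.parametrize("votes,call", [(5, "positive"), (3, "positive"),
                                            (2, "weak"), (1, "weak"), (0, "negative")])
    def test_call_from_votes_invariants(self, votes, call):
        assert md.PhenotypeCall.from_votes("s", "p", votes).call == call

    def test_missing_families_count_as_absent(self):
        committee = make_committee([[1, 1]] * 5, biases=[-0.5] * 5)
        # profile only mentions F0; F1 treated as 0 -> decision 1 - 0.5 > 0
        call = md.predict(committee, pd.Series({"F0": 1}), sample_id="s")
        assert call.call == "positive"

    def test_zero_weight_absent_family_padding_is_ignored(self):
        committee = make_committee([[1, 0]] * 5, biases=[-0.5] * 5)
        base = md.predict(committee, pd.Series({"F0": 1, "F1": 0}), "s")
        padded = md.predict(committee, pd.Series({"F0": 1, "F1": 0, "EXTRA": 1}), "s")
        assert base.positive_votes == padded.positive_votes


class TestConsensus:
    def call(self, call_type, votes):
        return md.PhenotypeCall("s", "p", votes, call_type)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("positive", 5), ("positive", 3), "positive"),
            (("positive", 4), ("negative", 0), "negative"),
            (("weak", 2), ("positive", 5), "negative"),  # weak is not positive
        ],
    )
    def test_intersection_rule(self, a, b, expected):
        assert md.consensus(self.call(*a), self.call(*b)).call == expected

    def test_mismatched_pair_rejected(self):
        other = md.PhenotypeCall("s2", "p", 5, "positive")
        with pytest.raises(ValueError):
            md.consensus(self.call("positive", 5), other)

    def test_consensus_positives_subset_of_components(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            va, vb = int(rng.integers(6)), int(rng.integers(6))
            a = md.PhenotypeCall.from_votes("s", "p", va)
            b = md.PhenotypeCall.from_votes("s", "p", vb)
            c = md.consensus(a, b)
            if c.call == "positive":
                assert a.call == "positive" and b.call == "positive"


class TestNestedCV:
    def test_too_few_labeled_samples_rejected(self, small_truth):
        y = small_truth.labels["phenotype"].iloc[:9]
        with pytest.raises(ValueError, match="folds"):
            md.nested_cv_train(small_truth.matrix, y, folds=10)

    def test_separable_fixture_reaches_perfect_outer_accuracy(self, separable_truth):
        y = separable_truth.labels["phenotype"]
        res = md.nested_cv_train(separable_truth.matrix, y, mode="phypat", seed=0)
        c = res.confusion
        assert c["FP"] == 0 and c["FN"] == 0
        assert c["TP"] + c["TN"] == int(y.notna().sum())

    def test_committee_has_five_members_sorted_by_score(self, separable_truth):
        y = separable_truth.labels["phenotype"]
        com = md.train_committee(separable_truth.matrix, y, seed=0)
        assert len(com.members) == 5
        scores = [m.cv_score for m in com.members]
        assert scores == sorted(scores, reverse=True)

    def test_determinism_under_fixed_seed(self, separable_truth):
        y = separable_truth.labels["phenotype"]
        c1 = md.train_committee(separable_truth.matrix, y, seed=3)
        c2 = md.train_committee(separable_truth.matrix, y, seed=3)
        for m1, m2 in zip(c1.members, c2.members):
            np.testing.assert_array_equal(m1.weights, m2.weights)
            assert m1.bias == m2.bias and m1.C == m2.C

    def test_pgl_event_rows_never_use_test_fold_taxa(self, monkeypatch):
        """No outer-test leaf may enter the pruned training tree of its fold."""
        cfg = SimulationConfig(n_leaves=30, n_families=25, n_causal=3, seed=5)
        truth = simulate_evolution(cfg)
        y = truth.labels["phenotype"]
        recorded = []
        original = md.event_training_rows

        def spy(tree, matrix, y_tr, **kw):
            recorded.append(frozenset(y_tr.index))
            return original(tree, matrix, y_tr, **kw)

        monkeypatch.setattr(md, "event_training_rows", spy)
        md.nested_cv_train(
            truth.matrix, y, tree=truth.tree, mode="phypat+PGL",
            folds=5, seed=9, gain_rate=0.3, loss_rate=0.3,
        )
        labeled = y.dropna()
        all_taxa = frozenset(labeled.index)
        from sklearn.model_selection import StratifiedKFold

        outer = StratifiedKFold(n_splits=5, shuffle=True, random_state=9)
        test_folds = [
            frozenset(labeled.index[te]) for _, te in outer.split(np.zeros(len(labeled)), labeled)
        ]
        for taxa in recorded:
            if taxa == all_taxa:  # final committee uses everything, by design
                continue
            assert any(not (taxa & fold) for fold in test_folds)

    def test_pgl_mode_without_tree_rejected(self, small_truth):
        with pytest.raises(ValueError, match="phylogeny"):
            md.train_committee(small_truth.matrix, small_truth.labels["phenotype"],
                               mode="phypat+PGL")


class TestPersistence:
    def test_archive_round_trip_preserves_predictions_exactly(self, separable_truth, tmp_path):
        y = separable_truth.labels["phenotype"]
        com = md.train_committee(separable_truth.matrix, y, seed=1)
        path = tmp_path / "models.json"
        md.save_committees({"phenotype": com}, path)
        loaded = md.load_committees(path)["phenotype"]
        X = separable_truth.matrix
        for m1, m2 in zip(com.members, loaded.members):
            np.testing.assert_array_equal(m1.weights, m2.weights)
            assert m1.bias == m2.bias
        calls1 = md.predict_matrix(com, X)
        calls2 = md.predict_matrix(loaded, X)
        assert [c.positive_votes for c in calls1] == [c.positive_votes for c in calls2]

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError):
            md.load_committees(path)
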