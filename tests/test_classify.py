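import numpy as np
import pytest

from repform import (
    TechniqueForest,
    accept_proposal,
    balance_training_set,
    compute_feature_vector,
    reject_proposal,
)
from repform.classify import UnbalancedTrainingError


class TestBalancing:
    def test_fifty_forty_keeps_forty_of_each(self):
        labels = ["Acceptable"] * 50 + ["Aberrant"] * 40
        keep = balance_training_set(labels, seed=3)
        kept = [labels[i] for i in keep]
        assert kept.count("Acceptable") == 40
        assert kept.count("Aberrant") == 40
        assert len(keep) == len(set(keep)) == 80

    def test_already_balanced_all_retained(self):
        labels = ["Acceptable"] * 20 + ["Aberrant"] * 20
        assert balance_training_set(labels, seed=0) == list(range(40))

    def test_three_class_minority_rule(self):
        labels = ["A"] * 30 + ["B"] * 20 + ["C"] * 10
        kept = [labels[i] for i in balance_training_set(labels, seed=1)]
        assert kept.count("A") == kept.count("B") == kept.count("C") == 10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            balance_training_set(["Acceptable"] * 10, seed=0)

    def test_deterministic_given_seed(self):
        labels = ["A"] * 37 + ["B"] * 12
        assert balance_training_set(labels, seed=9) == balance_training_set(labels, seed=9)

    def test_mapping_input_returns_keys(self):
        labels = {("s", "e", i): ("A" if i < 6 else "B") for i in range(10)}
        kept = balance_training_set(labels, seed=2)
        assert len(kept) == 8
        assert all(k in labels for k in kept)


def toy_model(n_per_class=10, sep=4.0, n_features=306, seed=0, n_trees=50):
    rng = np.random.default_rng(seed)
    x_a = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    x_b = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    x_b[:, :10] += sep
    exog = np.vstack([x_a, x_b])
    endog = ["Acceptable"] * n_per_class + ["Aberrant"] * n_per_class
    return TechniqueForest(endog, exog, exercise="squat", n_trees=n_trees)


class TestTraining:
    def test_unbalanced_refused_with_guidance(self):
        rng = np.random.default_rng(0)
        exog = rng.normal(size=(30, 306))
        endog = ["Acceptable"] * 20 + ["Aberrant"] * 10
        with pytest.raises(UnbalancedTrainingError, match="balance_training_set"):
            TechniqueForest(endog, exog)

    def test_default_hyperparameters(self):
        model = toy_model(n_trees=400)
        results = model.fit(seed=0)
        assert results.n_trees == 400
        assert results.forest.n_estimators == 400
        assert results.forest.max_features == "sqrt"
        assert int(np.sqrt(306)) == 17  # the realized per-split subset size

    def test_seeded_determinism(self):
        probe = np.random.default_rng(7).normal(size=(20, 306))
        r1 = toy_model().fit(seed=5)
        r2 = toy_model().fit(seed=5)
        np.testing.assert_array_equal(r1.predict(probe)[0], r2.predict(probe)[0])
        np.testing.assert_array_equal(r1.predict(probe)[1], r2.predict(probe)[1])

    def test_separated_classes_high_oob(self):
        results = toy_model(sep=4.0).fit(seed=0)
        assert results.oob_accuracy >= 0.9

    def test_identical_class_distributions_chance_oob(self):
        from repform import SynthConfig, generate_labeled_dataset

        db = generate_labeled_dataset(
            SynthConfig(n_reps=20, seed=0),
            SynthConfig(n_reps=20, seed=0, deviation="frontal_wobble", deviation_magnitude=0.0),
            seed=9,
        )
        results = TechniqueForest.from_database(db, "squat").fit(seed=0)
        assert 0.35 <= results.oob_accuracy <= 0.65

    def test_summary_mentions_key_facts(self):
        results = toy_model().fit(seed=0)
        text = results.summary()
        for token in ("squat", "OOB accuracy", "Acceptable", "Trees:"):
            assert token in text


class TestPrediction:
    def test_training_exemplar_strong_vote(self):
        model = toy_model(sep=5.0)
        results = model.fit(seed=0)
        label, vote = results.predict(model.exog[0])
        assert label == "Acceptable"
        assert vote > 0.8

    def test_feature_permutation_invariance(self):
        model = toy_model()
        results = model.fit(seed=1)
        rng = np.random.default_rng(3)
        perm = rng.permutation(306)
        names = tuple(results.feature_order[i] for i in perm)
        probe = model.exog[5]
        direct = results.predict(probe)
        permuted = results.predict(probe[perm], feature_names=names)
        assert direct == permuted

    def test_name_mismatch_lists_discrepancy(self):
        results = toy_model().fit(seed=1)
        names = list(results.feature_order)
        names[0] = "not_a_feature"
        with pytest.raises(ValueError, match="not_a_feature"):
            results.predict(np.zeros(306), feature_names=names)

    def test_exact_tie_breaks_to_acceptable(self):
        results = toy_model().fit(seed=0)

        class SplitForest:
            classes_ = np.array(["Aberrant", "Acceptable"])

            def predict_proba(self, values):
                return np.full((len(values), 2), 0.5)

        results.forest = SplitForest()
        label, vote = results.predict(np.zeros(306))
        assert label == "Acceptable"
        assert vote == 0.5

    def test_wrong_width_rejected(self):
        results = toy_model().fit(seed=0)
        with pytest.raises(ValueError, match="306"):
            results.predict(np.zeros(10))


class TestDatabaseWorkflow:
    def test_from_database_balances_and_fits(self, labeled_db):
        model = TechniqueForest.from_database(labeled_db, "squat", balance_seed=0, n_trees=100)
        assert len(model.endog) == 40  # 20/20 already balanced
        results = model.fit(seed=0)
        assert results.oob_accuracy > 0.8

    def test_auto_label_proposals_match_truth(self, labeled_db):
        import copy

        db = copy.deepcopy(labeled_db)
        # hold the last 5 reps of each class out as "unlabeled"
        unlabeled_keys = [k for k in db.keys() if k[2] > 15]
        truth = {k: db.get(k).label for k in unlabeled_keys}
        for k in unlabeled_keys:
            rep = db.get(k)
            rep.label = "Acceptable"
            rep.labeled = False
        train_keys = [k for k in db.keys() if k[2] <= 15]
        import repform

        matrix, labels, keys = repform.build_feature_matrix(db, "squat")
        idx = [keys.index(k) for k in train_keys]
        model = TechniqueForest(
            [labels[i] for i in idx], matrix[idx], exercise="squat", n_trees=100
        )
        results = model.fit(seed=0)
        proposals = results.auto_label(db)
        assert {p.rep_key for p in proposals} == set(unlabeled_keys)
        agree = sum(p.proposed_label == truth[p.rep_key] for p in proposals)
        assert agree >= 9  # >= 9 of 10 on well-separated classes

        # accept commits; reject queues for manual review
        accept_proposal(db, proposals[0])
        assert db.get(proposals[0].rep_key).label == proposals[0].proposed_label
        assert db.get(proposals[0].rep_key).labeled
        reject_proposal(db, proposals[1])
        assert not db.get(proposals[1].rep_key).labeled
        assert proposals[1].rep_key in db.pending_review

    def test_exercise_mismatch(self, labeled_db):
        results = TechniqueForest.from_database(labeled_db, "squat").fit(seed=0)
        results.exercise = "lunge"
        with pytest.raises(ValueError, match="lunge"):
            results.auto_label(labeled_db, keys=labeled_db.keys()[:1])
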