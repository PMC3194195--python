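"""Vector assembly, clustering, folds, training, metrics and CV protocol."""

import numpy as np
import pytest

from sap3d.io_formats import MutationRecord
from sap3d.model_eval import (CVResult, FeatureScaling, apply_scaling,
                              assemble_vector, auc_rank, balance_with_reverse,
                              cluster_proteins, compute_metrics, cross_validate,
                              fit_scaling, holdout_by_function, load_model,
                              make_folds, mcc_from_counts, pairwise_identity,
                              predict, predict_proba, read_feature_tsv,
                              reliability_curve, reliability_index, roc_points,
                              save_model, stratify_by_rsa, train,
                              write_feature_tsv, FeatureTable)


def rec(pid, label, position=1, wt="A", mut="V"):
    return MutationRecord(pid, "A", position, wt, mut, label)


class TestAssembleVector:
    def test_structure_variant_length(self):
        v = assemble_vector(np.zeros(20), np.zeros(21), np.zeros(5),
                            np.zeros(4), np.zeros(2), "3d")
        assert v.shape == (52,)

    def test_sequence_variant_length(self):
        v = assemble_vector(np.zeros(20), np.zeros(20), np.zeros(5),
                            np.zeros(4), np.zeros(2), "seq")
        assert v.shape == (51,)

    def test_block_order_is_fixed(self):
        v = assemble_vector(np.full(20, 1.0), np.full(21, 2.0), np.full(5, 3.0),
                            np.full(4, 4.0), np.full(2, 5.0), "3d")
        assert (v[:20] == 1).all() and (v[20:41] == 2).all()
        assert (v[41:46] == 3).all() and (v[46:50] == 4).all()
        assert (v[50:] == 5).all()

    def test_wrong_block_length_rejected(self):
        with pytest.raises(ValueError, match="block length"):
            assemble_vector(np.zeros(20), np.zeros(20), np.zeros(5),
                            np.zeros(4), np.zeros(2), "3d")

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            assemble_vector(np.zeros(20), np.full(21, np.nan), np.zeros(5),
                            np.zeros(4), np.zeros(2), "3d")


class TestReverseBalancing:
    def test_reverse_appended_for_neutrals_only(self):
        records = [rec("P1", "disease", 5, "C", "S"),
                   rec("P1", "neutral", 10, "A", "V")]
        balanced = balance_with_reverse(records)
        assert len(balanced) == 3
        reverse = balanced[2]
        assert (reverse.wt, reverse.mut, reverse.label) == ("V", "A", "neutral")
        assert reverse.position == 10 and reverse.is_reverse

    def test_class_counts(self):
        records = ([rec("P1", "disease", p) for p in range(1, 6)]
                   + [rec("P2", "neutral", p) for p in range(1, 4)])
        balanced = balance_with_reverse(records)
        assert sum(r.label == "disease" for r in balanced) == 5
        assert sum(r.label == "neutral" for r in balanced) == 6

    def test_empty(self):
        assert balance_with_reverse([]) == []


class TestClustering:
    def test_identical_sequences_merge(self):
        clusters = cluster_proteins({"a": "ACDEFGHIKL" * 5, "b": "ACDEFGHIKL" * 5})
        assert clusters["a"] == clusters["b"]

    def test_unrelated_sequences_split(self):
        rng = np.random.default_rng(0)
        from sap3d._residues import AA1
        seqs = {f"p{i}": "".join(rng.choice(list(AA1), 80)) for i in range(4)}
        clusters = cluster_proteins(seqs)
        assert len(set(clusters.values())) == 4

    def test_single_linkage_transitivity(self):
        rng = np.random.default_rng(1)
        from sap3d._residues import AA1
        x1, x2, x3, x4 = ("".join(rng.choice(list(AA1), 50)) for _ in range(4))
        seqs = {"A": x1 + x2, "B": x1 + x3, "C": x4 + x3}
        assert pairwise_identity(seqs["A"], seqs["B"]) >= 0.3
        assert pairwise_identity(seqs["B"], seqs["C"]) >= 0.3
        assert pairwise_identity(seqs["A"], seqs["C"]) < 0.3
        clusters = cluster_proteins(seqs)
        assert len(set(clusters.values())) == 1


class TestFolds:
    def test_leave_one_protein_out(self):
        records = [rec(f"P{i}", "disease" if i % 2 else "neutral")
                   for i in range(6)]
        clusters = {f"P{i}": i for i in range(6)}
        plan = make_folds(records, clusters, k=6, seed=0)
        assert sorted(len(f) for f in plan.folds) == [1] * 6

    def test_partition_and_cluster_confinement(self, small_world):
        w = small_world
        clusters = cluster_proteins(w.sequences)
        plan = make_folds(w.records, clusters, k=20, seed=3)
        plan.validate(w.records)  # raises on violation
        assert sum(len(f) for f in plan.folds) == len(w.records)

    def test_two_planted_clusters(self):
        records = ([rec("A1", "disease", p) for p in range(1, 4)]
                   + [rec("A2", "neutral", p) for p in range(1, 4)]
                   + [rec("B1", "disease", p) for p in range(1, 4)])
        clusters = {"A1": 0, "A2": 0, "B1": 1}
        plan = make_folds(records, clusters, k=2, seed=0)
        folds_by_cluster = {clusters[records[i].protein_id]
                            for f in plan.folds for i in f}
        assert folds_by_cluster == {0, 1}
        plan.validate(records)

    def test_too_many_folds(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_folds([rec("P1", "disease")], {"P1": 0}, k=2, seed=0)


class TestScaling:
    def test_min_max_and_extrapolation(self):
        X = np.array([[0.0, 5.0], [10.0, 5.0], [5.0, 5.0]])
        scaling = fit_scaling(X)
        Xs = apply_scaling(scaling, X)
        assert Xs[0, 0] == -1.0 and Xs[1, 0] == 1.0
        assert (Xs[:, 1] == 0.0).all()  # constant feature maps to 0
        held_out = apply_scaling(scaling, np.array([[20.0, 5.0]]))
        assert held_out[0, 0] > 1.0  # no clipping


def _separable_toy(n=60, seed=0, dim=52):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    y = (np.arange(n) % 2).astype(int)
    X[:, 0] = np.where(y == 1, 5.0, -5.0) + rng.normal(scale=0.1, size=n)
    return X, y


class TestTrainPredict:
    def test_separable_toy_perfect_training_accuracy(self):
        X, y = _separable_toy()
        model = train(X, y, seed=0)
        o_d = predict_proba(model, X)
        assert (((o_d >= 0.5).astype(int)) == y).all()

    def test_same_seed_identical_predictions(self):
        X, y = _separable_toy(seed=2)
        m1 = train(X, y, seed=5)
        m2 = train(X, y, seed=5)
        assert np.array_equal(predict_proba(m1, X), predict_proba(m2, X))

    def test_single_class_rejected(self):
        X = np.zeros((5, 52))
        with pytest.raises(ValueError, match="both classes"):
            train(X, np.ones(5, dtype=int))

    def test_prediction_fields(self):
        X, y = _separable_toy(seed=3)
        model = train(X, y, seed=0)
        pred = predict(model, X[1])
        assert pred.label == ("disease" if pred.o_disease >= 0.5 else "neutral")
        assert pred.ri == pytest.approx(20 * abs(pred.o_disease - 0.5))

    def test_length_mismatch(self):
        X, y = _separable_toy()
        model = train(X, y, seed=0, variant="3d")
        with pytest.raises(ValueError, match="length"):
            predict_proba(model, np.zeros((1, 51)))

    def test_reliability_index_mapping(self):
        assert reliability_index(0.5) == 0.0
        assert reliability_index(1.0) == 10.0
        assert reliability_index(0.8) == pytest.approx(6.0)

    def test_model_round_trip_and_version_guard(self, tmp_path):
        X, y = _separable_toy(seed=4)
        model = train(X, y, seed=0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        again = load_model(path)
        assert np.array_equal(predict_proba(model, X), predict_proba(again, X))
        import joblib
        joblib.dump({"format_version": 999, "model": None}, path)
        with pytest.raises(ValueError, match="incompatible"):
            load_model(path)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1, 1, 0, 0])
        m = compute_metrics(y, np.array([0.9, 0.8, 0.1, 0.2]))
        assert m.q2 == 1.0 and m.mcc == 1.0 and m.auc == 1.0

    def test_hand_computed_confusion(self):
        # p=40, n=30, u=10, o=20 for the disease class
        y = np.array([1] * 50 + [0] * 50)
        o_d = np.array([0.9] * 40 + [0.1] * 10 + [0.1] * 30 + [0.9] * 20)
        m = compute_metrics(y, o_d)
        assert m.q2 == pytest.approx(0.70, abs=1e-9)
        assert m.mcc == pytest.approx(1000 / np.sqrt(50 * 60 * 40 * 50), abs=1e-9)
        assert m.sensitivity["disease"] == pytest.approx(40 / 50, abs=1e-9)
        assert m.ppv["disease"] == pytest.approx(40 / 60, abs=1e-9)

    def test_single_class_prediction_convention(self):
        y = np.array([1, 1, 0])
        m = compute_metrics(y, np.array([0.9, 0.8, 0.7]))
        assert m.mcc == 0.0
        assert m.sensitivity["disease"] == 1.0
        assert any("degenerate" in f for f in m.flags)

    def test_mcc_equals_pearson(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p, n, u, o = rng.integers(1, 40, size=4)
            mcc = mcc_from_counts(p, n, u, o)
            y_true = np.r_[np.ones(p + u), np.zeros(n + o)]
            y_pred = np.r_[np.ones(p), np.zeros(u), np.zeros(n), np.ones(o)]
            assert mcc == pytest.approx(np.corrcoef(y_true, y_pred)[0, 1],
                                        abs=1e-12)

    def test_auc_rank_equals_trapezoid(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            scores = np.round(rng.random(n), 2)  # force ties
            fpr, tpr = roc_points(y, scores)
            assert auc_rank(y, scores) == pytest.approx(
                np.trapezoid(tpr, fpr), abs=1e-9)

    def test_auc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 300)
        scores = np.round(rng.random(300), 2)
        assert auc_rank(y, scores) == pytest.approx(roc_auc_score(y, scores),
                                                    abs=1e-12)

    def test_tpr_at_fpr_bounds(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        m = compute_metrics(y, np.linspace(1, 0, 10))
        assert 0.0 <= m.tpr_at_fpr10 <= 1.0
        assert 0.0 <= m.tpr_at_fdr10 <= 1.0


class TestReliabilityAndStratification:
    def make_predictions(self, seed=21, n=400):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        o_d = np.clip(0.5 + (y - 0.5) * rng.random(n) * 0.9
                      + rng.normal(scale=0.15, size=n), 0, 1)
        return y, o_d

    def test_threshold_zero_keeps_confident_subset_only(self):
        y, o_d = self.make_predictions()
        curve = reliability_curve(y, o_d)
        assert curve.loc[0, "n"] == (reliability_index(o_d) > 0).sum()
        assert (curve["coverage"].diff().dropna() <= 1e-12).all()

    def test_matches_direct_refilter(self):
        y, o_d = self.make_predictions(seed=22)
        curve = reliability_curve(y, o_d)
        ri = reliability_index(o_d)
        for threshold in (2, 5, 8):
            mask = ri > threshold
            if mask.sum() == 0:
                continue
            direct = compute_metrics(y[mask], o_d[mask])
            row = curve.loc[threshold]
            assert row["q2"] == pytest.approx(direct.q2)
            assert row["mcc"] == pytest.approx(direct.mcc)

    def test_rsa_bins(self):
        y, o_d = self.make_predictions(seed=23, n=200)
        rsa = np.random.default_rng(24).uniform(0, 100, 200)
        table = stratify_by_rsa(y, o_d, rsa)
        assert (table["n_disease"] + table["n_neutral"]).sum() == 200
        assert table["rsa_lo"].tolist() == [10.0 * b for b in range(10)]

    def test_all_buried_single_bin(self):
        y = np.array([1, 0, 1, 0])
        table = stratify_by_rsa(y, np.array([0.9, 0.1, 0.8, 0.2]),
                                np.zeros(4))
        populated = (table["n_disease"] + table["n_neutral"]) > 0
        assert populated.sum() == 1 and populated.iloc[0]


class TestCrossValidationProtocol:
    def test_no_signal_features_give_chance_auc(self):
        rng = np.random.default_rng(31)
        n = 240
        records = [rec(f"P{i % 40}", "disease" if rng.random() < 0.5 else "neutral",
                       position=i // 40 + 1) for i in range(n)]
        table = FeatureTable(records, "3d",
                             rng.normal(size=(n, 20)), rng.normal(size=(n, 21)),
                             rng.normal(size=(n, 5)), rng.normal(size=(n, 4)))
        clusters = {f"P{i}": i for i in range(40)}
        result = cross_validate(table, clusters=clusters, k=20, seed=1)
        assert 0.40 <= result.metrics.auc <= 0.60

    def test_go_counts_leakage_free_per_fold(self, small_world,
                                             small_world_features):
        from sap3d.function_features import build_propagated, fit_go_counts
        w = small_world
        clusters = cluster_proteins(w.sequences)
        plan = make_folds(w.records, clusters, k=20, seed=0)
        propagated = build_propagated(w.ontology, w.annotations)
        test_idx = set(plan.folds[0].tolist())
        train_records = [r for i, r in enumerate(w.records) if i not in test_idx]
        baseline = fit_go_counts(train_records, propagated)
        flipped_world = [
            r if i not in test_idx else MutationRecord(
                r.protein_id, r.chain_id, r.position, r.wt, r.mut,
                "neutral" if r.label == "disease" else "disease")
            for i, r in enumerate(w.records)]
        train_after = [r for i, r in enumerate(flipped_world) if i not in test_idx]
        assert fit_go_counts(train_after, propagated) == baseline

    def test_holdout_by_function_split(self, small_world):
        from sap3d.function_features import build_propagated
        w = small_world
        propagated = build_propagated(w.ontology, w.annotations)
        split = holdout_by_function(w.records, w.sequences, propagated,
                                    w.ontology, w.marked_term)
        train_p = {w.records[i].protein_id for i in split.train_idx}
        test_p = {w.records[i].protein_id for i in split.test_idx}
        assert not train_p & test_p
        # the held-out subtree is gone from the scoring annotations
        for pid in test_p:
            assert w.marked_term not in split.annotations[pid]

    def test_holdout_removes_near_identical_training_protein(self):
        from sap3d.io_formats import OntologyDag
        rng = np.random.default_rng(41)
        from sap3d._residues import AA1
        base = "".join(rng.choice(list(AA1), 60))
        near = base[:57] + "AAA"  # ~95% identical
        far = "".join(rng.choice(list(AA1), 60))
        sequences = {"T": base, "NEAR": near, "FAR": far}
        dag = OntologyDag({"kin": ()}, {"kin": "molecular_function"})
        annotations = {"T": frozenset({"kin"}), "NEAR": frozenset(),
                       "FAR": frozenset()}
        records = [rec("T", "disease"), rec("NEAR", "neutral"),
                   rec("FAR", "neutral")]
        split = holdout_by_function(records, sequences, annotations, dag, "kin")
        assert {records[i].protein_id for i in split.test_idx} == {"T"}
        assert {records[i].protein_id for i in split.train_idx} == {"FAR"}

    def test_empty_test_when_no_protein_annotated(self, small_world):
        from sap3d.io_formats import OntologyDag
        dag = OntologyDag({"lonely": ()}, {"lonely": "molecular_function"})
        split = holdout_by_function(small_world.records[:10],
                                    small_world.sequences,
                                    {}, dag, "lonely")
        assert len(split.test_idx) == 0


class TestFeatureTsv:
    def test_lossless_round_trip(self, small_world, small_world_features,
                                 tmp_path):
        table = small_world_features
        rng = np.random.default_rng(51)
        go = rng.normal(size=(len(table), 2))
        path = tmp_path / "features.tsv"
        write_feature_tsv(table, path, go)
        records, X, variant = read_feature_tsv(path)
        assert variant == "3d" and X.shape == (len(table), 52)
        assert np.array_equal(X, table.matrix(go))
        assert records[0].protein_id == table.records[0].protein_id
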