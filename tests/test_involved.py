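"""Cohort splitting, the patch classifier and pseudo-label refinement."""

import numpy as np
import pytest

from rollmap.involved import (COLITIS, CONTROL, INVOLVED_LABEL,
                              UNINVOLVED_LABEL, ClusterRelabeler,
                              InvolvedPatchClassifier, cluster_and_relabel,
                              evaluate_patch_model, extract_features,
                              split_cohort, train_patch_classifier)
from rollmap.textures import render_texture_patch


def _texture_set(name, n, size=48, seed0=0):
    return np.stack([render_texture_patch(name, size, seed0 + s)
                     for s in range(n)])


class TestSplit:
    def test_ten_mice_largest_remainder(self):
        split = split_cohort([f"m{i}" for i in range(10)], seed=1)
        assert (len(split.train), len(split.validation), len(split.test)) == (7, 1, 2)

    def test_deterministic_and_disjoint(self):
        ids = [f"m{i}" for i in range(12)]
        labs = ["A"] * 6 + ["B"] * 6
        a = split_cohort(ids, labs, seed=5)
        b = split_cohort(ids, labs, seed=5)
        assert a == b
        all_ids = list(a.train) + list(a.validation) + list(a.test)
        assert sorted(all_ids) == sorted(ids)

    def test_stratification_across_labels(self):
        ids = [f"m{i}" for i in range(20)]
        labs = ["A"] * 10 + ["B"] * 10
        s = split_cohort(ids, labs, seed=2)
        train_labs = [labs[ids.index(m)] for m in s.train]
        assert set(train_labs) == {"A", "B"}

    def test_too_few_mice_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(["a", "b"], seed=0)


class TestClassifier:
    def test_separable_textures_reach_f1_095(self):
        """200 patches of two planted textures -> held-out F1 >= 0.95."""
        X = np.concatenate([_texture_set("Crypts", 100),
                            _texture_set("Inflammatory", 100, seed0=500)])
        y = np.array([UNINVOLVED_LABEL] * 100 + [INVOLVED_LABEL] * 100)
        rng = np.random.default_rng(0)
        idx = rng.permutation(200)
        tr, te = idx[:150], idx[150:]
        model = train_patch_classifier(
            X[tr], y[tr], {"epochs": 15, "feature_width": 64}, seed=0,
            val_patches=X[tr[:30]], val_labels=y[tr[:30]])
        res = evaluate_patch_model(model, X[te], y[te])
        assert res["overall_f1"] >= 0.95

    def test_zero_epochs_still_normalized(self):
        X = np.concatenate([_texture_set("Crypts", 10),
                            _texture_set("Rosettes", 10, seed0=99)])
        y = np.array([UNINVOLVED_LABEL] * 10 + [INVOLVED_LABEL] * 10)
        model = InvolvedPatchClassifier(epochs=0, feature_width=32).fit(X, y)
        proba = model.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_single_class_rejected(self):
        X = _texture_set("Crypts", 12)
        with pytest.raises(ValueError):
            InvolvedPatchClassifier().fit(X, np.array(["A"] * 12))

    def test_training_determinism(self):
        X = np.concatenate([_texture_set("Crypts", 20),
                            _texture_set("Inflammatory", 20, seed0=77)])
        y = np.array(["U"] * 20 + ["I"] * 20)
        cfg = {"epochs": 5, "feature_width": 32}
        a = train_patch_classifier(X, y, cfg, seed=4)
        b = train_patch_classifier(X, y, cfg, seed=4)
        assert np.allclose(a.predict_proba(X), b.predict_proba(X))


@pytest.fixture(scope="module")
def feature_model():
    X = np.concatenate([_texture_set("Crypts", 15),
                        _texture_set("Inflammatory", 15, seed0=300)])
    y = np.array(["U"] * 15 + ["I"] * 15)
    return train_patch_classifier(X, y, {"epochs": 8, "feature_width": 64},
                                  seed=1)


class TestFeatures:

    def test_shape_and_duplicate_consistency(self, feature_model):
        X = _texture_set("Crypts", 3)
        X = np.concatenate([X, X[:1]])
        F = extract_features(feature_model, X)
        assert F.shape == (4, 64)
        assert np.array_equal(F[0], F[3])

    def test_distinct_textures_have_distinct_features(self, feature_model):
        X = np.stack([render_texture_patch("Crypts", 48, 1),
                      render_texture_patch("Inflammatory", 48, 1)])
        F = extract_features(feature_model, X)
        assert np.linalg.norm(F[0] - F[1]) > 0


class TestRelabeling:
    def _toy(self, ctrl_high_frac=0.0):
        """Two 1-D blobs at 0 and 10; controls sit at 0 except an optional
        share at 10."""
        rng = np.random.default_rng(0)
        feats, mice, status = [], [], []
        for m in ("c1", "c2"):
            for i in range(20):
                at_high = i < ctrl_high_frac * 20
                feats.append([10.0 + rng.normal(0, .1) if at_high
                              else rng.normal(0, .1)])
                mice.append(m)
                status.append(CONTROL)
        for m in ("d1", "d2"):
            for i in range(20):
                feats.append([rng.normal(0, .1) if i < 10
                              else 10.0 + rng.normal(0, .1)])
                mice.append(m)
                status.append(COLITIS)
        return np.asarray(feats), mice, status

    def test_colitis_only_cluster_is_involved(self):
        feats, mice, status = self._toy(ctrl_high_frac=0.0)
        rel = cluster_and_relabel(feats, mice, status, k=2, seed=0)
        high = rel.kmeans_.predict([[10.0]])[0]
        assert rel.cluster_labels_[high] == INVOLVED_LABEL
        assert rel.cluster_labels_[1 - high] == UNINVOLVED_LABEL

    def test_cluster_common_in_controls_is_uninvolved(self):
        feats, mice, status = self._toy(ctrl_high_frac=0.4)
        rel = cluster_and_relabel(feats, mice, status, k=2, seed=0)
        high = rel.kmeans_.predict([[10.0]])[0]
        assert rel.cluster_labels_[high] == UNINVOLVED_LABEL

    def test_control_patches_never_involved(self):
        feats, mice, status = self._toy()
        rel = cluster_and_relabel(feats, mice, status, k=2, seed=0)
        refined = np.asarray(rel.refined_labels_)
        ctrl = np.asarray(status) == CONTROL
        assert np.all(refined[ctrl] == UNINVOLVED_LABEL)

    def test_rule_invariant_to_patch_order(self):
        feats, mice, status = self._toy()
        rel1 = cluster_and_relabel(feats, mice, status, k=2, seed=0)
        perm = np.random.default_rng(1).permutation(len(feats))
        rel2 = cluster_and_relabel(feats[perm], [mice[i] for i in perm],
                                   [status[i] for i in perm], k=2, seed=0)
        assert np.array_equal(np.asarray(rel1.refined_labels_)[perm],
                              rel2.refined_labels_)

    def test_manual_override(self):
        feats, mice, status = self._toy()
        rel = ClusterRelabeler(k=2, random_state=0,
                               overrides={0: INVOLVED_LABEL,
                                          1: INVOLVED_LABEL}
                               ).fit(feats, mice, status)
        assert set(rel.cluster_labels_.values()) == {INVOLVED_LABEL}

    def test_rejects_k_larger_than_data(self):
        feats, mice, status = self._toy()
        with pytest.raises(ValueError):
            cluster_and_relabel(feats[:3], mice[:3], [COLITIS, CONTROL, COLITIS],
                                k=5, seed=0)

    def test_requires_both_statuses(self):
        feats, mice, status = self._toy()
        with pytest.raises(ValueError):
            cluster_and_relabel(feats, mice, [COLITIS] * len(mice), k=2, seed=0)


class TestEvaluation:
    class _Stub:
        def __init__(self, constant, classes):
            self.constant = constant
            self.classes_ = np.asarray(classes)

        def predict(self, X):
            return np.array([self.constant] * len(X))

    def test_perfect_predictions(self):
        truth = np.array(["A"] * 5 + ["B"] * 5)

        class Perfect:
            classes_ = np.array(["A", "B"])

            def predict(self, X):
                return truth

        res = evaluate_patch_model(Perfect(), np.zeros((10, 1)), truth)
        assert res["overall_f1"] == 1.0
        assert res["confusion"][0, 1] == 0 and res["confusion"][1, 0] == 0

    def test_constant_predictor_closed_form(self):
        """All-'A' on balanced 2-class truth: F1_A = 2/3, F1_B = 0, so the
        support-weighted overall F1 is 1/3."""
        truth = np.array(["A"] * 10 + ["B"] * 10)
        res = evaluate_patch_model(self._Stub("A", ["A", "B"]),
                                   np.zeros((20, 1)), truth)
        assert res["overall_f1"] == pytest.approx(1 / 3)

    def test_empty_and_unknown_rejected(self):
        stub = self._Stub("A", ["A", "B"])
        with pytest.raises(ValueError):
            evaluate_patch_model(stub, np.zeros((0, 1)), np.array([]))
        with pytest.raises(ValueError):
            evaluate_patch_model(stub, np.zeros((2, 1)), np.array(["A", "C"]))


class TestTwoPhase:
    def test_refined_labels_match_truth(self, two_phase_runs):
        """>= 90% of training patches receive refined labels matching truth
        involvement."""
        assert two_phase_runs[1]["relabel_accuracy"] >= 0.9

    def test_no_control_patch_refined_involved(self, two_phase_runs):
        rel = two_phase_runs[1]["relabeler"]
        refined = np.asarray(rel.refined_labels_)
        ctrl = np.asarray(rel.status_) == CONTROL
        assert ctrl.any()
        assert np.all(refined[ctrl] == UNINVOLVED_LABEL)
        assert set(rel.enrichment_["label"]) == {INVOLVED_LABEL, UNINVOLVED_LABEL}
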