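"""Variance-targeted PCA, k-means class discovery and proportion features."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from rollmap.discovery import (PatchKMeans, VarianceTargetPCA,
                               class_proportions, fit_kmeans, fit_pca,
                               representatives)
from rollmap.patching import PatchRef
from rollmap.textures import INVOLVED_CLASSES


class TestPCA:
    def test_exact_3d_subspace_needs_3_components(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(3, 512))
        coeffs = rng.normal(size=(60, 3))  # comparable variance per direction
        X = 10.0 + coeffs @ basis
        assert fit_pca(X, 0.95).n_components_ == 3

    def test_target_one_on_full_rank_data(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 10))
        assert fit_pca(X, 1.0).n_components_ == 10  # min(n-1, width)
        X = rng.normal(size=(5, 10))
        assert fit_pca(X, 1.0).n_components_ == 4

    def test_component_count_matches_eigenvalue_scan_oracle(self):
        """Independent oracle: brute-force cumulative-eigenvalue scan of the
        sample covariance gives the same minimal component count."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(1000, 10)) * np.linspace(3.0, 0.5, 10)
        pca = fit_pca(X, 0.95)
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        cum = np.cumsum(eig) / eig.sum()
        oracle_n = int(np.argmax(cum >= 0.95)) + 1
        assert pca.n_components_ == oracle_n

    def test_sign_convention_and_orthonormality(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 8))
        pca = fit_pca(X, 0.95)
        C = pca.components_
        assert np.allclose(C @ C.T, np.eye(len(C)), atol=1e-9)
        peaks = C[np.arange(len(C)), np.abs(C).argmax(axis=1)]
        assert np.all(peaks > 0)

    def test_reconstruction_error_equals_residual_variance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 12)) * np.linspace(4.0, 0.2, 12)
        pca = fit_pca(X, 0.9)
        Xc = X - pca.mean_
        recon = pca.transform(X) @ pca.components_
        err = np.sum((Xc - recon) ** 2)
        total = np.sum(Xc ** 2)
        captured = pca.explained_variance_ratio_.sum()
        assert err == pytest.approx((1 - captured) * total, rel=1e-6)

    def test_invalid_target_rejected(self):
        X = np.zeros((5, 3))
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                fit_pca(X, bad)


class TestKMeans:
    def test_k1_centroid_is_sample_mean(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(40, 6))
        model = fit_kmeans(Z, k=1, seed=0)
        assert np.allclose(model.cluster_centers_[0], Z.mean(axis=0))

    def test_separated_blobs_recovered(self):
        """4 Gaussian blobs (sigma 0.1, centres >= 10 apart) -> ARI >= 0.99."""
        rng = np.random.default_rng(6)
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
        truth = np.repeat(np.arange(4), 50)
        Z = centers[truth] + rng.normal(0, 0.1, size=(200, 2))
        model = fit_kmeans(Z, k=4, seed=0)
        assert adjusted_rand_score(truth, model.predict(Z)) >= 0.99

    def test_duplicated_dataset_same_centroids(self):
        rng = np.random.default_rng(7)
        centers = np.array([[0.0, 0.0], [8.0, 8.0]])
        Z = centers[np.repeat([0, 1], 30)] + rng.normal(0, 0.05, (60, 2))
        a = fit_kmeans(Z, k=2, seed=1)
        b = fit_kmeans(np.concatenate([Z, Z]), k=2, seed=1)
        order_a = np.argsort(a.cluster_centers_[:, 0])
        order_b = np.argsort(b.cluster_centers_[:, 0])
        assert np.allclose(a.cluster_centers_[order_a],
                           b.cluster_centers_[order_b], atol=1e-7)

    def test_k_exceeding_points_rejected(self):
        with pytest.raises(ValueError):
            fit_kmeans(np.zeros((3, 2)), k=5, seed=0)


class TestRepresentatives:
    def _model_1d(self):
        Z = np.array([[0.0], [1.0], [10.0]])
        model = fit_kmeans(Z, k=2, seed=0,
                           class_names=("near", "far"))
        return model, Z

    def test_hand_computed_toy(self):
        model, Z = self._model_1d()
        refs = [PatchRef("m", i, 0, 16) for i in range(3)]
        reps = representatives(model, Z, refs, n=2)
        lo = "near" if model.predict([[0.0]])[0] == model.names_.index("near") else "far"
        # the 10.0 point is alone in its cluster
        far_name = model.names_[model.predict([[10.0]])[0]]
        assert [r.x for r in reps[far_name]] == [2]
        near_name = model.names_[model.predict([[0.0]])[0]]
        # both near points at distance 0.5 from centroid 0.5 -> manifest order
        assert [r.x for r in reps[near_name]] == [0, 1]

    def test_coincident_point_ranks_first(self):
        rng = np.random.default_rng(8)
        Z = rng.normal(size=(30, 3))
        model = fit_kmeans(Z, k=3, seed=0)
        Z2 = np.concatenate([Z, model.cluster_centers_[:1]])
        refs = [PatchRef("m", i, 0, 16) for i in range(len(Z2))]
        reps = representatives(model, Z2, refs, n=5)
        name0 = model.names_[0]
        assert reps[name0][0].x == len(Z2) - 1

    def test_n_exceeding_membership_returns_whole_class(self):
        model, Z = self._model_1d()
        refs = [PatchRef("m", i, 0, 16) for i in range(3)]
        reps = representatives(model, Z, refs, n=50)
        assert sum(len(v) for v in reps.values()) == 3

    def test_empty_class_warns(self):
        model, Z = self._model_1d()
        refs = [PatchRef("m", i, 0, 16) for i in range(2)]
        with pytest.warns(UserWarning):
            representatives(model, Z[:2], refs, n=2)


class TestProportions:
    def test_all_uninvolved(self):
        calls = pd.DataFrame({"mouse_id": ["a"] * 5, "call": ["Uninvolved"] * 5})
        props = class_proportions(calls, ("c1", "c2", "c3", "c4"))
        assert props.loc["a"].tolist() == [1.0, 0, 0, 0, 0]

    def test_50_25_25_split(self):
        calls = pd.DataFrame({
            "mouse_id": ["a"] * 8,
            "call": ["Uninvolved"] * 4 + ["c1"] * 2 + ["c2"] * 2,
        })
        props = class_proportions(calls, ("c1", "c2"))
        assert props.loc["a"].tolist() == [0.5, 0.25, 0.25]

    def test_rows_sum_to_one_and_order_invariant(self, phenotype_run):
        props = phenotype_run["proportions"]
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-9)
        assert (props.to_numpy() >= 0).all()

    def test_zero_patch_mouse_rejected(self):
        calls = pd.DataFrame({"mouse_id": ["a"], "call": ["Uninvolved"]})
        with pytest.raises(ValueError, match="b"):
            class_proportions(calls, ("c1",), mice=["a", "b"])

    def test_unknown_call_rejected(self):
        calls = pd.DataFrame({"mouse_id": ["a"], "call": ["weird"]})
        with pytest.raises(ValueError):
            class_proportions(calls, ("c1",))

    def test_control_mice_are_nearly_all_uninvolved(self, phenotype_run):
        props = phenotype_run["proportions"]
        meta = phenotype_run["metadata"]
        ctrl = props.loc[meta.index[meta["model"] == "Control"]]
        assert (ctrl["Uninvolved"] >= 0.95).all()

    def test_per_model_mix_recovery(self, phenotype_run):
        """Mean involved-class composition per colitis model matches the
        planted mix within +-0.1 per entry."""
        from rollmap.synthetic import DEFAULT_PROFILES
        props = phenotype_run["proportions"]
        meta = phenotype_run["metadata"]
        for model in ("KLF5", "DSS", "Combined"):
            rows = props.loc[meta.index[meta["model"] == model]]
            inv = rows[list(INVOLVED_CLASSES)].mean(axis=0)
            mix = inv / inv.sum()
            planted = np.asarray(DEFAULT_PROFILES[model].involved_class_mix)
            assert np.all(np.abs(mix.to_numpy() - planted) <= 0.1), model
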