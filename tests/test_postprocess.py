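import numpy as np
import pytest

from hive.postprocess import (FeatureNormalizer, PCAReducer, merge, normalize,
                              pca_reduce)
from hive.records import FeatureMatrix, FeatureVector


def make_vectors():
    rng = np.random.default_rng(3)
    vectors = []
    for iid in ("img_a", "img_b", "img_c"):
        vectors.append(FeatureVector(iid, "HOG", rng.random(81)))
        vectors.append(FeatureVector(iid, "LBP", rng.random(16)))
    return vectors


class TestMerge:
    def test_concatenation_shape_and_order(self):
        matrix = merge(make_vectors())
        assert matrix.shape == (3, 97)
        assert matrix.image_ids == ["img_a", "img_b", "img_c"]
        assert matrix.labels[0] == "HOG_0"
        assert matrix.labels[81] == "LBP_0"

    def test_single_vector_identity(self):
        vec = FeatureVector("only", "GLCM", [1.0, 2.0, 3.0],
                            ["GLCM_a", "GLCM_b", "GLCM_c"])
        matrix = merge([vec])
        assert matrix.shape == (1, 3)
        assert np.array_equal(matrix.values[0], vec.values)

    def test_missing_pair_names_the_gap(self):
        vectors = make_vectors()[:-1]  # drop img_c's LBP vector
        with pytest.raises(ValueError, match="img_c.*LBP"):
            merge(vectors)

    def test_length_mismatch_names_image(self):
        vectors = make_vectors()
        vectors[1] = FeatureVector("img_a", "LBP", np.zeros(9))
        with pytest.raises(ValueError, match="img_a"):
            merge(vectors)

    def test_class_labels_follow_sorted_ids(self):
        labels = {"img_b": 1, "img_a": 0, "img_c": 1}
        matrix = merge(make_vectors(), class_labels=labels)
        assert list(matrix.class_labels) == [0, 1, 1]


class TestNormalize:
    def test_zero_mean_unit_population_sd(self, rng):
        matrix = FeatureMatrix(["a", "b", "c", "d"], [f"f{i}" for i in range(5)],
                               rng.random((4, 5)))
        out = normalize(matrix)
        assert np.allclose(out.values.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(out.values.std(axis=0), 1, atol=1e-12)

    def test_constant_column_becomes_zero(self):
        values = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        out = normalize(FeatureMatrix(["a", "b", "c"], ["x", "y"], values))
        assert np.all(out.values[:, 1] == 0)

    def test_known_column_arithmetic(self):
        values = np.array([[1.0], [2.0], [3.0]])
        out = normalize(FeatureMatrix(["a", "b", "c"], ["x"], values))
        assert np.allclose(out.values[:, 0], [-1.224745, 0.0, 1.224745],
                           atol=1e-6)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            normalize(FeatureMatrix(["a"], ["x"], [[1.0]]))


class TestPCA:
    def test_default_components_min_rows_cols(self, rng):
        matrix = FeatureMatrix([f"i{i}" for i in range(20)],
                               [f"f{i}" for i in range(50)],
                               rng.random((20, 50)))
        out = pca_reduce(matrix)
        assert out.shape == (20, 20)
        assert out.labels[0] == "PC1" and out.labels[-1] == "PC20"

    def test_variance_conserved_at_full_rank(self, rng):
        X = rng.random((12, 12))
        matrix = FeatureMatrix([f"i{i}" for i in range(12)],
                               [f"f{i}" for i in range(12)], X)
        out = pca_reduce(matrix)
        centered = X - X.mean(axis=0)
        assert out.values.var(axis=0).sum() == pytest.approx(
            centered.var(axis=0).sum(), rel=1e-8)

    def test_scores_orthogonal(self, rng):
        X = rng.random((15, 30))
        out = pca_reduce(FeatureMatrix([f"i{i}" for i in range(15)],
                                       [f"f{i}" for i in range(30)], X))
        gram = out.values.T @ out.values
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * max(1.0, np.max(np.abs(gram)))

    def test_explained_variance_nonincreasing(self, rng):
        reducer = PCAReducer().fit(rng.random((10, 6)))
        ev = reducer.explained_variance_
        assert np.all(ev >= -1e-12)
        assert np.all(np.diff(ev) <= 1e-12)

    def test_anisotropic_cloud_pc1_explains_99pct(self, rng):
        t = rng.standard_normal(200)
        noise = 0.01 * rng.standard_normal(200)
        X = np.stack([t + noise, t - noise], axis=1) / np.sqrt(2)
        reducer = PCAReducer().fit(X)
        ratio = reducer.explained_variance_ratio_
        assert ratio[0] >= 0.99
        # oracle: eigen-decomposition of the 2x2 covariance
        eig = np.linalg.eigvalsh(np.cov(X.T))
        assert ratio[0] == pytest.approx(eig[-1] / eig.sum(), rel=1e-10)

    def test_sign_convention_deterministic(self, rng):
        X = rng.random((9, 5))
        r1 = PCAReducer().fit(X)
        r2 = PCAReducer().fit(X.copy())
        assert np.array_equal(r1.components_, r2.components_)
        for row in r1.components_:
            assert row[np.argmax(np.abs(row))] > 0

    def test_row_permutation_permutes_scores(self, rng):
        X = rng.random((10, 7))
        perm = rng.permutation(10)
        ids = [f"i{i}" for i in range(10)]
        out = pca_reduce(FeatureMatrix(ids, [f"f{i}" for i in range(7)], X))
        out_p = pca_reduce(FeatureMatrix([ids[i] for i in perm],
                                         [f"f{i}" for i in range(7)], X[perm]))
        order = {iid: k for k, iid in enumerate(out_p.image_ids)}
        reordered = out_p.values[[order[iid] for iid in out.image_ids]]
        assert np.allclose(reordered, out.values, atol=1e-10)

    def test_excessive_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_reduce(FeatureMatrix(["a", "b"], ["x", "y", "z"],
                                     rng.random((2, 3))), n_components=3)
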