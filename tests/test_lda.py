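"""Unit and property tests for the canonical LDA core."""

import numpy as np
import pytest
from scipy.stats import chi2, norm

import gaitlda.lda as L
from gaitlda.lda import LabeledMatrix

from conftest import fisher_direction


def random_two_group(rng, n_max=30, p_max=5):
    p = int(rng.integers(2, p_max + 1))
    g = 2
    n = int(rng.integers(p + g + 2, n_max + 1))
    n1 = int(rng.integers(3, n - 3))
    X = rng.normal(size=(n, p)) @ rng.normal(size=(p, p)) * 0.7
    y = np.array(["g1"] * n1 + ["g2"] * (n - n1))
    X[y == "g2"] += rng.normal(scale=2.0, size=p)
    return LabeledMatrix(X, y, [f"v{j}" for j in range(p)])


class TestFit:
    @pytest.mark.parametrize("seed", range(10))
    def test_two_group_axis_equals_fisher_direction(self, seed):
        rng = np.random.default_rng(seed)
        data = random_two_group(rng)
        model = L.fit_lda(data)
        w = fisher_direction(data.X, data.y)
        v = model.coeffs[:, 0]
        cos = abs(v @ w) / (np.linalg.norm(v) * np.linalg.norm(w))
        assert cos >= 1 - 1e-8

    def test_identical_means_give_zero_eigenvalues(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = np.array(["a", "b"] * 20)
        for lab in ("a", "b"):
            X[y == lab] -= X[y == lab].mean(axis=0)  # equal (zero) means
        model = L.fit_lda(LabeledMatrix(X, y, list("xyz")))
        assert np.allclose(model.eigenvalues, 0, atol=1e-10)
        assert np.allclose(model.canonical_correlations, 0, atol=1e-5)

    def test_two_groups_yield_single_axis_in_seven_variables(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 7))
        y = np.repeat(["h", "g"], 20)
        X[y == "g"] += 1.0
        model = L.fit_lda(LabeledMatrix(X, y, [f"v{j}" for j in range(7)]))
        assert model.n_axes == 1

    def test_toy_axis_parallel_to_closed_form(self, toy_two_group):
        model = L.fit_lda(toy_two_group)
        w = fisher_direction(toy_two_group.X, toy_two_group.y)
        v = model.coeffs[:, 0]
        cos = abs(v @ w) / (np.linalg.norm(v) * np.linalg.norm(w))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_unit_pooled_variance_scaling_and_sign_convention(self, toy_two_group):
        model = L.fit_lda(toy_two_group)
        v = model.coeffs[:, 0]
        assert v @ model.pooled_cov @ v == pytest.approx(1.0, rel=1e-10)
        assert v[np.argmax(np.abs(v))] > 0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        data = random_two_group(rng)
        model = L.fit_lda(data)
        perm = rng.permutation(len(data.y))
        shuffled = LabeledMatrix(data.X[perm], data.y[perm], data.variable_names)
        model_p = L.fit_lda(shuffled)
        assert model.groups == model_p.groups
        np.testing.assert_allclose(model_p.coeffs, model.coeffs, atol=1e-9)
        np.testing.assert_allclose(model_p.means, model.means, atol=1e-12)

    def test_singular_covariance_raises_naming_collinearity(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        X[:, 2] = X[:, 0] + X[:, 1]  # exact collinearity
        y = np.repeat(["a", "b"], 15)
        data = LabeledMatrix(X, y, ["u", "v", "w"])
        with pytest.raises(L.FitError, match="singular"):
            L.fit_lda(data)
        # ridge rescues the fit
        model = L.fit_lda(data, ridge=1e-8)
        assert model.n_axes == 1

    def test_tiny_group_raises(self):
        X = np.arange(12.0).reshape(6, 2)
        y = np.array(["a"] * 5 + ["b"])
        with pytest.raises(L.FitError, match="fewer than 2"):
            L.fit_lda(LabeledMatrix(X, y, ["u", "v"]))

    def test_priors_conventions(self):
        rng = np.random.default_rng(5)
        data = random_two_group(rng)
        prop = L.fit_lda(data, priors="proportional")
        counts = np.array([np.sum(data.y == lab) for lab in prop.groups])
        np.testing.assert_allclose(prop.priors, counts / counts.sum())
        eq = L.fit_lda(data, priors="equal")
        np.testing.assert_allclose(eq.priors, [0.5, 0.5])


class TestTransform:
    def test_group_means_of_scores_are_centroid_scores(self, toy_two_group):
        model = L.fit_lda(toy_two_group)
        scores = L.transform(model, toy_two_group.X)
        for i, lab in enumerate(model.groups):
            np.testing.assert_allclose(
                scores[toy_two_group.y == lab].mean(axis=0),
                model.centroid_scores[i], atol=1e-12)

    def test_grand_mean_maps_to_origin(self, toy_two_group):
        model = L.fit_lda(toy_two_group)
        score = L.transform(model, toy_two_group.X.mean(axis=0))
        np.testing.assert_allclose(score, 0, atol=1e-12)

    def test_scores_match_fisher_projection_up_to_scale(self, toy_two_group):
        model = L.fit_lda(toy_two_group)
        scores = L.transform(model, toy_two_group.X)[:, 0]
        w = fisher_direction(toy_two_group.X, toy_two_group.y)
        proj = (toy_two_group.X - toy_two_group.X.mean(axis=0)) @ w
        ratio = scores / proj
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_variable_mismatch_raises(self, toy_two_group):
        model = L.fit_lda(toy_two_group)
        with pytest.raises(ValueError, match="variables"):
            L.transform(model, np.zeros((2, 5)))


class TestLoadings:
    def test_variable_identical_to_score_loads_one(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 2))
        y = np.repeat(["a", "b"], 15)
        X[y == "b", 0] += 3
        data = LabeledMatrix(X, y, ["u", "v"])
        model = L.fit_lda(data)
        scores = L.transform(model, X)[:, 0]
        aug = LabeledMatrix(np.column_stack([X, scores]), y, ["u", "v", "f"])
        model_aug = L.fit_lda(aug, ridge=1e-10)
        loads = L.factor_loadings(model_aug, aug)
        assert abs(loads[2, 0]) == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_correlations(self, toy_two_group):
        model = L.fit_lda(toy_two_group)
        loads = L.factor_loadings(model, toy_two_group)
        scores = L.transform(model, toy_two_group.X)
        for j in range(2):
            for i in range(model.n_axes):
                expected = np.corrcoef(toy_two_group.X[:, j], scores[:, i])[0, 1]
                assert loads[j, i] == pytest.approx(expected, abs=1e-12)
        assert np.all(np.abs(loads) <= 1 + 1e-12)

    def test_zero_variance_variable_raises(self):
        rng = np.random.default_rng(19)
        X = np.column_stack([rng.normal(size=12), np.ones(12)])
        X[6:, 0] += 3
        y = np.repeat(["a", "b"], 6)
        data = LabeledMatrix(X, y, ["u", "const"])
        model = L.fit_lda(data, ridge=1e-8)  # constant column is singular
        with pytest.raises(ValueError, match="zero-variance"):
            L.factor_loadings(model, data)


class TestPosteriors:
    def _model_1d(self):
        """2-group 1-D model, means 0 and 2, pooled variance 1."""
        rng = np.random.default_rng(7)
        X = np.concatenate([rng.normal(size=50), rng.normal(size=50)])
        X = np.concatenate([X[:50] - X[:50].mean(), X[50:] - X[50:].mean() + 2.0])
        # rescale each group to make the pooled variance exactly 1
        s = np.sqrt((np.sum(X[:50] ** 2) + np.sum((X[50:] - 2) ** 2)) / 98)
        X = np.concatenate([X[:50] / s, (X[50:] - 2) / s + 2.0])
        y = np.repeat(["a", "b"], 50)
        return L.fit_lda(LabeledMatrix(X[:, None], y, ["x"]), priors="equal")

    def test_matches_hand_computed_density_ratio(self):
        model = self._model_1d()
        np.testing.assert_allclose(model.means.ravel(), [0, 2], atol=1e-12)
        assert model.pooled_cov[0, 0] == pytest.approx(1.0, rel=1e-10)
        post = L.posterior_probabilities(model, np.array([0.5]))
        da, db = norm.pdf(0.5, 0, 1), norm.pdf(0.5, 2, 1)
        np.testing.assert_allclose(post, [da / (da + db), db / (da + db)],
                                   rtol=1e-10)

    def test_sum_to_one_on_random_queries(self, toy_two_group):
        model = L.fit_lda(toy_two_group)
        rng = np.random.default_rng(8)
        X = rng.normal(scale=50, size=(1000, 2))  # far tails included
        post = L.posterior_probabilities(model, X)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(post >= 0)

    def test_equidistant_equal_priors_is_uniform(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(20, 2))
        base -= base.mean(axis=0)
        X = np.vstack([base + [3, 0], -(base + [3, 0])])  # mirror symmetry
        y = np.repeat(["a", "b"], 20)
        model = L.fit_lda(LabeledMatrix(X, y, ["u", "v"]), priors="equal")
        post = L.posterior_probabilities(model, np.zeros(2))
        np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-12)

    def test_at_far_isolated_centroid_probability_tends_to_one(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 2))
        y = np.repeat(["a", "b", "c"], 20)
        X[y == "b"] += [50, 0]
        X[y == "c"] += [0, 50]
        model = L.fit_lda(LabeledMatrix(X, y, ["u", "v"]))
        k = model.groups.index("b")
        post = L.posterior_probabilities(model, model.means[k])
        assert post[k] > 1 - 1e-12


class TestClassify:
    def test_centroid_classified_to_own_group(self, toy_two_group):
        model = L.fit_lda(toy_two_group, priors="equal")
        for i, lab in enumerate(model.groups):
            assert L.classify(model, model.means[i]) == lab

    def test_exact_tie_breaks_to_first_group(self):
        X = np.array([[0.0], [1.0], [-1.0], [4.0], [5.0], [3.0]])
        y = np.repeat(["a", "b"], 3)
        model = L.fit_lda(LabeledMatrix(X, y, ["x"]), priors="equal")
        midpoint = model.means.mean(axis=0)
        assert L.classify(model, midpoint) == model.groups[0]

    def test_batch_matches_posterior_argmax(self, toy_two_group):
        model = L.fit_lda(toy_two_group)
        preds = L.classify(model, toy_two_group.X)
        post = L.posterior_probabilities(model, toy_two_group.X)
        expected = [model.groups[i] for i in np.argmax(post, axis=1)]
        assert preds == expected


class TestEllipse:
    def test_standard_normal_axes_match_chi2_quantile(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=(20000, 2))
        ell = L.confidence_ellipse(scores, level=0.95)
        expected = np.sqrt(chi2.ppf(0.95, 2))  # ~2.448
        np.testing.assert_allclose(ell.axes, expected, rtol=0.05)
        np.testing.assert_allclose(ell.center, 0, atol=0.05)

    def test_empirical_coverage_matches_level(self):
        rng = np.random.default_rng(12)
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        scores = rng.multivariate_normal([1, -1], cov, size=20000)
        ell = L.confidence_ellipse(scores, level=0.90)
        # Mahalanobis test of membership using the sample covariance
        d = scores - scores.mean(axis=0)
        S = np.cov(scores, rowvar=False)
        m2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(S), d)
        coverage = np.mean(m2 <= chi2.ppf(0.90, 2))
        se = np.sqrt(0.9 * 0.1 / len(scores))
        assert abs(coverage - 0.90) < 3 * se

    def test_of_mean_shrinks_by_sqrt_n(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=(400, 2))
        cover = L.confidence_ellipse(scores)
        mean = L.confidence_ellipse(scores, of_mean=True)
        np.testing.assert_allclose(mean.axes, cover.axes / 20, rtol=1e-9)

    def test_degenerate_and_tiny_inputs_raise(self):
        line = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError, match="degenerate"):
            L.confidence_ellipse(line)
        with pytest.raises(ValueError, match="at least 3"):
            L.confidence_ellipse(np.zeros((2, 2)))


class TestLeaveOneOut:
    def test_separated_clusters_are_never_misclassified(self):
        rng = np.random.default_rng(14)
        X = rng.normal(scale=0.1, size=(20, 2))
        y = np.repeat(["a", "b"], 10)
        X[y == "b"] += 10
        cm = L.loo_misclassification(LabeledMatrix(X, y, ["u", "v"]))
        assert cm.misclassification_rate == 0.0
        assert cm.counts.sum() == 20
        np.testing.assert_array_equal(cm.counts.sum(axis=1), [10, 10])

    def test_identical_groups_misclassify_at_chance(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(200, 3))
        y = np.tile(["a", "b"], 100)
        cm = L.loo_misclassification(LabeledMatrix(X, y, ["u", "v", "w"]))
        # chance is ~0.5 (slightly above for LOO on null data); binomial 3-SE
        assert abs(cm.misclassification_rate - 0.5) < 3 * np.sqrt(0.25 / 200) + 0.05

    def test_matches_explicit_refit_per_fold(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(12, 2))
        y = np.repeat(["a", "b", "c"], 4)
        X += np.repeat([[0, 0], [1.5, 0], [0, 1.5]], 4, axis=0)
        data = LabeledMatrix(X, y, ["u", "v"])
        cm = L.loo_misclassification(data)
        labels = list(cm.labels)
        naive = np.zeros((3, 3), dtype=int)
        for i in range(12):
            keep = np.arange(12) != i
            fold = L.fit_lda(LabeledMatrix(X[keep], y[keep], ["u", "v"]))
            pred = L.classify(fold, X[i])
            naive[labels.index(y[i]), labels.index(pred)] += 1
        np.testing.assert_array_equal(cm.counts, naive)

    def test_group_below_three_raises(self):
        X = np.arange(14.0).reshape(7, 2)
        y = np.array(["a"] * 5 + ["b"] * 2)
        with pytest.raises(L.FitError, match="b"):
            L.loo_misclassification(LabeledMatrix(X, y, ["u", "v"]))


class TestCollapse:
    def test_identity_mapping_is_noop(self):
        cm = L.ConfusionMatrix(["a", "b"], np.array([[5, 1], [2, 6]]))
        out = L.collapse_confusion_to_phenotype(cm, {"a": "a", "b": "b"})
        np.testing.assert_array_equal(out.counts, cm.counts)

    def test_errors_wrong_in_age_only_collapse_to_zero(self):
        # every misclassification stays within phenotype
        cm = L.ConfusionMatrix(
            ["G_2", "G_3", "H_2", "H_3"],
            np.array([[0, 5, 0, 0], [5, 0, 0, 0],
                      [0, 0, 0, 4], [0, 0, 4, 0]]))
        out = L.collapse_confusion_to_phenotype(
            cm, {"G_2": "G", "G_3": "G", "H_2": "H", "H_3": "H"})
        assert out.misclassification_rate == 0.0

    def test_random_matrix_matches_brute_force_recount(self):
        rng = np.random.default_rng(17)
        counts = rng.integers(0, 20, size=(5, 5))
        labels = ["G_2", "G_3", "G_4", "H_2", "H_3"]
        label_map = {lab: lab[0] for lab in labels}
        cm = L.ConfusionMatrix(labels, counts)
        out = L.collapse_confusion_to_phenotype(cm, label_map)
        wrong = sum(counts[i, j] for i in range(5) for j in range(5)
                    if label_map[labels[i]] != label_map[labels[j]])
        assert out.misclassification_rate == pytest.approx(wrong / counts.sum())
        # theorem: collapsing can only reduce the misclassification rate
        assert out.misclassification_rate <= cm.misclassification_rate

    def test_unmapped_label_raises(self):
        cm = L.ConfusionMatrix(["a", "b"], np.eye(2, dtype=int))
        with pytest.raises(KeyError, match="b"):
            L.collapse_confusion_to_phenotype(cm, {"a": "x"})


class TestSerialization:
    def test_round_trip_preserves_model_behavior(self, toy_two_group, tmp_path):
        model = L.fit_lda(toy_two_group)
        path = tmp_path / "model.json"
        L.save_model(model, path)
        loaded, doc = L.load_model(path)
        assert doc["format_version"] == L.MODEL_FORMAT_VERSION
        np.testing.assert_allclose(
            L.transform(loaded, toy_two_group.X),
            L.transform(model, toy_two_group.X), atol=1e-12)
        np.testing.assert_allclose(
            L.posterior_probabilities(loaded, toy_two_group.X),
            L.posterior_probabilities(model, toy_two_group.X), atol=1e-12)

    def test_version_field_is_mandatory(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{}")
        with pytest.raises(ValueError, match="format_version"):
            L.load_model(path)


class TestSklearnCrossCheck:
    """scikit-learn's LDA as an independent oracle (never the
    implementation): identical posteriors and predictions on a random
    three-group problem."""

    def test_posteriors_and_predictions_agree(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(18)
        X = rng.normal(size=(90, 4))
        y = np.repeat(["a", "b", "c"], 30)
        X[y == "b"] += [1.5, 0, -1, 0.5]
        X[y == "c"] += [-1, 2, 0, 0]
        model = L.fit_lda(LabeledMatrix(X, y, [f"v{j}" for j in range(4)]))
        sk = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        np.testing.assert_allclose(L.posterior_probabilities(model, X),
                                   sk.predict_proba(X), atol=1e-10)
        assert L.classify(model, X) == list(sk.predict(X))
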