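"""PCA, NIPALS PLS-DA, latent-variable selection, VIP, and OPLS contrasts."""

import numpy as np
import pytest

from oliveauth import chemometrics as chem
from oliveauth.preprocessing import apply_scaling_matrix, fit_scaling


def two_cluster_data(rng, n=20, p=5, gap=6.0):
    x = rng.normal(size=(n, p))
    labels = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    x[labels == "B", 0] += gap
    return x, labels


class TestPCA:
    def test_rank_one_matrix_fully_explained(self):
        x = np.outer([1.0, 2.0, 3.0], [4.0, 5.0])
        res = chem.fit_pca(x, 2)
        assert res.explained[0] == pytest.approx(1.0)
        assert res.explained[1] == pytest.approx(0.0, abs=1e-12)

    def test_pc1_separates_two_clusters(self, rng):
        x, labels = two_cluster_data(rng)
        res = chem.fit_pca(x, 2)
        pc1 = res.scores[:, 0]
        assert (pc1[labels == "A"].mean() < pc1[labels == "B"].mean()) or (
            pc1[labels == "A"].mean() > pc1[labels == "B"].mean()
        )
        # no overlap between cluster score ranges
        a, b = pc1[labels == "A"], pc1[labels == "B"]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or (
            a.max() < b.min() or b.max() < a.min()
        )

    def test_qc_rows_cluster_tighter_than_samples(self, bundle):
        t = bundle.table
        params = fit_scaling(t, "pareto")
        z = apply_scaling_matrix(t.intensities, params)
        res = chem.fit_pca(z, 2)
        qc = res.scores[t.role_mask("qc")]
        samp = res.scores[t.role_mask("sample")]

        def mean_dist(pts):
            c = pts.mean(axis=0)
            return np.linalg.norm(pts - c, axis=1).mean()

        assert mean_dist(qc) < mean_dist(samp)

    def test_explained_fractions_non_increasing(self, rng):
        res = chem.fit_pca(rng.normal(size=(15, 8)), 5)
        assert np.all(np.diff(res.explained) <= 1e-12)


class TestPLSDAFit:
    def test_separable_one_variable(self, rng):
        x, labels = two_cluster_data(rng, gap=10.0)
        model = chem.fit_plsda(x, labels, 1)
        _, assign, _ = chem.predict(model, x)
        assert np.all(assign == labels)

    def test_zero_components_rejected(self, rng):
        x, labels = two_cluster_data(rng)
        with pytest.raises(ValueError):
            chem.fit_plsda(x, labels, 0)

    def test_single_class_rejected(self, rng):
        x = rng.normal(size=(8, 3))
        with pytest.raises(ValueError):
            chem.fit_plsda(x, ["A"] * 8, 1)

    def test_scores_mutually_orthogonal(self, curated, split):
        train = curated.subset_samples(split.train_ids)
        params = fit_scaling(train, "pareto")
        x = apply_scaling_matrix(train.sample_matrix, params)
        model = chem.fit_plsda(x, train.sample_classes, 3)
        gram = model.t.T @ model.t
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() / np.diag(gram).max() < 1e-8

    def test_first_component_matches_svd_oracle(self, rng):
        """Component-1 weights equal the leading left singular vector of
        the X'Y cross-covariance (classical PLS2 property)."""
        x = rng.normal(size=(6, 4))
        labels = np.array(["A", "A", "B", "B", "C", "C"])
        model = chem.fit_plsda(x, labels, 1)
        y = np.zeros((6, 3))
        for i, lab in enumerate(labels):
            y[i, ord(lab) - ord("A")] = 1.0
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        u, _, _ = np.linalg.svd(xc.T @ yc)
        w_oracle = u[:, 0]
        w = model.w[:, 0]
        sign = np.sign(w @ w_oracle)
        assert w == pytest.approx(sign * w_oracle, abs=1e-6)

    def test_matches_sklearn_pls_regression(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        x = rng.normal(size=(20, 8))
        labels = np.array(["A"] * 7 + ["B"] * 7 + ["C"] * 6)
        x[labels == "B", 0] += 6
        x[labels == "C", 1] += 6
        model = chem.fit_plsda(x, labels, 3)
        yhat, _, _ = chem.predict(model, x)
        y = np.zeros((20, 3))
        for i, lab in enumerate(labels):
            y[i, ord(lab) - ord("A")] = 1.0
        # run the reference NIPALS at a comparable convergence tolerance
        ref = sklearn.PLSRegression(
            n_components=3, scale=False, tol=1e-12, max_iter=5000
        ).fit(x, y)
        assert yhat == pytest.approx(ref.predict(x), abs=1e-5)

    def test_r2y_non_decreasing_in_components(self, rng):
        x, labels = two_cluster_data(rng, n=16, p=6, gap=2.0)
        r2 = [chem.fit_plsda(x, labels, a).r2y for a in range(1, 5)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_prediction_invariant_to_feature_reordering(self, rng):
        x, labels = two_cluster_data(rng)
        perm = rng.permutation(x.shape[1])
        m1 = chem.fit_plsda(x, labels, 2)
        m2 = chem.fit_plsda(x[:, perm], labels, 2)
        y1, _, _ = chem.predict(m1, x)
        y2, _, _ = chem.predict(m2, x[:, perm])
        assert y1 == pytest.approx(y2, abs=1e-8)


class TestPredict:
    def test_probability_rows_sum_to_one(self, rng):
        x, labels = two_cluster_data(rng)
        model = chem.fit_plsda(x, labels, 2)
        _, _, proba = chem.predict(model, x)
        assert proba.sum(axis=1) == pytest.approx(np.ones(len(x)), abs=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        x, labels = two_cluster_data(rng)
        model = chem.fit_plsda(x, labels, 1)
        with pytest.raises(ValueError):
            chem.predict(model, x[:, :3])

    def test_synthetic_test_set_fully_correct(self, pipeline_result):
        assert pipeline_result.metrics.error_test == 0.0


class TestLatentVariableSelection:
    def test_separable_toy_needs_one_lv(self, rng):
        x, labels = two_cluster_data(rng, n=20, gap=10.0)
        n_lv, errors = chem.select_n_lv(x, labels, k=5, max_lv=4)
        assert n_lv == 1
        assert errors[0] == 0.0

    def test_default_bundle_reaches_zero_cv_error(self, curated, split):
        train = curated.subset_samples(split.train_ids)
        params = fit_scaling(train, "pareto")
        x = apply_scaling_matrix(train.sample_matrix, params)
        n_lv, errors = chem.select_n_lv(
            x, train.sample_classes, k=5, max_lv=6
        )
        assert errors[n_lv - 1] == 0.0

    def test_fold_count_exceeding_class_size_rejected(self, rng):
        x, labels = two_cluster_data(rng, n=8)
        with pytest.raises(ValueError):
            chem.select_n_lv(x, labels, k=5)


class TestVIP:
    def test_single_variable_vip_is_one(self, rng):
        x = rng.normal(size=(10, 1))
        labels = np.where(x[:, 0] > 0, "A", "B")
        if len(set(labels)) < 2:
            labels[0] = "A" if labels[0] == "B" else "B"
        model = chem.fit_plsda(x, labels, 1)
        assert chem.vip(model) == pytest.approx([1.0])

    def test_mean_squared_vip_is_one(self, rng):
        for n, p, a in [(12, 6, 2), (20, 15, 3), (30, 8, 4)]:
            x = rng.normal(size=(n, p))
            labels = np.array(["A", "B", "C"])[rng.integers(0, 3, n)]
            while len(set(labels)) < 3:
                labels = np.array(["A", "B", "C"])[rng.integers(0, 3, n)]
            model = chem.fit_plsda(x, labels, a)
            v = chem.vip(model)
            assert np.mean(v ** 2) == pytest.approx(1.0, abs=1e-6)

    def test_truth_markers_dominate_vip_ranking(self, pipeline_result):
        truth = pipeline_result.truth
        markers = set(truth.loc[truth.marker_class.notna(), "feature_id"])
        selected = {r.feature_id for r in pipeline_result.markers}
        assert markers <= selected
        for rec in pipeline_result.markers:
            if rec.feature_id in markers:
                assert rec.vip_overall > 0.83


class TestPairwiseOPLS:
    def test_marker_high_in_own_pairs_low_in_third(self, pipeline_result):
        truth = pipeline_result.truth.set_index("feature_id")
        for rec in pipeline_result.markers:
            cls = truth.loc[rec.feature_id, "marker_class"]
            if cls is None or (isinstance(cls, float) and np.isnan(cls)):
                continue
            own = [v for pair, v in rec.vip_pairwise.items() if cls in pair]
            other = [v for pair, v in rec.vip_pairwise.items()
                     if cls not in pair]
            assert min(own) > 0.83
            assert min(own) > max(other)

    def test_predictive_scores_uncorrelated_with_orthogonal(self, rng):
        x, labels = two_cluster_data(rng, n=30, p=10, gap=3.0)
        x[:, 5] += rng.normal(scale=4.0, size=30)  # class-orthogonal variance
        t_pred, t_orth = chem.oplsda_components(x, labels, ("A", "B"))
        r = np.corrcoef(t_pred, t_orth[:, 0])[0, 1]
        assert abs(r) < 1e-6

    def test_empty_class_rejected(self, rng):
        x, labels = two_cluster_data(rng)
        with pytest.raises(ValueError):
            chem.pairwise_oplsda_vip(x, labels, [("A", "Z")])


class TestMarkerSelection:
    def test_strict_cutoff_boundary(self):
        records = [
            chem.VIPRecord("f1", 0.5),
            chem.VIPRecord("f2", 0.83),
            chem.VIPRecord("f3", 0.84),
        ]
        selected = chem.select_markers(records, cutoff=0.83)
        assert [r.feature_id for r in selected] == ["f3"]

    def test_empty_input(self):
        assert chem.select_markers([]) == []
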