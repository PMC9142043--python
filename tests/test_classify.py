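"""PCA-LDA classification and grouped (leave-one-mouse-out) cross-validation."""

import dataclasses

import numpy as np
import pytest

from fabrycars import (
    biplot_data,
    image_mean_spectrum,
    lda_fit,
    lda_predict,
    lomo_cv,
    pc_sweep,
    pca_fit,
)
from fabrycars.classify import ImageFeature
from fabrycars.simulate import leakage_demo_config
from conftest import cohort_features
from oracles import bayes_rule_predict, covariance_pca


class TestImageMeanSpectrum:
    def test_mean_of_identical_rows_is_the_row(self, dataset3_matrices):
        mat = dataset3_matrices[0]
        feat = image_mean_spectrum(mat)
        np.testing.assert_allclose(feat.mean_spectrum, mat.spectra.mean(axis=0))
        assert feat.mouse_id == mat.meta["mouse_id"]

    def test_two_row_average(self, dataset3_matrices):
        mat = dataclasses.replace(
            dataset3_matrices[0],
            spectra=dataset3_matrices[0].spectra[:2],
            pixel_index=dataset3_matrices[0].pixel_index[:2],
        )
        feat = image_mean_spectrum(mat)
        np.testing.assert_allclose(
            feat.mean_spectrum, (mat.spectra[0] + mat.spectra[1]) / 2
        )

    def test_ko_mean_spectrum_lipid_dominant(self, dataset3_matrices):
        ko = next(m for m in dataset3_matrices if m.meta["genotype"] == "KO")
        feat = image_mean_spectrum(ko)
        ax = ko.axis
        assert (
            feat.mean_spectrum[ax.nearest_channel(2850.0)]
            > feat.mean_spectrum[ax.nearest_channel(2940.0)]
        )


class TestPCA:
    def test_collinear_data_is_one_dimensional(self, rng):
        t = rng.normal(size=20)
        X = np.outer(t, np.array([1.0, -2.0, 0.5])) + 7.0
        model = pca_fit(X, 2)
        assert model.explained_variance[0] > 0
        assert model.explained_variance[1] == pytest.approx(0.0, abs=1e-12)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(10, 5))
        p = min(10 - 1, 5)
        model = pca_fit(X, p)
        scores = model.transform(X)
        back = scores @ model.loadings.T + model.mean_vector
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_matches_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(10, 5))
        model = pca_fit(X, 4)
        loadings, variances = covariance_pca(X, 4)
        np.testing.assert_allclose(model.explained_variance, variances, atol=1e-8)
        np.testing.assert_allclose(model.loadings, loadings, atol=1e-8)

    def test_loadings_orthonormal_variance_sorted(self, rng):
        X = rng.normal(size=(30, 8))
        model = pca_fit(X, 5)
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(5), atol=1e-8
        )
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_matches_sklearn(self, rng):
        decomposition = pytest.importorskip("sklearn.decomposition")
        X = rng.normal(size=(25, 7))
        ours = pca_fit(X, 3)
        ref = decomposition.PCA(n_components=3).fit(X)
        np.testing.assert_allclose(
            ours.explained_variance, ref.explained_variance_, atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(ours.loadings), np.abs(ref.components_.T), atol=1e-8
        )

    def test_p_out_of_range_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        for p in (0, 5):
            with pytest.raises(ValueError):
                pca_fit(X, p)


class TestLDA:
    def test_1d_well_separated_classes(self, rng):
        scores = np.concatenate([rng.normal(-1, 0.01, 20), rng.normal(1, 0.01, 20)])
        labels = np.array(["WT"] * 20 + ["KO"] * 20)
        model = lda_fit(scores[:, None], labels)
        pred = lda_predict(model, scores[:, None])
        assert (pred == labels).all()
        boundary = model.threshold / model.weight[0]
        assert abs(boundary) < 0.05

    def test_identical_class_means_fall_back_to_larger_class(self):
        scores = np.array([[0.0], [0.0], [0.0], [0.0], [0.0]])
        labels = np.array(["WT", "WT", "KO", "KO", "KO"])
        model = lda_fit(scores, labels)
        assert model.degenerate_class == "KO"
        assert (lda_predict(model, scores) == "KO").all()

    def test_missing_class_rejected(self, rng):
        with pytest.raises(ValueError):
            lda_fit(rng.normal(size=(5, 2)), np.array(["WT"] * 5))

    def test_matches_bayes_rule_on_shared_covariance_gaussians(self):
        """Trained on a large sample, predictions agree >= 95% with the
        closed-form equal-prior Bayes rule using the true parameters."""
        rng = np.random.default_rng(77)
        cov = np.array([[1.0, 0.4], [0.4, 0.8]])
        chol = np.linalg.cholesky(cov)
        mu_wt, mu_ko = np.array([0.0, 0.0]), np.array([1.2, 0.6])
        n = 2000
        wt = rng.standard_normal((n, 2)) @ chol.T + mu_wt
        ko = rng.standard_normal((n, 2)) @ chol.T + mu_ko
        X = np.vstack([wt, ko])
        labels = np.array(["WT"] * n + ["KO"] * n)
        model = lda_fit(X, labels)
        test = rng.standard_normal((1000, 2)) @ chol.T + (mu_wt + mu_ko) / 2
        ours = lda_predict(model, test)
        bayes = bayes_rule_predict(test, mu_wt, mu_ko, cov)
        assert (ours == bayes).mean() >= 0.95

    def test_matches_sklearn_lda_predictions(self, rng):
        discriminant = pytest.importorskip("sklearn.discriminant_analysis")
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(1.5, 1, (40, 3))])
        labels = np.array(["WT"] * 40 + ["KO"] * 40)
        ours = lda_predict(lda_fit(X, labels), X)
        ref = (
            discriminant.LinearDiscriminantAnalysis(priors=[0.5, 0.5])
            .fit(X, labels)
            .predict(X)
        )
        assert (ours == ref).mean() >= 0.95


def synthetic_features(rng, n_wt=4, n_ko=4, images_per_mouse=2, effect=2.0, C=33):
    feats = []
    for g, n, shift in (("WT", n_wt, 0.0), ("KO", n_ko, effect)):
        for m in range(n):
            mouse = f"{g}{m}"
            base = rng.normal(0, 0.3, C)
            for i in range(images_per_mouse):
                vec = base + rng.normal(0, 0.05, C)
                vec[0] += shift
                feats.append(
                    ImageFeature(
                        mean_spectrum=vec,
                        image_id=f"{mouse}_i{i}",
                        mouse_id=mouse,
                        genotype=g,
                    )
                )
    return feats


class TestLomoCV:
    def test_training_never_contains_heldout_mouse(self, rng, monkeypatch):
        """Grouping invariant asserted programmatically on every fold."""
        import fabrycars.classify as cls

        feats = synthetic_features(rng)
        mouse_of = {f.image_id: f.mouse_id for f in feats}
        seen_folds = []
        real_pca_fit = cls.pca_fit

        X_all = np.array([f.mean_spectrum for f in feats])

        def spy(X, p):
            train_rows = {tuple(np.round(r, 12)) for r in X}
            held = [
                f.mouse_id
                for f, row in zip(feats, X_all)
                if tuple(np.round(row, 12)) not in train_rows
            ]
            seen_folds.append(set(held))
            return real_pca_fit(X, p)

        monkeypatch.setattr(cls, "pca_fit", spy)
        cls.lomo_cv(feats, 2, bootstrap_B=5, seed=0)
        assert seen_folds and all(len(held) == 1 for held in seen_folds)

    def test_perfect_separation_gives_100(self, rng):
        feats = synthetic_features(rng, effect=50.0)
        res = lomo_cv(feats, 2, bootstrap_B=10, seed=0)
        assert res.mean_sensitivity == pytest.approx(100.0)
        assert res.mean_sensitivity == pytest.approx(
            (res.sensitivity_wt + res.sensitivity_ko) / 2
        )

    def test_label_swap_leaves_mean_sensitivity_invariant(self, rng):
        feats = synthetic_features(rng, effect=0.8)
        swapped = [
            ImageFeature(
                mean_spectrum=f.mean_spectrum,
                image_id=f.image_id,
                mouse_id=f.mouse_id,
                genotype="KO" if f.genotype == "WT" else "WT",
            )
            for f in feats
        ]
        a = lomo_cv(feats, 2, bootstrap_B=5, seed=0)
        b = lomo_cv(swapped, 2, bootstrap_B=5, seed=0)
        assert a.mean_sensitivity == pytest.approx(b.mean_sensitivity)
        assert a.sensitivity_wt == pytest.approx(b.sensitivity_ko)

    def test_infeasible_n_pc_names_fold(self, rng):
        feats = synthetic_features(rng, n_wt=2, n_ko=2, images_per_mouse=1, C=5)
        with pytest.raises(ValueError, match="n_pc=4 infeasible in fold"):
            lomo_cv(feats, 4, bootstrap_B=5, seed=0)

    def test_fewer_than_two_mice_per_genotype_rejected(self, rng):
        feats = synthetic_features(rng, n_wt=1, n_ko=3)
        with pytest.raises(ValueError, match="2 mice"):
            lomo_cv(feats, 1)

    def test_permuted_labels_give_chance_level(self, dataset3_features):
        """Mouse-level label permutation null: mean of mean sensitivity over
        50 permutations sits near 50%."""
        rng = np.random.default_rng(5)
        mice = sorted({f.mouse_id for f in dataset3_features})
        genos = [
            next(f.genotype for f in dataset3_features if f.mouse_id == m)
            for m in mice
        ]
        vals = []
        for done in range(50):
            perm = rng.permutation(genos)
            mapping = dict(zip(mice, perm))
            permuted = [
                ImageFeature(
                    mean_spectrum=f.mean_spectrum,
                    image_id=f.image_id,
                    mouse_id=f.mouse_id,
                    genotype=mapping[f.mouse_id],
                )
                for f in dataset3_features
            ]
            vals.append(lomo_cv(permuted, 2, bootstrap_B=2, seed=done).mean_sensitivity)
        assert 40.0 <= float(np.mean(vals)) <= 60.0

    def test_subject_leakage_inflates_image_level_cv(self):
        """Zero genotype effect + strong per-mouse batch effects: naive
        image-level CV beats grouped LOMO-CV by >= 10 points."""
        grouped, naive = [], []
        for s in range(4):
            feats = cohort_features(leakage_demo_config(seed=s))
            grouped.append(lomo_cv(feats, 2, bootstrap_B=5, seed=s).mean_sensitivity)
            naive.append(
                lomo_cv(
                    feats, 2, bootstrap_B=5, seed=s, group_by_mouse=False
                ).mean_sensitivity
            )
        assert np.mean(naive) - np.mean(grouped) >= 10.0
        assert 25.0 <= np.mean(grouped) <= 75.0


class TestPCSweep:
    def test_curve_capped_at_15(self, dataset3_features):
        curve, optimal = pc_sweep(dataset3_features, max_pc=15, bootstrap_B=5, seed=0)
        assert len(curve) <= 15
        assert [r.n_pc for r in curve] == list(range(1, len(curve) + 1))
        assert 1 <= optimal <= len(curve)

    def test_pc1_separable_cohort_optimal_is_1(self, rng):
        feats = synthetic_features(rng, effect=50.0)
        curve, optimal = pc_sweep(feats, max_pc=4, bootstrap_B=5, seed=0)
        assert optimal == 1

    def test_optimal_is_smallest_argmax(self, rng, monkeypatch):
        import fabrycars.classify as cls

        feats = synthetic_features(rng)
        real = cls.lomo_cv

        def rigged(features, n_pc, bootstrap_B=200, seed=0, group_by_mouse=True):
            res = real(features, n_pc, bootstrap_B=bootstrap_B, seed=seed)
            forced = {1: 80.0, 2: 95.0, 3: 90.0, 4: 95.0}.get(n_pc, 70.0)
            return dataclasses.replace(res, mean_sensitivity=forced)

        monkeypatch.setattr(cls, "lomo_cv", rigged)
        _, optimal = cls.pc_sweep(feats, max_pc=4, bootstrap_B=2, seed=0)
        assert optimal == 2


class TestBiplot:
    def test_scores_centered_and_row_count(self, dataset3_features):
        df = biplot_data(dataset3_features)
        assert len(df) == len(dataset3_features)
        assert df.PC1.mean() == pytest.approx(0.0, abs=1e-8)
        assert df.PC2.mean() == pytest.approx(0.0, abs=1e-8)

    def test_scores_match_covariance_oracle(self, dataset3_features):
        X = np.array([f.mean_spectrum for f in dataset3_features])
        loadings, _ = covariance_pca(X, 2)
        expected = (X - X.mean(axis=0)) @ loadings
        df = biplot_data(dataset3_features)
        np.testing.assert_allclose(df[["PC1", "PC2"]].to_numpy(), expected, atol=1e-8)

    def test_too_few_images_rejected(self, dataset3_features):
        with pytest.raises(ValueError):
            biplot_data(dataset3_features[:2])
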