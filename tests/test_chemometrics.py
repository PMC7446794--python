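import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ramscreen import (
    DAPCModel,
    RamanSpectrum,
    SpectrumSet,
    SyntheticConfig,
    classify,
    fit_dapc,
    fit_pca,
    generate_cohort,
    preprocess_pipeline,
    project,
)
from ramscreen.chemometrics import canonical_coordinates, project_matrix


def _meta(ids, labels):
    return pd.DataFrame(
        {"specimen_id": ids, "class_label": labels, "dataset": "synthetic"}
    )


def _random_set(n_rows, n_cols, seed, labels=None):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n_rows)]
    labels = labels or ["x"] * n_rows
    return SpectrumSet(
        np.arange(400.0, 400.0 + n_cols),
        rng.normal(size=(n_rows, n_cols)),
        ids,
        [0] * n_rows,
        _meta(ids, labels),
    )


class TestPCA:
    def test_two_spectra_give_one_component(self):
        sset = _random_set(2, 20, seed=0)
        model = fit_pca(sset)
        assert model.n_components == 1

    def test_full_reconstruction(self):
        sset = _random_set(8, 12, seed=1)
        model = fit_pca(sset)
        centered = sset.matrix - model.mean_spectrum
        scores = centered @ model.loadings
        assert np.allclose(scores @ model.loadings.T, centered, atol=1e-8)

    def test_orthonormal_loadings_and_descending_variance(self):
        sset = _random_set(10, 30, seed=2)
        model = fit_pca(sset)
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(model.n_components), atol=1e-8)
        evf = model.explained_variance_fraction
        assert np.all(np.diff(evf) <= 1e-12)
        assert evf.sum() <= 1.0 + 1e-12

    def test_rank_one_data_concentrates_variance(self):
        rng = np.random.default_rng(3)
        direction = rng.normal(size=50)
        direction /= np.linalg.norm(direction)
        coords = rng.normal(size=(20, 1)) * 5.0
        matrix = coords * direction + rng.normal(scale=1e-3, size=(20, 50))
        ids = [f"s{i}" for i in range(20)]
        sset = SpectrumSet(np.arange(400.0, 450.0), matrix, ids, [0] * 20, _meta(ids, ["x"] * 20))
        model = fit_pca(sset)
        assert model.explained_variance_fraction[0] > 0.99

    def test_matches_brute_force_covariance_eigendecomposition(self):
        # independent oracle: eigendecomposition of the sample covariance
        sset = _random_set(10, 10, seed=4)
        model = fit_pca(sset)
        centered = sset.matrix - sset.matrix.mean(axis=0)
        cov = centered.T @ centered
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1][: model.n_components]
        for j, k in enumerate(order):
            v = eigvecs[:, k]
            dot = abs(float(v @ model.loadings[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)
            np.testing.assert_allclose(
                np.abs(centered @ v), np.abs(centered @ model.loadings[:, j]), atol=1e-8
            )

    def test_sign_convention_deterministic(self):
        sset = _random_set(6, 15, seed=5)
        model = fit_pca(sset)
        for j in range(model.n_components):
            i = np.argmax(np.abs(model.loadings[:, j]))
            assert model.loadings[i, j] > 0


class TestProject:
    def test_mean_spectrum_projects_to_zero(self):
        sset = _random_set(6, 15, seed=6)
        model = fit_pca(sset)
        mean = RamanSpectrum(sset.grid, model.mean_spectrum, "mean")
        assert np.allclose(project(model, mean), 0.0, atol=1e-10)

    def test_training_scores_reproduced(self):
        sset = _random_set(6, 15, seed=7)
        model = fit_pca(sset)
        stored = project_matrix(model, sset.matrix)
        for i, s in enumerate(sset.spectra()):
            assert np.allclose(project(model, s), stored[i], atol=1e-12)

    def test_score_norm_bounded_by_centered_norm(self):
        sset = _random_set(6, 15, seed=8)
        model = fit_pca(sset)
        for s in sset.spectra():
            centered = s.intensities - model.mean_spectrum
            assert np.linalg.norm(project(model, s)) <= np.linalg.norm(centered) + 1e-12

    def test_grid_mismatch_errors(self):
        sset = _random_set(4, 10, seed=9)
        model = fit_pca(sset)
        other = RamanSpectrum(np.arange(500.0, 510.0), np.zeros(10), "o")
        with pytest.raises(ValueError):
            project(model, other)


def _labelled_cohort(seed=21, effect=3.0, n=6):
    cfg = SyntheticConfig(
        seed=seed,
        n_per_class={"BCA-positive": n, "BCA-negative": n},
        scans_per_specimen=3,
        peaks=[
            # a large class-dependent peak plus stable background bands
            __import__("ramscreen").PeakSpec(
                center=1004.0, width=7.0, base_height=30.0,
                class_effect={"BCA-positive": effect},
            ),
            __import__("ramscreen").PeakSpec(center=680.0, width=9.0, base_height=40.0),
            __import__("ramscreen").PeakSpec(center=1440.0, width=10.0, base_height=25.0),
        ],
    )
    sset, _ = generate_cohort(cfg)
    return preprocess_pipeline(sset, average=True)


class TestDAPC:
    def test_strong_effect_separates_centroids(self):
        pre = _labelled_cohort()
        model = fit_dapc(pre, n_pcs=4)
        # canonical space is whitened: pooled within-class SD is 1
        sep = abs(model.class_centroids[0, 0] - model.class_centroids[1, 0])
        assert sep > 5.0

    def test_row_permutation_leaves_model_invariant(self):
        pre = _labelled_cohort()
        rng = np.random.default_rng(0)
        perm = rng.permutation(pre.n_rows)
        model_a = fit_dapc(pre, n_pcs=3)
        model_b = fit_dapc(pre.subset_rows(perm), n_pcs=3)
        assert model_a.class_labels == model_b.class_labels
        np.testing.assert_allclose(
            np.abs(model_a.class_centroids), np.abs(model_b.class_centroids), atol=1e-6
        )

    def test_three_classes_give_two_canonicals(self):
        cfg = SyntheticConfig(
            seed=13,
            n_per_class={"A": 4, "B": 4, "C": 4},
            scans_per_specimen=2,
        )
        sset, _ = generate_cohort(cfg)
        pre = preprocess_pipeline(sset, average=True)
        model = fit_dapc(pre, n_pcs=5)
        assert model.n_canonicals == 2

    def test_single_class_errors(self):
        sset = _random_set(4, 10, seed=10, labels=["x"] * 4)
        with pytest.raises(ValueError):
            fit_dapc(sset, n_pcs=2)

    def test_n_pcs_exceeding_components_errors(self):
        sset = _random_set(4, 10, seed=11, labels=["x", "x", "y", "y"])
        with pytest.raises(ValueError):
            fit_dapc(sset, n_pcs=10)

    def test_matches_sklearn_lda_subspace(self):
        # independent cross-check: canonical axis of 2-class DAPC spans the
        # same direction as sklearn's LDA scalings on the PC scores
        pre = _labelled_cohort()
        n_pcs = 4
        model = fit_dapc(pre, n_pcs=n_pcs)
        scores = project_matrix(model.pca, pre.matrix, n_pcs)
        lda = LinearDiscriminantAnalysis(solver="eigen").fit(scores, pre.labels())
        a = model.canonical_coefficients[:, 0]
        b = lda.scalings_[:, 0]
        cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_one_pc_two_class_equals_fisher_threshold(self):
        # closed-form oracle on a 1-D problem: the canonical axis is the
        # score axis itself, and classification thresholds at the midpoint
        # of the class centroids (equal within-class variances by pooling)
        rng = np.random.default_rng(14)
        ids = [f"s{i}" for i in range(12)]
        labels = ["neg"] * 6 + ["pos"] * 6
        base = np.zeros(8)
        x = np.concatenate([rng.normal(0.0, 1.0, 6), rng.normal(6.0, 1.0, 6)])
        matrix = base + np.outer(x, np.ones(8))
        sset = SpectrumSet(np.arange(400.0, 408.0), matrix, ids, [0] * 12, _meta(ids, labels))
        model = fit_dapc(sset, n_pcs=1)
        c_neg = model.class_centroids[model.class_labels.index("neg"), 0]
        c_pos = model.class_centroids[model.class_labels.index("pos"), 0]
        midpoint = 0.5 * (c_neg + c_pos)
        for i, s in enumerate(sset.spectra()):
            label, coords = classify(model, s)
            expected = "pos" if (coords[0] - midpoint) * np.sign(c_pos - c_neg) > 0 else "neg"
            assert label == expected

    def test_resubstitution_accuracy_monotone_in_n_pcs(self):
        pre = _labelled_cohort(seed=22, effect=1.5)
        labels = pre.labels()
        accs = []
        for n_pcs in range(1, 8):
            model = fit_dapc(pre, n_pcs=n_pcs)
            correct = sum(
                classify(model, s)[0] == lab for s, lab in zip(pre.spectra(), labels)
            )
            accs.append(correct)
        assert all(b >= a for a, b in zip(accs, accs[1:]))


class TestClassify:
    def test_centroid_spectrum_classifies_to_own_class(self):
        pre = _labelled_cohort()
        model = fit_dapc(pre, n_pcs=3)
        labels = pre.labels()
        for cls in model.class_labels:
            centroid = pre.matrix[labels == cls].mean(axis=0)
            label, _ = classify(model, RamanSpectrum(pre.grid, centroid, "c"))
            assert label == cls

    def test_tie_breaks_toward_reference_class(self):
        ids = ["a1", "a2", "b1", "b2"]
        labels = ["A", "A", "B", "B"]
        matrix = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1]])
        sset = SpectrumSet(np.array([400.0, 401.0]), matrix, ids, [0] * 4, _meta(ids, labels))
        model = fit_dapc(sset, n_pcs=1, reference_order=["B", "A"])
        midpoint = RamanSpectrum(np.array([400.0, 401.0]), np.array([5.0, 0.5]), "m")
        label, _ = classify(model, midpoint)
        assert label == "B"

    def test_classification_invariant_to_constant_offset_end_to_end(self, small_cohort):
        # a constant added to raw intensities is absorbed by the baseline fit
        sset, _ = small_cohort
        shifted = SpectrumSet(
            sset.grid, sset.matrix + 50.0, sset.specimen_ids, sset.scan_indices, sset.metadata
        )
        pre_a = preprocess_pipeline(sset, average=True)
        pre_b = preprocess_pipeline(shifted, average=True)
        model = fit_dapc(pre_a, n_pcs=4)
        for s_a, s_b in zip(pre_a.spectra(), pre_b.spectra()):
            assert classify(model, s_a)[0] == classify(model, s_b)[0]


def test_model_serialization_round_trip(tmp_path):
    pre = _labelled_cohort()
    model = fit_dapc(pre, n_pcs=3)
    path = tmp_path / "model.json"
    model.save(path)
    back = DAPCModel.load(path)
    assert back.class_labels == model.class_labels
    np.testing.assert_allclose(back.canonical_coefficients, model.canonical_coefficients)
    s = pre.spectra()[0]
    assert classify(back, s)[0] == classify(model, s)[0]
    np.testing.assert_allclose(canonical_coordinates(back, s), canonical_coordinates(model, s))
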