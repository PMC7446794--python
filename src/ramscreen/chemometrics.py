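"""PCA and discriminant analysis of principal components (DAPC).

PCA reduces each preprocessed urine spectrum (~1,400 intensity values) to a
small number of scores; DAPC then fits canonical discriminant axes on those
scores so that labelled specimen classes (e.g. BCA-positive vs BCA-negative
vs the Surine control) separate.  Classification of an unknown spectrum is
nearest-centroid in the whitened canonical space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .spectra import RamanSpectrum, SpectrumSet

__all__ = ["PCAModel", "DAPCModel", "fit_pca", "project", "fit_dapc", "classify"]


@dataclass(frozen=True)
class PCAModel:
    """Mean-centred SVD decomposition of a spectra matrix.

    ``loadings`` has orthonormal columns (wavenumbers x components);
    ``explained_variance_fraction`` is non-increasing and sums to <= 1.
    The sign of each component is fixed so its largest-magnitude loading
    element is positive, making scores reproducible across backends.
    """

    grid: np.ndarray
    mean_spectrum: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "mean_spectrum": self.mean_spectrum.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            np.asarray(d["grid"], float),
            np.asarray(d["mean_spectrum"], float),
            np.asarray(d["loadings"], float),
            np.asarray(d["explained_variance_fraction"], float),
        )


@dataclass(frozen=True)
class DAPCModel:
    """Canonical discriminant model on top of a truncated PCA.

    ``canonical_coefficients`` (n_pcs x n_canonicals) maps PC scores to
    canonical coordinates scaled so the pooled within-class covariance is
    the identity; nearest-centroid distance there is thus Mahalanobis.
    ``reference_order`` fixes deterministic tie-breaking: on exact distance
    ties the class occurring earliest in it wins (screening fails toward
    the reference/negative class, sending ties to gold-standard follow-up).
    """

    pca: PCAModel
    n_pcs: int
    canonical_coefficients: np.ndarray
    class_centroids: np.ndarray
    class_labels: list[str]
    reference_order: list[str]
    priors: np.ndarray

    @property
    def n_canonicals(self) -> int:
        return self.canonical_coefficients.shape[1]

    def to_dict(self) -> dict:
        return {
            "pca": self.pca.to_dict(),
            "n_pcs": self.n_pcs,
            "canonical_coefficients": self.canonical_coefficients.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "class_labels": list(self.class_labels),
            "reference_order": list(self.reference_order),
            "priors": self.priors.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DAPCModel":
        return cls(
            PCAModel.from_dict(d["pca"]),
            int(d["n_pcs"]),
            np.asarray(d["canonical_coefficients"], float),
            np.asarray(d["class_centroids"], float),
            list(d["class_labels"]),
            list(d["reference_order"]),
            np.asarray(d["priors"], float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "DAPCModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_pca(sset: SpectrumSet, n_components: int | None = None) -> PCAModel:
    """Fit PCA by SVD of the column-mean-centred spectra matrix.

    At most ``n_rows - 1`` components are retained (centring removes one
    degree of freedom).
    """
    if sset.n_rows < 2:
        raise ValueError("PCA needs at least 2 spectra")
    mean = sset.matrix.mean(axis=0)
    centered = sset.matrix - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(sset.n_rows - 1, centered.shape[1])
    if n_components is not None:
        k = min(k, int(n_components))
    loadings = vt[:k].T.copy()
    # deterministic sign: largest-|.| element of each loading made positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
    total_var = float((centered**2).sum())
    evf = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PCAModel(sset.grid.copy(), mean, loadings, evf)


def _check_grid(model_grid: np.ndarray, wavenumbers: np.ndarray) -> None:
    if len(wavenumbers) != len(model_grid) or not np.allclose(wavenumbers, model_grid):
        raise ValueError("spectrum grid does not match the model grid")


def project(model: PCAModel, spectrum: RamanSpectrum, n_pcs: int | None = None) -> np.ndarray:
    """PC scores of a spectrum: (intensities - mean) @ loadings[:, :n_pcs]."""
    _check_grid(model.grid, spectrum.wavenumbers)
    n_pcs = model.n_components if n_pcs is None else int(n_pcs)
    if n_pcs > model.n_components:
        raise ValueError(f"requested {n_pcs} PCs, model holds {model.n_components}")
    return (spectrum.intensities - model.mean_spectrum) @ model.loadings[:, :n_pcs]


def project_matrix(model: PCAModel, matrix: np.ndarray, n_pcs: int | None = None) -> np.ndarray:
    n_pcs = model.n_components if n_pcs is None else int(n_pcs)
    return (matrix - model.mean_spectrum) @ model.loadings[:, :n_pcs]


def fit_dapc(
    sset: SpectrumSet,
    n_pcs: int,
    label_column: str = "class_label",
    reference_order: list[str] | None = None,
) -> DAPCModel:
    """Fit DAPC: PCA truncation followed by canonical variates on scores.

    Canonical directions solve the generalized eigenproblem of the
    between-class against the pooled within-class scatter of the PC scores;
    the within-class scatter is ridge-regularized by 1e-8 x trace on the
    diagonal when near-singular.  n_canonicals = min(n_classes-1, n_pcs).
    Class priors are uniform.
    """
    labels = np.asarray(sset.labels(label_column), dtype=object)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("DAPC needs at least 2 classes")
    counts = {c: int((labels == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"every class needs >= 2 training spectra; too small: {small}")
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")

    pca = fit_pca(sset)
    if n_pcs > pca.n_components:
        raise ValueError(f"n_pcs={n_pcs} exceeds available components ({pca.n_components})")
    scores = project_matrix(pca, sset.matrix, n_pcs)

    overall = scores.mean(axis=0)
    n_can = min(len(classes) - 1, n_pcs)
    sw = np.zeros((n_pcs, n_pcs))
    sb = np.zeros((n_pcs, n_pcs))
    class_means = np.empty((len(classes), n_pcs))
    for ci, c in enumerate(classes):
        sub = scores[labels == c]
        mu = sub.mean(axis=0)
        class_means[ci] = mu
        dev = sub - mu
        sw += dev.T @ dev
        diff = mu - overall
        sb += len(sub) * np.outer(diff, diff)
    n_total = len(labels)
    sw /= max(n_total - len(classes), 1)
    sb /= max(len(classes) - 1, 1)
    ridge = 1e-8 * max(np.trace(sw), 1e-300)
    sw_reg = sw + ridge * np.eye(n_pcs)

    # generalized symmetric eigenproblem Sb v = lambda Sw v
    eigvals, eigvecs = scipy.linalg.eigh(sb, sw_reg)
    order = np.argsort(eigvals)[::-1][:n_can]
    coeffs = eigvecs[:, order]
    # scale columns so within-class variance along each canonical is 1
    for j in range(coeffs.shape[1]):
        v = coeffs[:, j]
        s2 = float(v @ sw_reg @ v)
        coeffs[:, j] = v / np.sqrt(max(s2, 1e-300))
        i = int(np.argmax(np.abs(coeffs[:, j])))
        if coeffs[i, j] < 0:
            coeffs[:, j] *= -1.0

    centroids = class_means @ coeffs
    pca_trunc = PCAModel(
        pca.grid,
        pca.mean_spectrum,
        pca.loadings[:, :n_pcs].copy(),
        pca.explained_variance_fraction[:n_pcs].copy(),
    )
    if reference_order is None:
        reference_order = classes
    priors = np.full(len(classes), 1.0 / len(classes))
    return DAPCModel(pca_trunc, n_pcs, coeffs, centroids, classes, list(reference_order), priors)


def canonical_coordinates(model: DAPCModel, spectrum: RamanSpectrum) -> np.ndarray:
    scores = project(model.pca, spectrum, model.n_pcs)
    return scores @ model.canonical_coefficients


def classify(model: DAPCModel, spectrum: RamanSpectrum) -> tuple[str, np.ndarray]:
    """Assign the class whose canonical centroid is nearest (Mahalanobis).

    Exact distance ties break toward the earliest class in
    ``model.reference_order``.
    """
    coords = canonical_coordinates(model, spectrum)
    diff = model.class_centroids - coords
    # rescale before squaring: whitening can blow coordinates up when the
    # within-class scatter is (near-)singular
    scale = max(float(np.max(np.abs(diff))), 1.0)
    d2 = ((diff / scale) ** 2).sum(axis=1)
    best = np.min(d2)
    tied = [model.class_labels[i] for i in np.flatnonzero(d2 == best)]
    if len(tied) > 1:
        rank = {c: i for i, c in enumerate(model.reference_order)}
        tied.sort(key=lambda c: rank.get(c, len(rank)))
    return tied[0], coords
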