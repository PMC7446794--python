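"""Spectral processing chain: truncate, baseline-correct, normalize, average.

The chain mirrors standard chemometric practice for liquid-urine Raman
screening: spectra are truncated to the 400-1,800 cm^-1 fingerprint region,
the broad fluorescence background is removed with a Goldindec-style
iterative polynomial fit, each scan is scaled to unit Euclidean norm, and
replicate scans of a specimen are averaged into one representative spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .spectra import RamanSpectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "BaselineResult",
    "truncate",
    "goldindec_baseline",
    "vector_normalize",
    "average_replicates",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Processing parameters.

    trunc_low/trunc_high : cm^-1, half-open truncation window [low, high).
    poly_order           : degree of the fluorescence-baseline polynomial.
    peak_ratio           : target fraction of points treated as peak-like
                           when choosing the asymmetric-loss threshold.
    smooth_window        : odd moving-average width (points) applied to the
                           input before the baseline fit.
    max_iter, tol        : inner-fit stopping rule (relative coefficient
                           change below tol, or max_iter reached).
    """

    trunc_low: float = 400.0
    trunc_high: float = 1800.0
    poly_order: int = 3
    peak_ratio: float = 0.5
    smooth_window: int = 5
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.trunc_low < self.trunc_high:
            raise ValueError("trunc_low must be < trunc_high")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        if not (0.0 < self.peak_ratio < 1.0):
            raise ValueError("peak_ratio must lie in (0, 1)")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")


@dataclass(frozen=True)
class BaselineResult:
    baseline: np.ndarray
    corrected: RamanSpectrum
    threshold: float
    converged: bool


def truncate(spectrum: RamanSpectrum, low: float = 400.0, high: float = 1800.0) -> RamanSpectrum:
    """Keep exactly the points with ``low <= w < high`` (half-open).

    The half-open window makes a 1 cm^-1 integer grid over the fingerprint
    region come out at exactly 1,400 points.
    """
    w = spectrum.wavenumbers
    mask = (w >= low) & (w < high)
    if int(mask.sum()) < 2:
        raise ValueError(
            f"truncation [{low}, {high}) leaves {int(mask.sum())} points of "
            f"spectrum {spectrum.specimen_id!r}:{spectrum.scan_index}"
        )
    return RamanSpectrum(w[mask], spectrum.intensities[mask], spectrum.specimen_id, spectrum.scan_index)


def _smooth(y: np.ndarray, window: int, poly_order: int) -> np.ndarray:
    if window <= 1:
        return y
    # Savitzky-Golay of the baseline's own order: suppresses scan noise while
    # reproducing any degree<=poly_order trend exactly, so smoothing never
    # biases the fitted baseline away from a polynomial input
    return scipy.signal.savgol_filter(y, window, min(poly_order, window - 1), mode="interp")


def _clipped_polyfit(
    basis_q: np.ndarray,
    y: np.ndarray,
    threshold: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, bool]:
    """Iterative asymmetric polynomial fit at a fixed peak threshold.

    Points rising more than ``threshold`` above the current baseline are
    treated as Raman peaks: their influence is capped by clipping the target
    at baseline + threshold before refitting (a truncated-quadratic loss in
    iteratively-reweighted form). Returns polynomial coefficients in the
    orthonormal basis and a convergence flag.
    """
    target = y
    coef = basis_q.T @ target
    for _ in range(max_iter):
        baseline = basis_q @ coef
        target = np.minimum(y, baseline + threshold)
        new_coef = basis_q.T @ target
        denom = max(np.linalg.norm(coef), 1e-30)
        delta = np.linalg.norm(new_coef - coef) / denom
        coef = new_coef
        if delta < tol:
            return coef, True
    return coef, False


def goldindec_baseline(spectrum: RamanSpectrum, cfg: PreprocessConfig | None = None) -> BaselineResult:
    """Fit and subtract a polynomial fluorescence baseline (Goldindec style).

    The input is smoothed with a centered moving average, then a degree-
    ``poly_order`` polynomial is fitted by an iterative asymmetric-cost
    procedure: intensities more than a threshold ``s`` above the running
    baseline count as peak-like and have their pull on the fit capped. The
    threshold is located by one-dimensional bisection so that the fraction
    of peak-like points matches ``peak_ratio`` (the fraction is monotone
    non-increasing in ``s``). Non-convergence sets ``converged=False`` on
    the result rather than raising.
    """
    cfg = cfg or PreprocessConfig()
    w = spectrum.wavenumbers
    y_raw = spectrum.intensities
    y = _smooth(y_raw, cfg.smooth_window, cfg.poly_order)

    # orthonormal polynomial basis on the (scaled) grid: one QR up front,
    # every inner fit is then a single projection
    x = (w - w.mean()) / max(np.ptp(w) / 2.0, 1e-30)
    vander = np.vander(x, cfg.poly_order + 1, increasing=True)
    basis_q, _ = np.linalg.qr(vander)

    scale = float(np.ptp(y))
    if scale == 0.0:
        baseline = np.full_like(y, y[0])
        corrected = spectrum.replace_intensities(y_raw - baseline)
        return BaselineResult(baseline, corrected, 0.0, True)

    def peak_fraction(threshold: float) -> tuple[float, np.ndarray, bool]:
        coef, conv = _clipped_polyfit(basis_q, y, threshold, cfg.max_iter, cfg.tol)
        baseline = basis_q @ coef
        frac = float(np.mean(y > baseline + threshold))
        return frac, baseline, conv

    lo, hi = 1e-12 * scale, 2.0 * scale
    frac_lo, baseline, converged = peak_fraction(lo)
    if frac_lo <= cfg.peak_ratio:
        # even a vanishing threshold marks fewer points peak-like than asked
        # (e.g. a peak-free polynomial input): keep the tightest fit
        threshold = lo
    else:
        threshold = hi
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            frac, baseline_mid, conv_mid = peak_fraction(mid)
            if frac > cfg.peak_ratio:
                lo = mid
            else:
                hi = mid
                baseline, converged = baseline_mid, conv_mid
            threshold = hi
            if (hi - lo) < 1e-9 * scale:
                break

    corrected = spectrum.replace_intensities(y_raw - baseline)
    return BaselineResult(baseline, corrected, float(threshold), bool(converged))


def vector_normalize(spectrum: RamanSpectrum) -> RamanSpectrum:
    """Scale intensities to unit Euclidean norm."""
    norm = float(np.linalg.norm(spectrum.intensities))
    if norm == 0.0:
        raise ValueError(
            f"cannot normalize all-zero spectrum {spectrum.specimen_id!r}:{spectrum.scan_index}"
        )
    return spectrum.replace_intensities(spectrum.intensities / norm)


def average_replicates(sset: SpectrumSet) -> SpectrumSet:
    """Collapse replicate scans to one pointwise-mean spectrum per specimen.

    Row order follows first appearance of each specimen; the averaged row
    gets scan_index 0.
    """
    if sset.n_rows == 0:
        raise ValueError("empty spectrum set")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(sset.specimen_ids):
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(i)
    matrix = np.vstack([sset.matrix[groups[sid]].mean(axis=0) for sid in order])
    return SpectrumSet(sset.grid, matrix, order, [0] * len(order), sset.metadata)


def preprocess_pipeline(
    sset: SpectrumSet,
    cfg: PreprocessConfig | None = None,
    average: bool = True,
) -> SpectrumSet:
    """Run truncate -> baseline -> vector-normalize (-> average) on a set.

    ``average=False`` keeps one row per scan, as used by the TPD analyses
    that operate on unaveraged replicate spectra.
    """
    cfg = cfg or PreprocessConfig()
    processed = []
    for s in sset.spectra():
        t = truncate(s, cfg.trunc_low, cfg.trunc_high)
        corrected = goldindec_baseline(t, cfg).corrected
        processed.append(vector_normalize(corrected))
    grid = processed[0].wavenumbers
    out = SpectrumSet(
        grid,
        np.vstack([p.intensities for p in processed]),
        list(sset.specimen_ids),
        list(sset.scan_indices),
        sset.metadata,
    )
    return average_replicates(out) if average else out
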