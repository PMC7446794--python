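"""Synthetic urine-like Raman cohorts with known ground truth.

Real patient spectra are license-restricted, so validation runs on
generated cohorts that emulate the acquisition structure of the screening
study: a 1 cm^-1 grid over 100-3,000 cm^-1, 10 replicate scans per
specimen, smooth cubic fluorescence baselines, urine-like Gaussian peaks
whose heights shift multiplicatively by class, between-specimen log-normal
height jitter and per-scan additive Gaussian noise.  The default cohort
composition matches the screening study's urology-clinic arm: 17
BCA-positive and 39 BCA-negative specimens.

Every run is driven by one explicitly seeded generator; the returned truth
table retains the per-specimen baseline coefficients and realized peak
heights so that baseline-recovery and signature-recovery tests have an
independent ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import SpectrumSet

__all__ = ["PeakSpec", "SyntheticConfig", "CohortTruth", "generate_cohort", "null_cohort"]

POSITIVE = "BCA-positive"
NEGATIVE = "BCA-negative"


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian Raman band.

    ``class_effect`` maps class label -> multiplicative height factor
    (classes not listed get 1.0).
    """

    center: float
    width: float
    base_height: float
    class_effect: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.base_height < 0:
            raise ValueError("base_height must be >= 0")
        if any(f <= 0 for f in self.class_effect.values()):
            raise ValueError("class-effect factors must be > 0")

    def factor(self, class_label: str) -> float:
        return self.class_effect.get(class_label, 1.0)


def default_peaks(effect: float = 1.3) -> list[PeakSpec]:
    """Urine-like band set: strong urea/creatinine background plus the
    signature bands, a subset of which carries a BCA-positive height effect."""
    affected = {576.0, 721.0, 1004.0, 1340.0, 1048.0}
    signature = [576, 702, 721, 817, 827, 846, 981, 1004, 1048, 1065, 1127, 1297, 1340, 1417, 1518]
    peaks = [
        # dominant urine background bands
        PeakSpec(center=1002.0, width=8.0, base_height=80.0),   # urea C-N stretch
        PeakSpec(center=680.0, width=9.0, base_height=25.0),    # creatinine
        PeakSpec(center=640.0, width=10.0, base_height=12.0),   # uric acid
        PeakSpec(center=1605.0, width=14.0, base_height=10.0),
        PeakSpec(center=2100.0, width=40.0, base_height=6.0),
        PeakSpec(center=2900.0, width=35.0, base_height=15.0),  # C-H stretch region
    ]
    for c in signature:
        eff = {POSITIVE: effect} if float(c) in affected else {}
        peaks.append(PeakSpec(center=float(c), width=7.0, base_height=12.0, class_effect=eff))
    return peaks


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort generation parameters.

    grid_*              : wavenumber grid (cm^-1), default 100-3,000 step 1.
    n_per_class         : specimens per class label (default 17 positive /
                          39 negative, the urology-clinic composition).
    scans_per_specimen  : replicate scans per specimen (default 10).
    peaks               : Gaussian band set; ``default_peaks()`` if None.
    baseline_ranges     : uniform draw ranges for the four cubic baseline
                          coefficients (constant..cubic) in the normalized
                          abscissa t = (w - mid)/halfspan.
    specimen_sd         : sigma of the log-normal between-specimen height
                          jitter (per peak).
    scan_sd             : sd of the additive per-scan Gaussian noise (a.u.).
    seed                : mandatory RNG seed.
    """

    seed: int
    grid_start: float = 100.0
    grid_stop: float = 3000.0
    grid_step: float = 1.0
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {POSITIVE: 17, NEGATIVE: 39}
    )
    scans_per_specimen: int = 10
    peaks: list[PeakSpec] | None = None
    baseline_ranges: tuple[tuple[float, float], ...] = (
        (150.0, 350.0),
        (-120.0, -30.0),
        (-40.0, 40.0),
        (-25.0, 25.0),
    )
    specimen_sd: float = 0.1
    scan_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_step <= 0 or self.grid_stop <= self.grid_start:
            raise ValueError("degenerate wavenumber grid")
        if any(n < 1 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 1")
        if self.scans_per_specimen < 1:
            raise ValueError("scans_per_specimen must be >= 1")
        if self.scan_sd < 0 or self.specimen_sd < 0:
            raise ValueError("noise levels must be >= 0")

    def grid(self) -> np.ndarray:
        n = int(np.floor((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)

    def resolved_peaks(self) -> list[PeakSpec]:
        return default_peaks() if self.peaks is None else list(self.peaks)


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth retained from generation.

    ``baseline_coeffs`` rows are per-specimen cubic coefficients in the
    normalized abscissa; :meth:`baseline_on` evaluates the true baseline
    of a specimen on any wavenumber subgrid.  ``peak_heights`` holds the
    realized (class effect x jitter x base) height of every band.
    """

    table: pd.DataFrame
    baseline_center: float
    baseline_halfspan: float

    def baseline_on(self, specimen_id: str, grid: np.ndarray) -> np.ndarray:
        row = self.table.set_index("specimen_id").loc[specimen_id]
        coeffs = [row[f"baseline_c{i}"] for i in range(4)]
        t = (np.asarray(grid, float) - self.baseline_center) / self.baseline_halfspan
        return sum(c * t**i for i, c in enumerate(coeffs))


def generate_cohort(cfg: SyntheticConfig) -> tuple[SpectrumSet, CohortTruth]:
    """Generate a labelled cohort; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid()
    peaks = cfg.resolved_peaks()
    center = 0.5 * (grid[0] + grid[-1])
    halfspan = max(0.5 * (grid[-1] - grid[0]), 1e-30)
    t = (grid - center) / halfspan
    # precompute unit-height band shapes (n_peaks x n_grid)
    shapes = np.exp(-((grid[None, :] - np.array([p.center for p in peaks])[:, None]) ** 2)
                    / (2.0 * np.array([p.width for p in peaks])[:, None] ** 2))

    rows, sids, scans, meta_rows, truth_rows = [], [], [], [], []
    for class_label, n in cfg.n_per_class.items():
        tag = "".join(ch for ch in class_label.upper() if ch.isalnum())[:6]
        for k in range(n):
            sid = f"{tag}-{k + 1:03d}"
            coeffs = np.array([rng.uniform(lo, hi) for lo, hi in cfg.baseline_ranges])
            baseline = np.polynomial.polynomial.polyval(t, coeffs)
            jitter = rng.lognormal(mean=0.0, sigma=cfg.specimen_sd, size=len(peaks)) \
                if cfg.specimen_sd > 0 else np.ones(len(peaks))
            heights = np.array(
                [p.base_height * p.factor(class_label) * j for p, j in zip(peaks, jitter)]
            )
            clean = baseline + heights @ shapes
            for scan in range(cfg.scans_per_specimen):
                noise = rng.normal(0.0, cfg.scan_sd, size=len(grid)) if cfg.scan_sd > 0 else 0.0
                rows.append(clean + noise)
                sids.append(sid)
                scans.append(scan)
            meta_rows.append({"specimen_id": sid, "class_label": class_label, "dataset": "synthetic"})
            truth = {"specimen_id": sid, "class_label": class_label}
            truth.update({f"baseline_c{i}": c for i, c in enumerate(coeffs)})
            truth.update({f"height_{p.center:g}": h for p, h in zip(peaks, heights)})
            truth_rows.append(truth)

    metadata = pd.DataFrame(meta_rows).set_index("specimen_id")
    sset = SpectrumSet(grid, np.vstack(rows), sids, scans, metadata)
    return sset, CohortTruth(pd.DataFrame(truth_rows), center, halfspan)


def null_cohort(cfg: SyntheticConfig) -> SpectrumSet:
    """Cohort with every class-effect factor forced to 1; labels retained.

    Class labels then carry no spectral information, so any downstream
    classifier should perform at chance.
    """
    peaks = [replace(p, class_effect={}) for p in cfg.resolved_peaks()]
    sset, _ = generate_cohort(replace(cfg, peaks=peaks))
    return sset
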