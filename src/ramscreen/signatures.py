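"""Raman-shift contributions and molecular band assignment.

A fitted PCA/DAPC model weighs every wavenumber; expressing each weight as
a percent of the component's total absolute weight identifies the Raman
shifts that drive class separation (the "molecular signature").  Shifts
surpassing a contribution threshold (0.3% by default) are annotated from a
band-assignment table of biological Raman bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import DAPCModel

__all__ = [
    "BandAssignment",
    "DEFAULT_BAND_TABLE",
    "DEFAULT_CONTRIBUTION_THRESHOLD",
    "shift_contributions",
    "assign_bands",
    "load_band_table",
]

DEFAULT_CONTRIBUTION_THRESHOLD = 0.3  # percent


@dataclass(frozen=True)
class BandAssignment:
    wavenumber: float
    molecule_class: str
    tolerance: float = 5.0


# urine-relevant biological Raman bands (cm^-1); a band may map to more
# than one molecule class (e.g. 1340 is both nucleic acid and collagen)
DEFAULT_BAND_TABLE: list[BandAssignment] = [
    BandAssignment(576.0, "phosphatidylinositol"),
    BandAssignment(721.0, "nucleic acids"),
    BandAssignment(827.0, "nucleic acids"),
    BandAssignment(1340.0, "nucleic acids"),
    BandAssignment(817.0, "protein (collagen)"),
    BandAssignment(981.0, "protein (collagen)"),
    BandAssignment(1065.0, "protein (collagen)"),
    BandAssignment(1127.0, "protein (collagen)"),
    BandAssignment(1340.0, "protein (collagen)"),
    BandAssignment(827.0, "aromatic amino acids"),
    BandAssignment(1004.0, "aromatic amino acids"),
    BandAssignment(702.0, "cholesterol and fatty acids"),
    BandAssignment(1297.0, "cholesterol and fatty acids"),
    BandAssignment(846.0, "monosaccharides"),
    BandAssignment(1048.0, "glycogen"),
    BandAssignment(1417.0, "carotenoids"),
    BandAssignment(1518.0, "carotenoids"),
]


def shift_contributions(
    model: DAPCModel,
    space: str = "dapc",
    n_components: int | None = None,
    threshold: float = DEFAULT_CONTRIBUTION_THRESHOLD,
) -> pd.DataFrame:
    """Percent contribution of each wavenumber to each model component.

    space='pca' uses the PC loadings directly; space='dapc' composes the
    loadings with the canonical coefficients, giving each canonical axis as
    a direction in wavenumber space.  Per component, contributions are
    |weight| / sum|weight| x 100 (they sum to 100); ``above_threshold``
    flags shifts surpassing ``threshold`` percent.

    Returns a long DataFrame with columns (space, component, wavenumber,
    contribution, above_threshold).
    """
    if space == "pca":
        directions = model.pca.loadings
        avail = directions.shape[1]
    elif space == "dapc":
        directions = model.pca.loadings @ model.canonical_coefficients
        avail = directions.shape[1]
    else:
        raise ValueError(f"unknown space {space!r}")
    n_components = avail if n_components is None else int(n_components)
    if n_components > avail:
        raise ValueError(f"requested {n_components} components, model holds {avail}")

    frames = []
    for j in range(n_components):
        w = np.abs(directions[:, j])
        total = w.sum()
        if total == 0:
            raise ValueError(f"component {j + 1} has zero total weight")
        contrib = 100.0 * w / total
        frames.append(
            pd.DataFrame(
                {
                    "space": space,
                    "component": j + 1,
                    "wavenumber": model.pca.grid,
                    "contribution": contrib,
                    "above_threshold": contrib > threshold,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def assign_bands(
    profile: pd.DataFrame,
    table: list[BandAssignment] | None = None,
) -> pd.DataFrame:
    """Annotate above-threshold shifts with molecule classes.

    Each above-threshold wavenumber is matched against every table entry
    within that entry's tolerance (default +/-5 cm^-1); all matches are
    joined with '; ', unmatched shifts get 'unassigned'.  Below-threshold
    rows get an empty assignment.
    """
    table = DEFAULT_BAND_TABLE if table is None else table
    if not table:
        raise ValueError("band table is empty")

    def lookup(w: float) -> str:
        hits = [b.molecule_class for b in table if abs(w - b.wavenumber) <= b.tolerance]
        seen: list[str] = []
        for h in hits:
            if h not in seen:
                seen.append(h)
        return "; ".join(seen) if seen else "unassigned"

    out = profile.copy()
    out["assignment"] = [
        lookup(w) if above else ""
        for w, above in zip(out["wavenumber"], out["above_threshold"])
    ]
    return out


def load_band_table(path: str | Path) -> list[BandAssignment]:
    """Read a band table CSV with columns wavenumber, molecule_class[, tolerance]."""
    df = pd.read_csv(path)
    tol = df["tolerance"] if "tolerance" in df.columns else pd.Series(5.0, index=df.index)
    rows = [
        BandAssignment(float(w), str(m), float(t))
        for w, m, t in zip(df["wavenumber"], df["molecule_class"], tol)
    ]
    if len({(b.wavenumber, b.molecule_class) for b in rows}) != len(rows):
        raise ValueError("duplicate (wavenumber, molecule_class) entries in band table")
    return rows
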