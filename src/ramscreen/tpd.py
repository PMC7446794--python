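"""Total Principal Component Distance (TPD) and group statistics.

TPD condenses each spectrum into one scalar: the distance between its top
four PC scores and those of a reference spectrum (by default the Surine
synthetic-urine control; in stability studies, the time-zero measurement).
Two variants are exposed because the distance can be read either as a sum
of per-component absolute deviations or as a sum of squared deviations:

    abs_sum : TPD_u = sum_{i=1..4} |P_u,i - P_ref,i|
    sq_sum  : TPD_u = sum_{i=1..4} (P_u,i - P_ref,i)^2

Group differences in TPD are tested with one-way ANOVA and Tukey HSD
pairwise comparisons, both on full-precision values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .chemometrics import PCAModel, project_matrix
from .spectra import SpectrumSet

__all__ = ["TPDResult", "PairwiseComparison", "compute_tpd", "anova_tpd", "tukey_pairwise"]

N_PCS_TPD = 4


@dataclass(frozen=True)
class TPDResult:
    """Per-spectrum TPD values with their provenance.

    ``table`` has columns specimen_id, scan_index, tpd.
    """

    table: pd.DataFrame
    reference_id: str
    n_pcs_used: int
    variant: str


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_difference: float
    p_value: float


def compute_tpd(
    pca: PCAModel,
    sset: SpectrumSet,
    reference_id: str,
    variant: str = "abs_sum",
) -> TPDResult:
    """TPD of every spectrum in ``sset`` against a reference specimen.

    The set should be unaveraged (one row per scan); the reference score
    vector is the mean over the reference specimen's scans.  Requires a
    PCA with at least four components.
    """
    if variant not in ("abs_sum", "sq_sum"):
        raise ValueError(f"unknown TPD variant {variant!r}")
    if pca.n_components < N_PCS_TPD:
        raise ValueError(f"TPD needs {N_PCS_TPD} PCs, model holds {pca.n_components}")
    scores = project_matrix(pca, sset.matrix, N_PCS_TPD)
    ref_rows = [i for i, sid in enumerate(sset.specimen_ids) if sid == reference_id]
    if not ref_rows:
        raise ValueError(f"reference specimen {reference_id!r} not present in the set")
    ref = scores[ref_rows].mean(axis=0)
    dev = scores - ref
    tpd = np.abs(dev).sum(axis=1) if variant == "abs_sum" else (dev**2).sum(axis=1)
    table = pd.DataFrame(
        {"specimen_id": sset.specimen_ids, "scan_index": sset.scan_indices, "tpd": tpd}
    )
    return TPDResult(table, reference_id, N_PCS_TPD, variant)


def _grouped_values(result: TPDResult, groups: np.ndarray) -> dict[str, np.ndarray]:
    groups = np.asarray(groups, dtype=object)
    if len(groups) != len(result.table):
        raise ValueError("one group label per TPD value required")
    out = {}
    for g in sorted(set(groups.tolist())):
        vals = result.table["tpd"].to_numpy()[groups == g]
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        out[g] = vals
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def anova_tpd(result: TPDResult, groups: np.ndarray) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of TPD values across groups: (F, p)."""
    by_group = _grouped_values(result, groups)
    f, p = scipy.stats.f_oneway(*by_group.values())
    # identical group means give F = 0 exactly; f_oneway may return nan
    # when the within-group variance is also zero
    if not np.isfinite(f):
        f, p = 0.0, 1.0
    return float(f), float(p)


def tukey_pairwise(result: TPDResult, groups: np.ndarray) -> list[PairwiseComparison]:
    """Tukey HSD comparisons of TPD between all group pairs.

    p-values come from the studentized-range distribution and control the
    family-wise error rate; mean_difference is mean(b) - mean(a).
    """
    by_group = _grouped_values(result, groups)
    names = list(by_group)
    res = scipy.stats.tukey_hsd(*by_group.values())
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out.append(
                PairwiseComparison(
                    group_a=names[i],
                    group_b=names[j],
                    mean_difference=float(by_group[names[j]].mean() - by_group[names[i]].mean()),
                    p_value=float(res.pvalue[i, j]),
                )
            )
    return out
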