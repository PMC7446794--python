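"""Leave-one-out screening evaluation and confusion-matrix metrics.

Each specimen is held out once, the PCA+DAPC model is refit on the
remainder, and the held-out spectrum is classified as an unknown.  Tallied
against the gold-standard labels this yields the five screening metrics
(accuracy, sensitivity, specificity, PPV, NPV), reported as percentages.

Control specimens (e.g. the Surine synthetic-urine standard) take part in
model fitting as their own class but are excluded from the binary
confusion counts; all non-positive, non-control classes pool as negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chemometrics import fit_dapc, fit_pca, classify
from .spectra import RamanSpectrum, SpectrumSet

__all__ = [
    "ConfusionCounts",
    "ScreenMetrics",
    "metrics_from_confusion",
    "leave_one_out",
    "sweep_pc_counts",
    "find_confusion_matrix",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ScreenMetrics:
    """The five screening percentages; NaN marks an undefined ratio.

    ``rounded()`` gives the 1-decimal reporting form; the stored fields
    keep full precision for internal comparisons.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_pcs: int | None = None
    variance_explained: float | None = None

    def rounded(self) -> dict[str, float]:
        return {
            k: (round(getattr(self, k), 1) if math.isfinite(getattr(self, k)) else float("nan"))
            for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv")
        }


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def metrics_from_confusion(c: ConfusionCounts, n_pcs: int | None = None,
                           variance_explained: float | None = None) -> ScreenMetrics:
    """Compute accuracy, sensitivity, specificity, PPV and NPV (percent).

    A zero denominator yields NaN for that metric, never 0.
    """
    return ScreenMetrics(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        n_pcs=n_pcs,
        variance_explained=variance_explained,
    )


def find_confusion_matrix(
    n_positive: int,
    n_negative: int,
    accuracy: float,
    sensitivity: float,
    specificity: float,
    ppv: float,
    npv: float,
) -> list[ConfusionCounts]:
    """Exhaustively enumerate integer confusion matrices matching printed metrics.

    Searches all (tp, tn) with the given class totals and returns those whose
    five metrics reproduce the given 1-decimal percentages after rounding.
    Useful for reconstructing the counts behind published screening tables.
    """
    want = (accuracy, sensitivity, specificity, ppv, npv)
    hits = []
    for tp in range(n_positive + 1):
        for tn in range(n_negative + 1):
            c = ConfusionCounts(tp=tp, fp=n_negative - tn, fn=n_positive - tp, tn=tn)
            m = metrics_from_confusion(c).rounded()
            got = (m["accuracy"], m["sensitivity"], m["specificity"], m["ppv"], m["npv"])
            if all(math.isfinite(g) and abs(g - w) < 1e-9 for g, w in zip(got, want)):
                hits.append(c)
    return hits


def _binary_outcome(gold: str, predicted: str, positive_class: str) -> tuple[bool, bool]:
    return gold == positive_class, predicted == positive_class


def leave_one_out(
    sset: SpectrumSet,
    n_pcs: int,
    positive_class: str,
    control_classes: Sequence[str] = (),
    label_column: str = "class_label",
) -> tuple[pd.DataFrame, ConfusionCounts]:
    """Hold out each specimen, refit PCA+DAPC on the rest, classify it.

    The input must be averaged to one row per specimen.  Control-class
    specimens are classified (the model knows their class) but excluded
    from the confusion counts; every other non-positive class counts as
    negative.  Returns a per-specimen prediction table and the counts.
    """
    if len(set(sset.specimen_ids)) != sset.n_rows:
        raise ValueError("leave_one_out expects one (averaged) spectrum per specimen")
    k = sset.n_rows
    if n_pcs >= k - 1:
        raise ValueError(f"n_pcs={n_pcs} would be degenerate in folds of {k - 1} spectra")
    labels = sset.labels(label_column)
    reference_order = _screening_reference_order(labels, positive_class, control_classes)

    rows = []
    tp = fp = fn = tn = 0
    for i in range(k):
        keep = np.ones(k, dtype=bool)
        keep[i] = False
        # a fold may leave a class with a single member (e.g. one of two
        # control specimens held out); such classes cannot contribute a
        # within-class scatter and are dropped from that fold's training
        fold_labels = labels[keep]
        viable = {c for c in set(fold_labels) if (fold_labels == c).sum() >= 2}
        keep &= np.array([lab in viable for lab in labels])
        train = sset.subset_rows(keep)
        model = fit_dapc(train, n_pcs, label_column, reference_order)
        held = RamanSpectrum(sset.grid, sset.matrix[i], sset.specimen_ids[i], sset.scan_indices[i])
        predicted, _ = classify(model, held)
        gold = labels[i]
        rows.append({"specimen_id": sset.specimen_ids[i], "gold": gold, "predicted": predicted})
        if gold in control_classes:
            continue
        gold_pos, pred_pos = _binary_outcome(gold, predicted, positive_class)
        if gold_pos and pred_pos:
            tp += 1
        elif gold_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    return pd.DataFrame(rows), ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _screening_reference_order(
    labels: np.ndarray, positive_class: str, control_classes: Sequence[str]
) -> list[str]:
    # ties break toward negative (non-positive, non-control) classes first,
    # then controls, then the positive class: the screen fails toward
    # gold-standard follow-up rather than toward a positive call
    classes = sorted(set(labels.tolist()))
    negatives = [c for c in classes if c != positive_class and c not in control_classes]
    controls = [c for c in classes if c in control_classes]
    return negatives + controls + [positive_class]


def sweep_pc_counts(
    sset: SpectrumSet,
    n_pcs_values: Sequence[int],
    positive_class: str,
    control_classes: Sequence[str] = (),
    label_column: str = "class_label",
) -> pd.DataFrame:
    """Leave-one-out metrics for each model size in ``n_pcs_values``.

    ``variance_explained`` is the cumulative percent variance of the top
    n_pcs components from the full-data PCA.
    """
    n_pcs_values = sorted(set(int(v) for v in n_pcs_values))
    full_pca = fit_pca(sset)
    cum = np.cumsum(full_pca.explained_variance_fraction) * 100.0
    records = []
    for n_pcs in n_pcs_values:
        _, counts = leave_one_out(sset, n_pcs, positive_class, control_classes, label_column)
        m = metrics_from_confusion(counts, n_pcs=n_pcs, variance_explained=float(cum[n_pcs - 1]))
        records.append(
            {
                "n_pcs": n_pcs,
                "variance_explained": m.variance_explained,
                **m.rounded(),
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "tn": counts.tn,
            }
        )
    return pd.DataFrame(records)
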