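"""Accuracy assessment: stratified point sampling, confusion matrix, kappa.

The automated class map is compared with a reference (manually corrected)
map by sampling up to 100 random points per class present in the
reference, tallying a classified-vs-truth confusion matrix, and deriving
overall, producer's (column-wise recall) and user's (row-wise precision)
accuracies, commission/omission errors, and Cohen's chance-corrected
kappa. Classes can be collapsed (e.g. both ice classes into "ice") to
assess coarser distinctions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "accuracy_metrics",
    "cohens_kappa",
    "collapse_classes",
    "confusion_matrix",
    "sample_points",
    "write_confusion_csv",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Classified (rows) x truth (columns) counts with class names."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError("counts must be square and match class names")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def rate(self, classified: str, truth: str) -> float:
        """Fraction of truth-class pixels assigned to a classified class."""
        i = self.classes.index(classified)
        j = self.classes.index(truth)
        col = self.col_totals()[j]
        return self.counts[i, j] / col if col else float("nan")


def sample_points(
    auto,
    truth,
    n_per_class: int = 100,
    seed: int = 0,
    class_names: dict[int, str] | None = None,
    stratify_by: str = "truth",
) -> list[tuple[tuple[int, int], str, str]]:
    """Sample stratified random points from an automated/reference map pair.

    For each class present in the stratifying map (the reference by
    default), up to ``n_per_class`` pixels are drawn uniformly without
    replacement, seeded. Classes absent from the map are simply not
    sampled. Returns ``[(position, auto_class, truth_class), ...]``.
    """
    from icehab.classify import CLASS_NAMES, EXCLUDED

    auto_labels = np.asarray(getattr(auto, "labels", auto))
    truth_labels = np.asarray(getattr(truth, "labels", truth))
    if auto_labels.shape != truth_labels.shape:
        raise ValueError("maps must share one shape")
    if class_names is None:
        class_names = CLASS_NAMES
    if stratify_by not in ("truth", "auto"):
        raise ValueError("stratify_by must be 'truth' or 'auto'")
    strata = truth_labels if stratify_by == "truth" else auto_labels

    rng = np.random.default_rng(seed)
    samples = []
    for cls in sorted(class_names):
        if cls == EXCLUDED:
            continue
        rows, cols = np.nonzero(strata == cls)
        if rows.size == 0:
            continue
        take = min(n_per_class, rows.size)
        pick = rng.choice(rows.size, size=take, replace=False)
        for k in pick:
            r, c = int(rows[k]), int(cols[k])
            samples.append(
                ((r, c), class_names[auto_labels[r, c]], class_names[truth_labels[r, c]])
            )
    return samples


def confusion_matrix(samples, classes: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """Tally samples into a classified-by-truth confusion matrix."""
    if not samples:
        raise ValueError("need >= 1 sample")
    if classes is None:
        seen = []
        for _, a, t in samples:
            for name in (a, t):
                if name not in seen:
                    seen.append(name)
        classes = tuple(seen)
    index = {name: i for i, name in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for _, a, t in samples:
        if a not in index or t not in index:
            raise ValueError(f"unknown class label {a!r}/{t!r}")
        counts[index[a], index[t]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def accuracy_metrics(cm: ConfusionMatrix) -> dict:
    """Overall, per-class producer's/user's accuracy and commission/omission.

    Producer's accuracy of a class is the diagonal over the truth-column
    total (1 - omission); user's accuracy is the diagonal over the
    classified-row total (1 - commission). Classes with an empty row or
    column have the corresponding metric absent (None).
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = cm.row_totals()
    cols = cm.col_totals()
    diag = np.diag(counts)
    out = {
        "overall": float(diag.sum() / total),
        "users": {},
        "producers": {},
        "commission": {},
        "omission": {},
    }
    for i, name in enumerate(cm.classes):
        users = float(diag[i] / rows[i]) if rows[i] else None
        producers = float(diag[i] / cols[i]) if cols[i] else None
        out["users"][name] = users
        out["producers"][name] = producers
        out["commission"][name] = None if users is None else 1.0 - users
        out["omission"][name] = None if producers is None else 1.0 - producers
    return out


def cohens_kappa(cm: ConfusionMatrix) -> float | None:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e).

    Returns None when expected agreement is 1 (all mass in one
    row/column pair), where kappa is undefined.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = float(np.diag(cm.counts).sum() / total)
    p_e = float((cm.row_totals() * cm.col_totals()).sum() / total**2)
    if p_e >= 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def collapse_classes(cm: ConfusionMatrix, mapping: dict[str, str]) -> ConfusionMatrix:
    """Merge classes into superclasses, summing counts.

    ``mapping`` must cover every class; the grand total is preserved.
    """
    missing = [c for c in cm.classes if c not in mapping]
    if missing:
        raise ValueError(f"mapping must cover every class; missing {missing}")
    new_classes = []
    for c in cm.classes:
        if mapping[c] not in new_classes:
            new_classes.append(mapping[c])
    index = {name: i for i, name in enumerate(new_classes)}
    k = len(new_classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for i, ci in enumerate(cm.classes):
        for j, cj in enumerate(cm.classes):
            counts[index[mapping[ci]], index[mapping[cj]]] += cm.counts[i, j]
    return ConfusionMatrix(counts=counts, classes=tuple(new_classes))


def write_confusion_csv(cm: ConfusionMatrix, path: str | Path) -> Path:
    """Write the confusion matrix with totals and metric margins as CSV."""
    path = Path(path)
    metrics = accuracy_metrics(cm)
    df = pd.DataFrame(cm.counts, index=list(cm.classes), columns=list(cm.classes))
    df["total"] = cm.row_totals()
    df["users_accuracy_pct"] = [
        round(100 * u, 1) if u is not None else "" for u in
        (metrics["users"][c] for c in cm.classes)
    ]
    footer_total = pd.Series(cm.col_totals(), index=list(cm.classes))
    footer_total["total"] = cm.total
    footer_prod = pd.Series(
        {
            c: round(100 * metrics["producers"][c], 1)
            if metrics["producers"][c] is not None
            else ""
            for c in cm.classes
        }
    )
    footer_prod["users_accuracy_pct"] = round(100 * metrics["overall"], 1)
    df.loc["total"] = footer_total
    df.loc["producers_accuracy_pct"] = footer_prod
    df.index.name = "classified"
    df.to_csv(path)
    return path
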