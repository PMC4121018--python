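"""Confusion matrices, tissue-wise accuracies and Cohen's kappa.

Rows of the 3x3 matrix are the expert (true) tissue classes in the order
granulation, slough, necrotic; columns are the classifier's predictions.
Per-class accuracy is the row-normalized diagonal; the headline overall
accuracy is the macro mean of per-class accuracies (the micro/pooled rate
is reported alongside).  Cohen's kappa corrects the pooled agreement for
chance: kappa = (p_o - p_e) / (1 - p_e) with p_e from the row/column
marginals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import LABELS


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (k, k) non-negative ints, rows = true class
    labels: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.labels):
            raise ValueError(f"expected a {len(self.labels)}x{len(self.labels)} matrix")
        if (c < 0).any():
            raise ValueError("negative counts")
        if c.sum() == 0:
            raise ValueError("empty confusion matrix")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true_labels, predicted_labels, labels: tuple[str, ...] = LABELS) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a matrix in the fixed label order."""
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p) or len(t) == 0:
        raise ValueError("label lists must be equal-length and non-empty")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for ti, pi in zip(t, p):
        if ti not in index or pi not in index:
            raise ValueError(f"unknown label in pair ({ti!r}, {pi!r})")
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(counts, labels)


def accuracies(cm: ConfusionMatrix) -> tuple[dict[str, float], float, float]:
    """(per-class %, macro %, micro %) from a confusion matrix.

    Per-class = 100 * diagonal / row total.  A class with an empty row is
    reported as NaN and excluded from the macro mean, with a warning.
    """
    counts = cm.counts.astype(np.float64)
    row_totals = counts.sum(axis=1)
    per_class: dict[str, float] = {}
    defined = []
    for i, lab in enumerate(cm.labels):
        if row_totals[i] == 0:
            warnings.warn(f"class {lab!r} has no true samples; accuracy undefined", stacklevel=2)
            per_class[lab] = float("nan")
        else:
            acc = 100.0 * counts[i, i] / row_totals[i]
            per_class[lab] = acc
            defined.append(acc)
    macro = float(np.mean(defined))
    micro = float(100.0 * np.trace(counts) / counts.sum())
    return per_class, macro, micro


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between expert and classifier labelings."""
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / total**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _round2(x: float) -> float:
    return float(np.round(x, 2))  # round-half-even, 2 decimals


@dataclass
class EvaluationReport:
    matrix: ConfusionMatrix
    per_class: dict[str, float] = field(init=False)
    macro_accuracy: float = field(init=False)
    micro_accuracy: float = field(init=False)
    kappa: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_class, self.macro_accuracy, self.micro_accuracy = accuracies(self.matrix)
        self.kappa = cohens_kappa(self.matrix)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.matrix.labels),
            "matrix": self.matrix.counts.tolist(),
            "per_class_accuracy_pct": {k: _round2(v) for k, v in self.per_class.items()},
            "overall_accuracy_macro_pct": _round2(self.macro_accuracy),
            "overall_accuracy_micro_pct": _round2(self.micro_accuracy),
            "cohens_kappa": float(np.round(self.kappa, 3)),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def write_matrix_csv(self, path: str | Path) -> None:
        lines = ["true\\pred," + ",".join(self.matrix.labels)]
        for lab, row in zip(self.matrix.labels, self.matrix.counts):
            lines.append(lab + "," + ",".join(str(int(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def evaluate(true_labels, predicted_labels) -> EvaluationReport:
    return EvaluationReport(confusion(true_labels, predicted_labels))
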