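"""Univariate feature screening with the one-way ANOVA F statistic.

Each of the 675 descriptor columns is scored by the ratio of
between-tissue-class to within-class mean squares; columns whose F exceeds
a threshold (default 21, i.e. far out in the F tail for hundreds of
regions, roughly p < 0.001) are retained for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .features import LABELS, META_COLUMNS, feature_names

DEFAULT_F_THRESHOLD = 21.0


@dataclass
class SelectionResult:
    f_values: pd.Series         # per feature column
    p_values: pd.Series
    threshold: float
    retained: list[str] = field(default_factory=list)

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.f_values.index,
                "F": self.f_values.values,
                "p": self.p_values.values,
                "retained": [f in set(self.retained) for f in self.f_values.index],
            }
        )

    def write_report(self, path: str | Path) -> None:
        self.report().to_csv(Path(path), index=False)


def _check_table(table: pd.DataFrame) -> tuple[np.ndarray, list[np.ndarray], list[str]]:
    cols = [c for c in table.columns if c not in META_COLUMNS]
    labels = table["label"].to_numpy()
    classes = [c for c in LABELS if (labels == c).sum() > 0]
    if len(classes) < 2:
        raise ValueError("feature selection needs at least 2 tissue classes")
    groups = []
    for c in classes:
        idx = labels == c
        if idx.sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
        groups.append(idx)
    return labels, groups, cols


def anova_f(table: pd.DataFrame, threshold: float = DEFAULT_F_THRESHOLD) -> SelectionResult:
    """Score every feature column with the classic one-way F and screen.

    F = MSB / MSW with (k - 1, N - k) degrees of freedom.  Conventions for
    degenerate columns: both mean squares zero -> F = 0; zero within-class
    variance with nonzero between -> F = +inf (a perfectly separating
    feature, always retained).  Retained set = {F > threshold}.
    """
    labels, groups, cols = _check_table(table)
    x = table[cols].to_numpy(dtype=np.float64)
    n = x.shape[0]
    k = len(groups)

    grand = x.mean(axis=0)
    ssb = np.zeros(x.shape[1])
    ssw = np.zeros(x.shape[1])
    for idx in groups:
        gx = x[idx]
        gm = gx.mean(axis=0)
        ssb += idx.sum() * (gm - grand) ** 2
        ssw += ((gx - gm) ** 2).sum(axis=0)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)

    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f = np.where(msw == 0, np.where(msb == 0, 0.0, np.inf), f)
    p = stats.f.sf(f, k - 1, n - k)
    p = np.where(np.isinf(f), 0.0, p)

    fs = pd.Series(f, index=cols)
    ps = pd.Series(p, index=cols)
    retained = [c for c in cols if fs[c] > threshold]
    return SelectionResult(f_values=fs, p_values=ps, threshold=threshold, retained=retained)
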