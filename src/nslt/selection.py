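"""Feature normalization and one-way ANOVA feature selection.

Each feature column is z-scored (population SD, so a standardized column
has mean 0 and SD 1 under the 1/n convention; the ANOVA F ratio is
invariant to the choice). Features are then ranked by the one-way ANOVA
F test of class separation and the top-k (or all with p < alpha) kept.
The selected count k is configuration: the study this follows reports
per-scenario counts (e.g. 3 of the run-length features) rather than a
single significance rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ProtocolError, ValidationError

__all__ = ["AnovaResult", "normalize_features", "anova_oneway", "anova_score", "select_features"]


@dataclass(frozen=True)
class AnovaResult:
    """Per-feature F statistics, p-values, rank order and selection mask."""

    table: pd.DataFrame  # columns: feature, F, p, rank, selected

    @property
    def selected(self) -> list[str]:
        t = self.table
        return list(t.loc[t["selected"], "feature"])

    def to_dict(self) -> dict:
        return {
            row.feature: {"F": row.F, "p": row.p, "rank": int(row.rank),
                          "selected": bool(row.selected)}
            for row in self.table.itertuples()
        }


def _split_table(table: pd.DataFrame):
    if "label" not in table.columns:
        raise ValidationError("table must carry a 'label' column")
    X = table.drop(columns="label")
    y = table["label"]
    return X, y


def normalize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every feature column; constant columns become all-zero and
    are flagged in ``result.attrs['constant_columns']``."""
    X, y = _split_table(table)
    if len(table) < 2:
        raise ValidationError("need at least 2 rows to normalize")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = list(X.columns[sd == 0])
    sd = sd.replace(0.0, 1.0)
    Z = (X - mu) / sd
    Z[constant] = 0.0
    out = Z.copy()
    out["label"] = y.to_numpy()
    out.attrs["constant_columns"] = constant
    return out


def anova_oneway(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MS_between / MS_within with
    df (k-1, n-k); p from the upper tail of the F distribution.

    Zero within-class variance with unequal group means yields
    ``(inf, 0.0)``; each group must have at least 2 members.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ProtocolError("ANOVA needs at least two groups")
    parts = [x[g == lab] for lab in labels]
    if any(len(p) < 2 for p in parts):
        raise ValidationError("each group needs >= 2 members")
    n, k = len(x), len(labels)
    grand = x.mean()
    ssb = sum(len(p) * (p.mean() - grand) ** 2 for p in parts)
    ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
    dfb, dfw = k - 1, n - k
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(F, dfb, dfw))
    return float(F), p


def anova_score(X, y):
    """Per-column (F, p) arrays; usable as an sklearn ``score_func``."""
    X = np.asarray(X, dtype=float)
    out = [anova_oneway(X[:, j], y) for j in range(X.shape[1])]
    F, p = zip(*out)
    return np.asarray(F), np.asarray(p)


def select_features(
    table: pd.DataFrame,
    k: int | None = None,
    alpha: float | None = None,
) -> tuple[pd.DataFrame, AnovaResult]:
    """Keep the top-k features by ascending ANOVA p (or all with p < alpha).

    Ties break deterministically by original column order; selection is
    invariant to row permutation of the table.
    """
    if (k is None) == (alpha is None):
        raise ValidationError("provide exactly one of k or alpha")
    X, y = _split_table(table)
    n_feat = X.shape[1]
    if k is not None and not (1 <= k <= n_feat):
        raise ValidationError(f"k must be in 1..{n_feat}, got {k}")
    F, p = anova_score(X.to_numpy(), y.to_numpy())
    order = np.lexsort((np.arange(n_feat), p))  # stable: p, then column order
    rank = np.empty(n_feat, dtype=int)
    rank[order] = np.arange(1, n_feat + 1)
    if k is not None:
        selected_mask = rank <= k
    else:
        selected_mask = p < alpha
        if not selected_mask.any():
            raise ValidationError(f"no feature reaches alpha={alpha}: empty selection")
    report = AnovaResult(pd.DataFrame({
        "feature": X.columns, "F": F, "p": p, "rank": rank, "selected": selected_mask,
    }))
    keep = [X.columns[idx] for idx in order if selected_mask[idx]]
    out = table[keep + ["label"]].copy()
    return out, report
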