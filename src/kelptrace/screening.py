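"""Per-feature one-way ANOVA and Duncan's multiple range test.

Each VOC feature is screened across the three origin groups with a classical
fixed-effects one-way ANOVA; features with p < alpha (strict, no
multiple-testing correction — mirroring per-feature reporting practice in
GC-IMS origin studies) are retained for modeling.  Duncan's multiple range
test assigns the familiar superscript letters: ranked group means whose span
falls below the least significant range

    R_p = q(1 - (1 - alpha)^(p-1); p, df_within) * sqrt(MSE / n_h)

share a letter, where q is the studentized-range quantile, p the number of
means spanned, and n_h the harmonic mean group size.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .cohort import SampleMatrix

__all__ = ["AnovaResult", "ScreenReport", "oneway_anova", "duncan_letters",
           "screen_features", "AnovaDuncanSelector"]


@dataclass(frozen=True)
class AnovaResult:
    feature_id: str
    f_stat: float
    p_value: float
    group_means: tuple[float, ...]
    mse: float
    df_within: int
    duncan_letters: tuple[str, ...]


@dataclass
class ScreenReport:
    results: list[AnovaResult]
    selected_ids: list[str]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rec = {"feature_id": r.feature_id, "F": r.f_stat, "p": r.p_value,
                   "mse": r.mse, "df_within": r.df_within,
                   "selected": r.feature_id in set(self.selected_ids)}
            for g, (m, letter) in enumerate(zip(r.group_means,
                                                r.duncan_letters)):
                rec[f"mean_{g}"] = m
                rec[f"letter_{g}"] = letter
            rows.append(rec)
        return pd.DataFrame(rows)

    def write(self, table_path: str | Path, summary_path: str | Path) -> None:
        self.to_frame().to_csv(table_path, sep="\t", index=False,
                               float_format="%.17g")
        with open(summary_path, "w", encoding="utf-8") as fh:
            json.dump({"alpha": self.alpha,
                       "n_selected": len(self.selected_ids),
                       "selected_ids": self.selected_ids}, fh, indent=1)


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.ndim != 1 or len(g) < 2:
            raise ValueError("each group needs at least two values")
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite values in group")
        out.append(g)
    return out


def oneway_anova(*groups: np.ndarray) -> tuple[float, float, float, int]:
    """Classical fixed-effects one-way ANOVA.

    Returns (F, p, MSE, df_within).  Degenerate cases: zero within-group
    variance with non-zero between-group variance gives F = inf, p = 0; all
    values identical gives F = 0, p = 1.
    """
    groups = _check_groups(list(groups))
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between, df_within = k - 1, n - k
    msb = ss_between / df_between
    mse = ss_within / df_within
    if mse == 0.0:
        if msb == 0.0:
            return 0.0, 1.0, 0.0, df_within
        return float("inf"), 0.0, 0.0, df_within
    f = msb / mse
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p, float(mse), df_within


@lru_cache(maxsize=1024)
def _sr_quantile(level: float, span: int, df: int) -> float:
    """Upper studentized-range quantile (cached: ppf is expensive)."""
    return float(stats.studentized_range.ppf(1.0 - level, span, df))


def duncan_letters(
    group_means: np.ndarray,
    group_sizes: np.ndarray,
    mse: float,
    df_within: int,
    alpha: float = 0.05,
) -> list[str]:
    """Duncan's multiple range test letter display.

    Means are ranked descending; a stretch of p adjacent ranked means is
    declared homogeneous when its span does not exceed the least significant
    range R_p at protection level 1 - (1-alpha)^(p-1).  A range contained in
    a homogeneous stretch is not tested (the standard protection rule).
    Letters run 'a' from the largest mean downward; two groups share a letter
    iff they are not significantly different.
    """
    means = np.asarray(group_means, dtype=float)
    sizes = np.asarray(group_sizes, dtype=float)
    k = len(means)
    if df_within <= 0:
        raise ValueError("df_within must be positive")
    if mse < 0:
        raise ValueError("mse must be >= 0")
    if k == 1:
        return ["a"]

    n_h = k / np.sum(1.0 / sizes)  # harmonic mean group size
    order = np.argsort(-means, kind="stable")
    ranked = means[order]

    def lsr(span: int) -> float:
        if mse == 0.0:
            return 0.0
        level = 1.0 - (1.0 - alpha) ** (span - 1)
        return _sr_quantile(level, span, df_within) * np.sqrt(mse / n_h)

    # homogeneous[i][j]: ranked means i..j are not significantly different
    homogeneous = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(homogeneous, True)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if homogeneous[i, j]:
                continue  # contained in an accepted wider range (protection)
            if (ranked[i] - ranked[j]) <= lsr(span):
                homogeneous[i:j + 1, i:j + 1] = True

    # maximal homogeneous intervals -> letters
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = max(b for b in range(i, k) if homogeneous[i, b])
        if intervals and intervals[-1][1] >= j:
            continue  # contained in the previous interval
        intervals.append((i, j))

    letters_ranked = ["" for _ in range(k)]
    for letter, (i, j) in zip(string.ascii_lowercase, intervals):
        for t in range(i, j + 1):
            letters_ranked[t] += letter
    out = ["" for _ in range(k)]
    for rank_pos, orig_idx in enumerate(order):
        out[orig_idx] = letters_ranked[rank_pos]
    return out


class AnovaDuncanSelector(SelectorMixin, BaseEstimator):
    """Feature selector: keep features whose one-way ANOVA p < alpha.

    Fitting computes, per feature, the F statistic, p-value, within-group
    mean square and Duncan letter display across the label groups.  The
    transform keeps the columns with p strictly below ``alpha``, preserving
    input column order.

    Attributes (after fit)
    ----------------------
    f_statistic_, pvalues_ : ndarray of shape (n_features,)
    mse_ : ndarray, within-group mean squares
    df_within_ : int
    duncan_letters_ : list of per-group letter tuples
    """

    def __init__(self, alpha: float = 0.05, duncan_alpha: float = 0.05):
        self.alpha = alpha
        self.duncan_alpha = duncan_alpha

    def fit(self, X, y):
        if not (0 <= self.alpha <= 1):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need at least two label groups")
        groups = [X[y == c] for c in classes]
        for g in groups:
            if len(g) < 2:
                raise ValueError("each label group needs >= 2 samples")
        self.classes_ = classes
        n_features = X.shape[1]
        self.f_statistic_ = np.empty(n_features)
        self.pvalues_ = np.empty(n_features)
        self.mse_ = np.empty(n_features)
        self.group_means_ = np.empty((len(classes), n_features))
        self.duncan_letters_ = []
        sizes = np.array([len(g) for g in groups])
        for j in range(n_features):
            cols = [g[:, j] for g in groups]
            f, p, mse, dfw = oneway_anova(*cols)
            self.f_statistic_[j] = f
            self.pvalues_[j] = p
            self.mse_[j] = mse
            self.df_within_ = dfw
            means = np.array([c.mean() for c in cols])
            self.group_means_[:, j] = means
            self.duncan_letters_.append(
                tuple(duncan_letters(means, sizes, mse, dfw,
                                     alpha=self.duncan_alpha))
            )
        self.n_features_in_ = n_features
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "pvalues_")
        return self.pvalues_ < self.alpha


def screen_features(
    matrix: SampleMatrix, alpha: float = 0.05
) -> tuple[ScreenReport, SampleMatrix]:
    """Screen a cohort's features; return the report and the reduced cohort.

    Statistics are computed on the full cohort (screening precedes the
    train/test split, following the narrative order of the source study); to
    screen leakage-free instead, pass a training-only SampleMatrix.
    """
    sel = AnovaDuncanSelector(alpha=alpha).fit(matrix.intensities,
                                               matrix.labels)
    results = [
        AnovaResult(
            feature_id=fid,
            f_stat=float(sel.f_statistic_[j]),
            p_value=float(sel.pvalues_[j]),
            group_means=tuple(sel.group_means_[:, j]),
            mse=float(sel.mse_[j]),
            df_within=int(sel.df_within_),
            duncan_letters=sel.duncan_letters_[j],
        )
        for j, fid in enumerate(matrix.feature_ids)
    ]
    mask = sel.get_support()
    selected = [fid for fid, m in zip(matrix.feature_ids, mask) if m]
    report = ScreenReport(results=results, selected_ids=selected, alpha=alpha)
    return report, matrix.subset_features(selected)
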