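"""Group comparison: one-way ANOVA, Tukey-HSD, and compact-letter display.

The "homogeneous groups" lettering familiar from comparative tables works in
three steps: a one-way ANOVA tests for any between-group difference; the
Tukey-HSD (Tukey-Kramer for unbalanced designs) procedure tests every
unordered pair with family-wise error control via the studentized-range
distribution; and an insert-and-absorb pass converts the resulting
significance pattern into letters such that two groups share a letter if and
only if they are *not* significantly different.

Letter assignment follows the input group order, so a table's published
letter pattern is reproducible given its row order.  Every lettering is
audited against the significance matrix before being returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupStatsError",
    "AnovaResult",
    "GroupComparison",
    "one_way_anova",
    "tukey_hsd",
    "compact_letters",
    "compare_groups",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


class GroupStatsError(ValueError):
    """Raised for degenerate group structures."""


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    group_labels: list[str]
    group_means: np.ndarray
    group_ns: np.ndarray


@dataclass
class GroupComparison:
    """ANOVA + Tukey-HSD + compact letters for one grouping of one variable."""

    group_labels: list[str]
    group_means: np.ndarray
    group_ns: np.ndarray
    anova: AnovaResult
    pairwise: pd.DataFrame
    letters: list[str]
    alpha: float = 0.05


def _split_groups(
    values: Sequence[float], groups: Sequence[str]
) -> tuple[list[str], list[np.ndarray]]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise GroupStatsError("values and groups must have equal length")
    labels: list[str] = []
    for g in groups:
        if g not in labels:
            labels.append(g)
    data = [values[groups == g] for g in labels]
    if len(labels) < 2:
        raise GroupStatsError("need at least two groups")
    for lab, arr in zip(labels, data):
        if len(arr) < 2:
            raise GroupStatsError(f"group {lab!r} has fewer than 2 observations")
    return [str(lab) for lab in labels], data


def one_way_anova(values: Sequence[float], groups: Sequence[str]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA (between/within mean squares)."""
    labels, data = _split_groups(values, groups)
    all_vals = np.concatenate(data)
    if np.ptp(all_vals) == 0:
        raise GroupStatsError("zero total variance")
    grand = all_vals.mean()
    ns = np.array([len(d) for d in data])
    means = np.array([d.mean() for d in data])
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((d - m) ** 2) for d, m in zip(data, means)))
    df_b = len(data) - 1
    df_w = len(all_vals) - len(data)
    if ssw <= 0:
        raise GroupStatsError("zero within-group variance")
    msb = ssb / df_b
    msw = ssw / df_w
    F = msb / msw
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(
        F=float(F),
        p=min(1.0, p),
        df_between=df_b,
        df_within=df_w,
        ms_within=msw,
        group_labels=labels,
        group_means=means,
        group_ns=ns,
    )


def tukey_hsd(
    values: Sequence[float], groups: Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """All-pairs Tukey-HSD (Tukey-Kramer for unbalanced groups).

    For each unordered pair the studentized-range statistic is

        q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))

    with adjusted p-values from the studentized-range distribution with
    ``k`` groups and the ANOVA within-group degrees of freedom.
    """
    anova = one_way_anova(values, groups)
    k = len(anova.group_labels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = anova.group_ns[i], anova.group_ns[j]
            diff = anova.group_means[i] - anova.group_means[j]
            se = np.sqrt(anova.ms_within / 2.0 * (1.0 / ni + 1.0 / nj))
            if se == 0:
                raise GroupStatsError("zero within-group mean square")
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, anova.df_within))
            p_adj = min(1.0, max(p_adj, 0.0))
            rows.append(
                {
                    "group_i": anova.group_labels[i],
                    "group_j": anova.group_labels[j],
                    "diff": float(diff),
                    "q": float(q),
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return pd.DataFrame(rows)


def compact_letters(
    significant: np.ndarray, labels: Sequence[str] | None = None
) -> list[str]:
    """Compact-letter display from a boolean significant-difference matrix.

    Insert-and-absorb: start with one letter covering all groups; for each
    significantly different pair occurring in a shared letter column, split
    the column into two (each excluding one member of the pair); absorb
    columns contained in another; assign letters in order of each column's
    first group.  Output is deterministic for a given input order, and is
    audited: groups share a letter iff they are not significantly different.
    """
    S = np.asarray(significant, dtype=bool)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise GroupStatsError("significance matrix must be square")
    if not np.array_equal(S, S.T):
        raise GroupStatsError("significance matrix must be symmetric")
    if np.any(np.diag(S)):
        raise GroupStatsError("a group cannot differ from itself")
    k = S.shape[0]
    if labels is None:
        labels = [str(i) for i in range(k)]

    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not S[i, j]:
                continue
            new_cols: list[set[int]] = []
            for col in columns:
                if i in col and j in col:
                    new_cols.append(col - {i})
                    new_cols.append(col - {j})
                else:
                    new_cols.append(col)
            # absorb: drop empties, duplicates, and columns contained in another
            uniq: list[set[int]] = []
            for col in new_cols:
                if col and col not in uniq:
                    uniq.append(col)
            columns = [c for c in uniq if not any(c < o for o in uniq)]

    columns.sort(key=lambda col: min(col))
    if len(columns) > len(_LETTERS):
        raise GroupStatsError("more letter columns than available letters")
    letters = ["" for _ in range(k)]
    for letter, col in zip(_LETTERS, columns):
        for g in col:
            letters[g] += letter
    letters = ["".join(sorted(l)) for l in letters]

    _audit_letters(S, letters)
    return letters


def _audit_letters(S: np.ndarray, letters: list[str]) -> None:
    k = S.shape[0]
    for i in range(k):
        if not letters[i]:
            raise GroupStatsError(f"group {i} received no letter")
        for j in range(i + 1, k):
            share = bool(set(letters[i]) & set(letters[j]))
            if S[i, j] and share:
                raise GroupStatsError(
                    f"letter audit failed: significant pair ({i},{j}) shares a letter"
                )
            if not S[i, j] and not share:
                raise GroupStatsError(
                    f"letter audit failed: non-significant pair ({i},{j}) shares no letter"
                )


def compare_groups(
    values: Sequence[float], groups: Sequence[str], alpha: float = 0.05
) -> GroupComparison:
    """Full group comparison: ANOVA, Tukey-HSD pairs, and homogeneous-group letters."""
    anova = one_way_anova(values, groups)
    pairwise = tukey_hsd(values, groups, alpha=alpha)
    labels = anova.group_labels
    k = len(labels)
    S = np.zeros((k, k), dtype=bool)
    for _, row in pairwise.iterrows():
        i = labels.index(row["group_i"])
        j = labels.index(row["group_j"])
        S[i, j] = S[j, i] = bool(row["significant"])
    letters = compact_letters(S, labels)
    return GroupComparison(
        group_labels=labels,
        group_means=anova.group_means,
        group_ns=anova.group_ns,
        anova=anova,
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
    )
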