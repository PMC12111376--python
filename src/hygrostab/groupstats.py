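"""Group comparisons: one-way ANOVA (between-subjects and repeated-measures),
Tukey HSD at alpha = 0.05, and compact letter displays.

Two designs cover a storage study's comparisons: a between-subjects one-way
ANOVA across humidity conditions at a fixed storage time, and a one-way
repeated-measures ANOVA across storage times within a condition (replicate
trays as subjects).  Post-hoc all-pairs testing uses the Tukey–Kramer
studentized-range statistic

    q_ij = |mean_i - mean_j| / sqrt(MS_error/2 * (1/n_i + 1/n_j)),

with critical values from the studentized-range distribution computed
numerically (no table lookup).  Sphericity corrections are not applied to
the repeated-measures F; the uncorrected degrees of freedom are reported.

Letter displays follow the insert-and-absorb construction and are verified
on every call: two groups share a letter if and only if they are not
significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError

__all__ = [
    "GroupData", "TukeyResult", "oneway_anova", "repeated_measures_anova",
    "tukey_hsd", "compact_letter_display", "tukey_between", "tukey_repeated",
    "read_groups_csv",
]


@dataclass(frozen=True)
class GroupData:
    """Labeled replicate measurements under a between or repeated design.

    For the repeated design the group labels are the time levels and each
    group's array is ordered by subject, so arrays must be equal length
    (balanced) and aligned.
    """

    groups: Mapping[str, np.ndarray]
    design: str = "between"
    subjects: Sequence[str] | None = None

    def __post_init__(self):
        if self.design not in ("between", "repeated"):
            raise DomainError(f"unknown design '{self.design}'")
        conv = {str(k): np.asarray(v, float) for k, v in self.groups.items()}
        object.__setattr__(self, "groups", conv)
        if len(conv) < 2:
            raise DomainError("need >= 2 groups")
        for label, arr in conv.items():
            if arr.ndim != 1 or len(arr) < 2:
                raise DomainError(f"group '{label}' needs >= 2 observations")
        if self.design == "repeated":
            lengths = {len(a) for a in conv.values()}
            if len(lengths) != 1:
                raise DomainError("repeated design must be balanced "
                                  "(equal observations per time level)")

    @property
    def labels(self):
        return list(self.groups)


@dataclass(frozen=True)
class TukeyResult:
    """All-pairs comparisons plus a compact letter display.

    ``pairwise`` rows: (group_i, group_j, mean difference, q statistic,
    p-value, significant at alpha).  Groups sharing any letter are not
    significantly different, and conversely.
    """

    pairwise: list[tuple]
    letters: dict[str, str]
    alpha: float
    q_critical: float


def _ss_partition(data: GroupData):
    values = np.concatenate(list(data.groups.values()))
    grand = values.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in data.groups.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in data.groups.values())
    return ss_between, ss_within, len(values)


def oneway_anova(data: GroupData) -> tuple[float, int, int, float]:
    """Between-subjects one-way ANOVA: returns (F, df1, df2, p)."""
    if data.design != "between":
        raise DomainError("oneway_anova requires a between-subjects design")
    ss_b, ss_w, n = _ss_partition(data)
    k = len(data.groups)
    df1, df2 = k - 1, n - k
    if ss_b == 0.0:
        return 0.0, df1, df2, 1.0
    if ss_w == 0.0:
        return float("inf"), df1, df2, 0.0
    F = (ss_b / df1) / (ss_w / df2)
    return float(F), df1, df2, float(stats.f.sf(F, df1, df2))


def repeated_measures_anova(data: GroupData) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA (subjects crossed with time levels).

    F = MS_time / MS_(subject x time); the subject main effect is
    partitioned out of the error term.  Uncorrected df (no sphericity
    adjustment).
    """
    if data.design != "repeated":
        raise DomainError("repeated_measures_anova requires a repeated design")
    table = np.column_stack(list(data.groups.values()))  # subjects x times
    n_subj, k = table.shape
    grand = table.mean()
    ss_time = n_subj * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_err = ss_total - ss_time - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n_subj - 1)
    if ss_time <= 1e-30:
        return 0.0, df1, df2, 1.0
    if ss_err <= 1e-30:
        return float("inf"), df1, df2, 0.0
    F = (ss_time / df1) / (ss_err / df2)
    return float(F), df1, df2, float(stats.f.sf(F, df1, df2))


def tukey_hsd(means, ns, MS_error: float, df_error: int,
              alpha: float = 0.05, labels=None) -> TukeyResult:
    """Tukey–Kramer HSD on group means given an ANOVA error term."""
    means = np.asarray(means, float)
    ns = np.asarray(ns, int)
    if df_error < 1:
        raise DomainError(f"df_error must be >= 1: {df_error}")
    if MS_error <= 0:
        raise DomainError(f"MS_error must be > 0: {MS_error}")
    k = len(means)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    labels = [str(x) for x in labels]
    q_crit = float(stats.studentized_range.ppf(1 - alpha, k, df_error))
    pairwise = []
    sig = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(MS_error / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_error))
            significant = bool(q > q_crit)
            pairwise.append((labels[i], labels[j], float(diff), float(q), p,
                             significant))
            sig[(labels[i], labels[j])] = significant
            sig[(labels[j], labels[i])] = significant
    order = sorted(labels, key=lambda l: (-means[labels.index(l)], l))
    letters = compact_letter_display(sig, order=order)
    return TukeyResult(pairwise=pairwise, letters=letters, alpha=alpha,
                       q_critical=q_crit)


def compact_letter_display(significance: Mapping[tuple, bool],
                           order: Sequence[str] | None = None) -> dict[str, str]:
    """Letters from a symmetric pairwise significance relation.

    Insert-and-absorb: start with one letter column holding every group; for
    each significant pair split every column containing both; absorb columns
    that become subsets of another.  Letters are assigned in the given order
    (by convention, groups sorted by descending mean).  The result is
    checked exhaustively against the relation before returning.
    """
    labels = sorted({l for pair in significance for l in pair})
    for (a, b), v in significance.items():
        if a == b:
            raise DomainError("significance relation contains a self-pair")
        if significance.get((b, a), v) != v:
            raise DomainError(f"significance relation not symmetric for ({a}, {b})")
    if order is None:
        order = labels
    columns = [set(labels)]
    sig_pairs = sorted({tuple(sorted(p)) for p, v in significance.items() if v})
    for a, b in sig_pairs:
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend([col - {a}, col - {b}])
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another
        columns = [c for c in new_cols
                   if c and not any(c < d for d in new_cols)]
        # dedupe while keeping order
        seen, uniq = [], []
        for c in columns:
            if c not in seen:
                seen.append(c)
                uniq.append(c)
        columns = uniq
    rank = {l: i for i, l in enumerate(order)}
    columns.sort(key=lambda c: min(rank.get(l, len(rank)) for l in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {l: "" for l in labels}
    membership = {l: set() for l in labels}
    for idx, col in enumerate(columns):
        ch = alphabet[idx % 26] * (idx // 26 + 1)
        for l in sorted(col, key=lambda l: rank.get(l, len(rank))):
            letters[l] += ch
            membership[l].add(idx)
    # self-check: share-a-letter <=> not significantly different
    for a, b in {tuple(sorted(p)) for p in significance}:
        shares = bool(membership[a] & membership[b])
        if shares == significance[(a, b)]:
            raise DomainError(
                f"letter display inconsistent for pair ({a}, {b})")
    return letters


def tukey_between(data: GroupData, alpha: float = 0.05) -> TukeyResult:
    """Between-subjects ANOVA error term feeding Tukey HSD."""
    _, _, df2, _ = oneway_anova(data)
    _, ss_w, _ = _ss_partition(data)
    ms_err = ss_w / df2
    means = [a.mean() for a in data.groups.values()]
    ns = [len(a) for a in data.groups.values()]
    return tukey_hsd(means, ns, ms_err, df2, alpha=alpha, labels=data.labels)


def tukey_repeated(data: GroupData, alpha: float = 0.05) -> TukeyResult:
    """Repeated-measures error term (subject x time MS) feeding Tukey HSD."""
    table = np.column_stack(list(data.groups.values()))
    n_subj, k = table.shape
    grand = table.mean()
    ss_time = n_subj * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_err = ((table - grand) ** 2).sum() - ss_time - ss_subj
    df2 = (k - 1) * (n_subj - 1)
    ms_err = ss_err / df2
    means = table.mean(axis=0)
    ns = [n_subj] * k
    return tukey_hsd(means, ns, ms_err, df2, alpha=alpha, labels=data.labels)


def read_groups_csv(path, design: str = "between") -> GroupData:
    """Read tidy group data: columns ``value,group[,subject]``."""
    df = pd.read_csv(path)
    for col in ("value", "group"):
        if col not in df.columns:
            raise DomainError(f"groups CSV missing column '{col}'")
    if design == "repeated" and "subject" in df.columns:
        df = df.sort_values(["group", "subject"])
    groups = {str(g): sub["value"].to_numpy(float)
              for g, sub in df.groupby("group", sort=True)}
    return GroupData(groups=groups, design=design)
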