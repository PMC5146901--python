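"""One-way ANOVA across timepoints and Duncan's multiple range test.

Duncan's procedure compares ranked group means with span-dependent least
significant ranges: for a stretch of p ordered means the critical range
is

    R_p = q(1 - alpha_p; p, df_error) * sqrt(MSE / n_h),
    alpha_p = 1 - (1 - alpha)^(p - 1),

with q the studentized-range quantile at Duncan's protection level and
n_h the harmonic mean group size. Two means differ when their gap
exceeds R_p AND no enclosing stretch has already been declared
homogeneous. The partition is rendered as a compact letter display:
groups sharing a letter are not significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = ["AnovaResult", "LetterGroups", "one_way_anova", "duncan_letters"]


class AnovaResult(NamedTuple):
    f_statistic: float
    p_value: float
    mse: float
    df_error: int


@dataclass
class LetterGroups:
    """Duncan letter display for one gene across timepoints."""

    f_statistic: float
    p_value: float
    letters: dict
    group_means: dict
    alpha: float = 0.05


def _check_groups(groups):
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    for i, a in enumerate(arrs):
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    return arrs


def one_way_anova(groups) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    Returns (F, p, MSE, df_error). With zero within-group variance, F is
    +inf (p = 0) for unequal means and 0 (p = 1) for equal means.
    """
    arrs = _check_groups(groups)
    n_total = sum(a.size for a in arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_between = len(arrs) - 1
    df_error = n_total - len(arrs)
    ms_between = ss_between / df_between
    mse = ss_within / df_error
    if mse == 0.0:
        f = np.inf if ms_between > 0 else 0.0
        p = 0.0 if ms_between > 0 else 1.0
    else:
        f = ms_between / mse
        p = float(stats.f.sf(f, df_between, df_error))
    return AnovaResult(float(f), float(p), float(mse), int(df_error))


def duncan_critical_range(p_span: int, df_error: int, mse: float, n_h: float,
                          alpha: float = 0.05) -> float:
    """Least significant range R_p for a stretch of ``p_span`` ordered means."""
    if p_span < 2:
        raise ValueError("span must be >= 2")
    if mse == 0.0:
        return 0.0
    protection = 1.0 - (1.0 - alpha) ** (p_span - 1)
    q = stats.studentized_range.ppf(1.0 - protection, p_span, df_error)
    return float(q * np.sqrt(mse / n_h))


def duncan_letters(groups, alpha: float = 0.05, labels=None) -> LetterGroups:
    """Duncan's multiple range test with a compact letter display.

    Parameters
    ----------
    groups : sequence of sequences
        Replicate values per group (>= 2 groups of >= 2 values).
    alpha : float
        Nominal per-comparison significance level (Duncan protection
        levels are derived from it per span).
    labels : sequence, optional
        Group labels (e.g. ZT hours); defaults to 0..k-1.

    Returns letter assignments keyed by label; letters are ordered 'a',
    'b', ... by descending group mean, and two groups share a letter iff
    the Duncan procedure does not separate them. Unequal group sizes use
    the harmonic mean n_h.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    if labels is None:
        labels = list(range(k))
    labels = list(labels)
    if len(labels) != k:
        raise ValueError("labels length must match number of groups")

    anova = one_way_anova(arrs)
    means = np.array([a.mean() for a in arrs])
    n_h = k / np.sum([1.0 / a.size for a in arrs])

    order = np.argsort(-means, kind="stable")  # descending
    sorted_means = means[order]

    ranges = {p: duncan_critical_range(p, anova.df_error, anova.mse, n_h, alpha)
              for p in range(2, k + 1)}

    # nonsig[i][j]: ordered positions i..j form a homogeneous stretch.
    # Work spans longest-first so the protection rule (a stretch inside a
    # homogeneous stretch is itself homogeneous) propagates downward.
    nonsig = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(nonsig, True)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            gap = sorted_means[i] - sorted_means[j]
            homogeneous = gap <= ranges[span] and not (
                anova.mse == 0.0 and gap > 0
            )
            if homogeneous or nonsig[i, j]:
                nonsig[i:j + 1, i:j + 1] = True

    # maximal homogeneous intervals -> letters (insert-and-absorb on an
    # interval relation reduces to dropping contained intervals)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        intervals.append((i, j))
    maximal = [
        iv for iv in intervals
        if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv for o in intervals)
    ]
    maximal = sorted(set(maximal))

    letter_by_pos = {pos: "" for pos in range(k)}
    for letter_idx, (i, j) in enumerate(maximal):
        letter = chr(ord("a") + letter_idx)
        for pos in range(i, j + 1):
            letter_by_pos[pos] += letter

    letters = {labels[order[pos]]: letter_by_pos[pos] for pos in range(k)}
    group_means = {labels[i]: float(means[i]) for i in range(k)}
    return LetterGroups(
        f_statistic=anova.f_statistic,
        p_value=anova.p_value,
        letters=letters,
        group_means=group_means,
        alpha=alpha,
    )
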