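"""Rhythm-gated Pearson correlation screening between gene pairs.

Pairs are correlated on their per-timepoint mean profiles (replicates
are distinct animals, so there is no within-sample pairing to exploit).
A pair is retained when |r| exceeds a magnitude cutoff (0.5) and at
least one member shows daily rhythmicity; retained pairs are labelled
moderate (0.5 < |r| < 0.80) or strong (|r| >= 0.80), with the direction
tracked separately from the magnitude category.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationRecord",
    "mean_profile",
    "pearson_r",
    "classify_correlation",
    "correlation_table",
]

STRONG_MIN = 0.80
MODERATE_MIN = 0.5


@dataclass(frozen=True)
class CorrelationRecord:
    gene_a: str
    gene_b: str
    r: float
    direction: str
    strength: str
    gate_passed: bool


def mean_profile(expr: pd.DataFrame, gene: str, timepoints=None) -> np.ndarray:
    """Per-timepoint mean expression of ``gene``, ordered by ZT.

    ``timepoints`` defaults to the design timepoints (all ZTs present in
    the table); a timepoint with no observation for the gene raises an
    error naming it.
    """
    if timepoints is None:
        timepoints = np.sort(expr["zt"].unique())
    sub = expr.loc[expr["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from expression table")
    means = sub.groupby("zt")["value"].mean()
    out = np.empty(len(timepoints))
    for i, t in enumerate(timepoints):
        if t not in means.index:
            raise ValueError(f"gene {gene!r} has no observation at ZT{t:g}")
        out[i] = means[t]
    return out


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance profile")
    return float(stats.pearsonr(x, y).statistic)


def classify_correlation(r: float) -> tuple:
    """Map r to (direction, strength) per the screening categories."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    direction = "positive" if r >= 0 else "negative"
    mag = abs(r)
    if mag >= STRONG_MIN:
        strength = "strong"
    elif mag > MODERATE_MIN:
        strength = "moderate"
    else:
        strength = "none"
    return direction, strength


def correlation_table(
    expr: pd.DataFrame,
    rhythm: pd.DataFrame,
    gene_set_a,
    gene_set_b=None,
    min_abs_r: float = MODERATE_MIN,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Screen gene pairs by correlation magnitude and rhythmicity gate.

    Parameters
    ----------
    expr : DataFrame
        Long relative-expression table (sample_id, gene, zt, replicate, value).
    rhythm : DataFrame
        Cosinor summary with columns (gene, rhythmic) covering every
        screened gene.
    gene_set_a, gene_set_b : iterables of gene names
        With ``gene_set_b`` omitted, all unordered pairs within
        ``gene_set_a``; otherwise all unordered cross pairs. Each
        unordered pair appears once.
    min_abs_r : float
        Magnitude gate (strict) on |r|.
    keep_all : bool
        Return every evaluated pair (with ``gate_passed`` flags) instead
        of only the retained ones.
    """
    rhythmic = dict(zip(rhythm["gene"], rhythm["rhythmic"].astype(bool)))
    gene_set_a = list(gene_set_a)
    if gene_set_b is None:
        pairs = list(combinations(gene_set_a, 2))
    else:
        pairs, seen = [], set()
        for a in gene_set_a:
            for b in gene_set_b:
                if a == b or frozenset((a, b)) in seen:
                    continue
                seen.add(frozenset((a, b)))
                pairs.append((a, b))

    for gene in {g for p in pairs for g in p}:
        if gene not in rhythmic:
            raise ValueError(f"no rhythmicity flag for gene {gene!r}")

    timepoints = np.sort(expr["zt"].unique())
    profiles = {}
    records = []
    for a, b in pairs:
        for g in (a, b):
            if g not in profiles:
                profiles[g] = mean_profile(expr, g, timepoints)
        r = pearson_r(profiles[a], profiles[b])
        direction, strength = classify_correlation(r)
        gate = abs(r) > min_abs_r and (rhythmic[a] or rhythmic[b])
        records.append(CorrelationRecord(a, b, r, direction, strength, gate))

    if not keep_all:
        records = [rec for rec in records if rec.gate_passed]
    return pd.DataFrame(
        [
            dict(
                gene_a=rec.gene_a,
                gene_b=rec.gene_b,
                r=rec.r,
                direction=rec.direction,
                strength=rec.strength,
                gate_passed=rec.gate_passed,
            )
            for rec in records
        ],
        columns=["gene_a", "gene_b", "r", "direction", "strength", "gate_passed"],
    )
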