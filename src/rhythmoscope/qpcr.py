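"""Relative qPCR quantification (2^-ddCt) and geNorm reference stability.

Relative expression of a target gene in a sample is

    R = 2^-ddCt,   ddCt = (Ct_target - Ct_reference)_sample
                          - (Ct_target - Ct_reference)_calibrator

where Ct_reference is the arithmetic mean Ct over the reference-gene set
(equivalent to normalising by the geometric mean of reference
quantities, the geNorm convention). The calibrator defines the unit of
the expression scale only; it never changes fold-relations between
samples.

Reference-gene stability follows the published geNorm definition: for
candidate genes j, k the pairwise variation V_jk is the SD over samples
of log2(q_j/q_k), the stability M_j is the mean of V_jk over k != j, and
candidates are iteratively excluded worst-first. The pairwise variation
V(n/n+1) between normalisation factors built from the n and n+1 most
stable genes guides how many references are needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "delta_delta_ct",
    "quantify",
    "genorm",
    "select_reference",
    "GeNormResult",
    "DeltaDeltaCt",
    "GeNormSelector",
]

_CALIBRATORS = ("global_mean", "zt0_mean", "min")


def _pivot_ct(ct: pd.DataFrame) -> pd.DataFrame:
    dup = ct.duplicated(["sample_id", "gene"])
    if dup.any():
        raise ValueError(
            f"duplicate (sample_id, gene) rows, e.g. "
            f"{ct.loc[dup.idxmax(), ['sample_id', 'gene']].tolist()}"
        )
    return ct.pivot(index="sample_id", columns="gene", values="ct")


def delta_delta_ct(
    ct: pd.DataFrame,
    target: str,
    reference,
    calibrator: str = "global_mean",
) -> pd.DataFrame:
    """Relative expression R = 2^-ddCt for one target gene.

    Parameters
    ----------
    ct : DataFrame
        Long-format Ct table with columns (sample_id, gene, zt, replicate, ct).
    target : str
        Target gene name.
    reference : str or iterable of str
        Reference (housekeeping) gene or gene set; the per-sample
        reference Ct is their arithmetic mean.
    calibrator : {"global_mean", "zt0_mean", "min"}
        The "control" condition anchoring ddCt = 0: per-target mean dCt
        over all samples (default), mean dCt of the earliest-ZT samples,
        or the minimum dCt (most expressed sample scales to R = 1).

    Returns a long table (sample_id, gene, zt, replicate, value) with
    value = R > 0 for every retained sample.
    """
    if isinstance(reference, str):
        reference = [reference]
    reference = list(reference)
    if not reference:
        raise ValueError("empty reference gene set")
    if calibrator not in _CALIBRATORS:
        raise ValueError(f"unknown calibrator rule {calibrator!r}")

    wide = _pivot_ct(ct)
    for gene in [target, *reference]:
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from Ct table")
        missing = wide.index[wide[gene].isna()]
        if len(missing):
            raise ValueError(f"missing Ct for gene {gene!r} in sample {missing[0]!r}")

    d_ct = wide[target] - wide[reference].mean(axis=1)

    meta = (
        ct.loc[ct["gene"] == target, ["sample_id", "zt", "replicate"]]
        .set_index("sample_id")
        .loc[d_ct.index]
    )
    if calibrator == "global_mean":
        cal = d_ct.mean()
    elif calibrator == "zt0_mean":
        cal = d_ct[meta["zt"] == meta["zt"].min()].mean()
    else:  # min
        cal = d_ct.min()

    out = meta.reset_index()
    out["gene"] = target
    out["value"] = 2.0 ** -(d_ct.to_numpy() - cal)
    return out[["sample_id", "gene", "zt", "replicate", "value"]]


def quantify(
    ct: pd.DataFrame, targets, reference, calibrator: str = "global_mean"
) -> pd.DataFrame:
    """Apply :func:`delta_delta_ct` to each target gene and concatenate."""
    frames = [delta_delta_ct(ct, g, reference, calibrator) for g in targets]
    return pd.concat(frames, ignore_index=True)


@dataclass
class GeNormResult:
    """geNorm output: per-gene stability M, ranking and variation V.

    ``m_values`` are full-panel stabilities; ``ranking`` orders genes by
    ascending M (most stable first); ``exclusion_order`` lists genes as
    removed by the iterative worst-first procedure (the two survivors are
    appended most-stable-last); ``pairwise_variation`` maps n to
    V(n/n+1).
    """

    m_values: "pd.Series"
    ranking: list
    exclusion_order: list
    pairwise_variation: dict


def _m_values(logq: pd.DataFrame) -> pd.Series:
    genes = list(logq.columns)
    m = {}
    for j in genes:
        vs = [logq[j].sub(logq[k]).std(ddof=1) for k in genes if k != j]
        m[j] = float(np.mean(vs))
    return pd.Series(m)


def genorm(quantities: pd.DataFrame) -> GeNormResult:
    """geNorm stability analysis of candidate reference genes.

    Parameters
    ----------
    quantities : DataFrame
        Samples x genes table of relative quantities, all > 0
        (wide format; use ``df.pivot(index="sample_id", columns="gene",
        values="value")`` on a long table).
    """
    if quantities.shape[1] < 3:
        raise ValueError("geNorm needs at least 3 candidate genes")
    if quantities.shape[0] < 2:
        raise ValueError("geNorm needs at least 2 samples")
    if (quantities <= 0).any().any() or quantities.isna().any().any():
        raise ValueError("all quantities must be positive and finite")

    logq = np.log2(quantities.astype(float))
    m_full = _m_values(logq)
    ranking = list(m_full.sort_values(kind="stable").index)

    exclusion_order = []
    remaining = list(logq.columns)
    while len(remaining) > 2:
        m_now = _m_values(logq[remaining])
        worst = m_now.idxmax()
        exclusion_order.append(worst)
        remaining.remove(worst)
    # record the survivors, most stable last
    final = _m_values(logq[list(logq.columns)]).loc[remaining]
    exclusion_order.extend(final.sort_values(ascending=False, kind="stable").index)

    pairwise_variation = {}
    k = quantities.shape[1]
    for n in range(2, k):
        nf_n = logq[ranking[:n]].mean(axis=1)  # log2 geometric mean
        nf_n1 = logq[ranking[: n + 1]].mean(axis=1)
        pairwise_variation[n] = float((nf_n - nf_n1).std(ddof=1))

    return GeNormResult(
        m_values=m_full,
        ranking=ranking,
        exclusion_order=exclusion_order,
        pairwise_variation=pairwise_variation,
    )


def select_reference(
    result: GeNormResult, v_threshold: float = 0.15, single: bool = False
) -> list:
    """Choose the reference-gene set from a geNorm analysis.

    ``single=True`` returns just the most stable gene (single-reference
    usage). Otherwise returns the smallest top-n set (n >= 2) whose
    V(n/n+1) falls below ``v_threshold``; when no V qualifies, the full
    ranked panel is returned.
    """
    if single:
        return [result.ranking[0]]
    for n in sorted(result.pairwise_variation):
        if result.pairwise_variation[n] < v_threshold:
            return result.ranking[:n]
    return list(result.ranking)


class DeltaDeltaCt(TransformerMixin, BaseEstimator):
    """Transformer from long Ct tables to relative expression tables.

    Thin sklearn-style wrapper over :func:`quantify`; ``fit`` validates
    the configured genes against the table, ``transform`` computes
    R = 2^-ddCt for every target.
    """

    def __init__(self, target_genes=None, reference_genes=("rpl13",),
                 calibrator="global_mean"):
        self.target_genes = target_genes
        self.reference_genes = reference_genes
        self.calibrator = calibrator

    def fit(self, X: pd.DataFrame, y=None):
        genes = list(dict.fromkeys(X["gene"]))
        refs = list(self.reference_genes)
        targets = (
            list(self.target_genes)
            if self.target_genes is not None
            else [g for g in genes if g not in refs]
        )
        for g in [*targets, *refs]:
            if g not in genes:
                raise ValueError(f"gene {g!r} absent from Ct table")
        self.target_genes_ = targets
        self.reference_genes_ = refs
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "target_genes_")
        return quantify(X, self.target_genes_, self.reference_genes_, self.calibrator)


class GeNormSelector(TransformerMixin, BaseEstimator):
    """Sklearn-style selector of stable reference genes via geNorm.

    ``fit`` expects a samples x genes quantity table; fitted attributes
    expose ``m_values_``, ``ranking_``, ``pairwise_variation_`` and the
    chosen ``selected_genes_``; ``transform`` restricts the table to the
    selection.
    """

    def __init__(self, v_threshold: float = 0.15, single: bool = False):
        self.v_threshold = v_threshold
        self.single = single

    def fit(self, X: pd.DataFrame, y=None):
        result = genorm(X)
        self.feature_names_in_ = list(X.columns)
        self.result_ = result
        self.m_values_ = result.m_values
        self.ranking_ = result.ranking
        self.exclusion_order_ = result.exclusion_order
        self.pairwise_variation_ = result.pairwise_variation
        self.selected_genes_ = select_reference(
            result, v_threshold=self.v_threshold, single=self.single
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_genes_")
        return X[self.selected_genes_]

    def get_support(self):
        check_is_fitted(self, "selected_genes_")
        return [g in self.selected_genes_ for g in self.feature_names_in_]
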