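"""Published reference values and gene panels for the Chinese perch
muscle daily-rhythm study.

Ships transcriptions of the published per-gene rhythmicity parameters
(amplitude, noise/signal P, mesor, acrophase, ZT of peak) for fast and
slow skeletal muscle, the clock / myogenic / reference-candidate gene
panels, and the cloned cDNA segment lengths. These are values of record
for consistency checks; the raw expression measurements behind them were
never deposited.
"""

from __future__ import annotations

import warnings
from importlib import resources

import pandas as pd

__all__ = [
    "CLOCK_GENES",
    "MYOGENIC_GENES",
    "REFERENCE_CANDIDATES",
    "CDNA_SEGMENTS",
    "normalize_gene_name",
    "load_rhythm_params",
    "count_rhythmic",
    "transcript_structure_total",
]

#: Core circadian oscillator genes assayed in both muscle types.
CLOCK_GENES = [
    "arntl1", "arntl2", "cry1", "cry2", "cry3", "npas2", "nr1d1", "nr1d2",
    "per1", "per2", "per3", "rora", "tim", "clock", "crydash",
]

#: Myogenesis-related genes assayed alongside the clock panel.
MYOGENIC_GENES = [
    "foxk2", "mbnl1", "mrf4", "mstn", "murf1",
    "myf5", "myod", "myog", "pdk4", "pcna", "ucp3",
]

#: Candidate housekeeping genes screened for stability (rpl13 won).
REFERENCE_CANDIDATES = ["rpl13", "actb", "hprt1", "rps29", "gapdh", "rna18s"]

#: Cloned full-length cDNAs: gene -> (5'UTR, ORF, 3'UTR) in bp.
CDNA_SEGMENTS = {
    "clock": (412, 2697, 589),
    "cry1": (837, 1866, 773),
    "per1": (300, 4311, 795),
    "nr1d2": (380, 1770, 534),
}

_NAME_MAP = {"rorα": "rora", "rora": "rora", "cry-dash": "crydash"}


def normalize_gene_name(name: str) -> str:
    """Canonical lower-case gene symbol (e.g. 'rorα' -> 'rora')."""
    key = name.strip().lower().replace("α", "a")
    key = _NAME_MAP.get(key, key)
    return key.replace("-", "")


def load_rhythm_params(tissue: str) -> pd.DataFrame:
    """Published rhythmicity parameter table for one muscle type.

    Columns: gene, amplitude, p_value, mesor, acrophase (rad), zt_h,
    rhythmic (the published bold/rhythmic annotation, i.e. P < 0.3).
    """
    if tissue not in ("fast", "slow"):
        raise ValueError("tissue must be 'fast' or 'slow'")
    path = resources.files("rhythmoscope.data") / f"{tissue}_muscle_rhythm_params.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def count_rhythmic(table: pd.DataFrame, gene_subset, threshold: float = 0.3) -> int:
    """Number of genes in ``gene_subset`` with p_value < threshold."""
    indexed = table.set_index("gene")["p_value"]
    n = 0
    for gene in gene_subset:
        if gene not in indexed.index:
            raise ValueError(f"gene {gene!r} absent from rhythm table")
        if indexed[gene] < threshold:
            n += 1
    return n


def transcript_structure_total(utr5: int, orf: int, utr3: int) -> int:
    """Full transcript length from 5'UTR + ORF + 3'UTR segment lengths."""
    for name, value in (("utr5", utr5), ("orf", orf), ("utr3", utr3)):
        if value < 0:
            raise ValueError(f"{name} length must be nonnegative, got {value}")
    if orf % 3 != 0:
        warnings.warn(
            f"ORF length {orf} bp is not a multiple of 3", stacklevel=2
        )
    return int(utr5) + int(orf) + int(utr3)
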