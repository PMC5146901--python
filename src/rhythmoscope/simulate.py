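"""Seeded synthetic qPCR datasets with cosinor structure.

Emulates a daily-rhythm sampling design: fish sampled every 3 h across one
light-dark cycle (ZT0, 3, ..., 24; ZT0 and ZT24 are distinct animals at
the same circadian phase), n replicates per timepoint, a panel of target
genes whose expression follows f(t) = M + A*cos(pi*t/12 - phi), plus
candidate reference genes that are either stable or drift with time of
day. Noise is multiplicative log-normal on expression (equivalently
additive Gaussian on Ct), the usual qPCR error structure.

Each gene draws from its own child random stream derived from the root
seed and the gene's position in the panel, so appending a gene never
perturbs earlier genes' values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cosinor import OMEGA

__all__ = [
    "GeneSpec",
    "StudyDesign",
    "cosinor_signal",
    "generate_expression_dataset",
    "generate_ct_dataset",
]


def cosinor_signal(t, mesor, amplitude, acrophase):
    """Noise-free 24-h cosinor curve M + A*cos(pi*t/12 - phi).

    Periodic with period 24 h; peaks at t = 12*phi/pi (mod 24).
    """
    if np.any(np.asarray(amplitude) < 0):
        raise ValueError("amplitude must be nonnegative")
    t = np.asarray(t, dtype=float)
    return mesor + amplitude * np.cos(OMEGA * t - acrophase)


@dataclass(frozen=True)
class GeneSpec:
    """Generating parameters for one simulated gene.

    ``mesor`` and ``amplitude`` are on the relative-expression scale;
    ``acrophase`` in radians (wrapped to [0, 2pi)); ``noise_sd`` is the
    SD of the additive log2 noise; ``drift`` is a deterministic log2
    trend per 24 h used for unstable reference candidates. Requires
    amplitude <= mesor so noiseless expression stays nonnegative.
    """

    name: str
    mesor: float
    amplitude: float = 0.0
    acrophase: float = 0.0
    noise_sd: float = 0.1
    role: str = "target"
    drift: float = 0.0

    _ROLES = ("target", "reference_stable", "reference_unstable")

    def __post_init__(self):
        if self.mesor <= 0:
            raise ValueError(f"{self.name}: mesor must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"{self.name}: amplitude must be >= 0")
        if self.amplitude > self.mesor:
            raise ValueError(
                f"{self.name}: amplitude {self.amplitude} exceeds mesor "
                f"{self.mesor}; noiseless expression would go negative"
            )
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: noise_sd must be >= 0")
        if self.role not in self._ROLES:
            raise ValueError(f"{self.name}: unknown role {self.role!r}")
        object.__setattr__(self, "acrophase", float(self.acrophase) % (2 * math.pi))

    def signal(self, t):
        """Expected (noise-free) expression at times ``t``."""
        base = cosinor_signal(t, self.mesor, self.amplitude, self.acrophase)
        if self.drift:
            base = base * 2.0 ** (self.drift * (np.asarray(t, float) - 12.0) / 24.0)
        return base


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout: Zeitgeber times, replicates per time, root seed."""

    timepoints: tuple = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0, 24.0)
    replicates: int = 6
    photoperiod: tuple = (12.0, 12.0)  # light, dark hours (annotation only)
    seed: int = 0

    def __post_init__(self):
        tp = tuple(float(t) for t in self.timepoints)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if tp and (tp[0] < 0 or tp[-1] > 24):
            raise ValueError("timepoints must lie in [0, 24]")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per timepoint")
        object.__setattr__(self, "timepoints", tp)

    @property
    def sample_ids(self):
        return [
            f"ZT{t:g}_r{r + 1}"
            for t in self.timepoints
            for r in range(self.replicates)
        ]


def _gene_rng(design: StudyDesign, index: int) -> np.random.Generator:
    # child stream per gene: appending genes never reshuffles earlier draws
    return np.random.default_rng([int(design.seed), int(index)])


def generate_expression_dataset(genes, design: StudyDesign) -> pd.DataFrame:
    """Draw a long-format relative-expression table.

    Each observation is signal(t) * 2**eps with eps ~ N(0, noise_sd^2),
    independent across fish and genes. Columns:
    (sample_id, gene, zt, replicate, value). Deterministic for a fixed
    (genes, design) pair.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("need at least one GeneSpec")
    tps = np.asarray(design.timepoints)
    nrep = design.replicates
    frames = []
    for idx, spec in enumerate(genes):
        rng = _gene_rng(design, idx)
        eps = rng.normal(0.0, spec.noise_sd, size=(tps.size, nrep))
        signal = spec.signal(tps)[:, None]
        values = signal * 2.0**eps
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": design.sample_ids,
                    "gene": spec.name,
                    "zt": np.repeat(tps, nrep),
                    "replicate": np.tile(np.arange(1, nrep + 1), tps.size),
                    "value": values.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_ct_dataset(genes, design: StudyDesign, base_ct: float = 22.0) -> pd.DataFrame:
    """Draw a long-format Ct table, ct = base_ct - log2(expression).

    A doubling of expression lowers Ct by exactly one cycle. Stable
    reference genes (amplitude 0, small noise) get near-constant Ct;
    unstable ones drift with ZT through their ``drift`` term. Columns:
    (sample_id, gene, zt, replicate, ct).
    """
    expr = generate_expression_dataset(genes, design)
    values = expr["value"].to_numpy()
    if np.any(values <= 0):
        raise ValueError("expression draw <= 0; cannot form a finite Ct")
    ct = expr.drop(columns="value")
    ct["ct"] = base_ct - np.log2(values)
    if not np.all(np.isfinite(ct["ct"])):
        raise ValueError("non-finite Ct generated")
    return ct
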