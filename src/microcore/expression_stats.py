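"""TPM normalization, cohort means, empirical percentile ranks and the
Δ-percentile concordance statistic.

Two cohorts profiled with different protocols cannot be compared on raw
abundance. Instead each cohort's mean expression vector is reduced to an
empirical percentile rank per gene (0 = most abundant, 100 = least), and the
per-gene absolute difference of ranks between cohorts (Δ percentile)
measures concordance on a protocol-free scale: a small Δ means the gene
occupies a similar position in both expression distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import CountTable, GeneLengthTable

logger = logging.getLogger(__name__)

__all__ = [
    "TpmMatrix",
    "PercentileProfile",
    "DeltaPercentileTable",
    "tpm_normalize",
    "cohort_mean",
    "percentile_rank",
    "delta_percentile",
]


@dataclass
class TpmMatrix:
    """Transcripts-per-million; every sample column sums to 1e6."""

    values: pd.DataFrame  # genes x samples
    cohort_of: dict[str, str]

    def samples_in(self, cohort: str) -> list[str]:
        out = [s for s in self.values.columns if self.cohort_of[s] == cohort]
        if not out:
            raise KeyError(f"unknown cohort {cohort!r}")
        return out


@dataclass
class PercentileProfile:
    """Per-gene abundance percentile within one cohort, 0 = most abundant."""

    cohort: str
    percentiles: pd.Series  # gene -> value in [0, 100]

    def top(self, cutoff: float = 10.0) -> set[str]:
        return set(self.percentiles.index[self.percentiles < cutoff])


@dataclass
class DeltaPercentileTable:
    """|percentile_a - percentile_b| per gene shared by two cohorts."""

    cohort_a: str
    cohort_b: str
    delta: pd.Series  # gene -> Δ percentile in [0, 100]

    @property
    def median(self) -> float:
        return float(self.delta.median())


def tpm_normalize(counts: CountTable, lengths: GeneLengthTable) -> TpmMatrix:
    """Length-normalize counts to TPM.

    Per sample: ``rate_g = count_g / length_kb_g``; ``tpm_g = 1e6 * rate_g /
    sum(rate)``. Genes without a length entry are dropped with a logged
    warning; a sample whose retained counts are all zero has no defined TPM
    and raises ``ValueError``.
    """
    keep = [g for g in counts.gene_ids if g in lengths]
    dropped = len(counts.gene_ids) - len(keep)
    if dropped:
        logger.warning("tpm_normalize: dropped %d genes without length", dropped)
    if not keep:
        raise ValueError("no gene has a length annotation")
    sub = counts.counts.loc[keep]
    kb = np.array([lengths[g] for g in keep], dtype=float) / 1000.0
    rate = sub.to_numpy(dtype=float) / kb[:, None]
    colsum = rate.sum(axis=0)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        raise ValueError(
            f"sample {sub.columns[zero[0]]!r} has all-zero counts; TPM undefined"
        )
    tpm = rate / colsum * 1e6
    return TpmMatrix(
        values=pd.DataFrame(tpm, index=sub.index, columns=sub.columns),
        cohort_of=dict(counts.cohort_of),
    )


def cohort_mean(tpm: TpmMatrix, cohort: str) -> pd.Series:
    """Arithmetic mean TPM across the cohort's samples, per gene."""
    samples = tpm.samples_in(cohort)
    return tpm.values[samples].mean(axis=1)


def percentile_rank(means: pd.Series, cohort: str = "") -> PercentileProfile:
    """Empirical percentile of each gene in a cohort's mean-expression vector.

    Genes are ranked by descending mean; tied means share the average of
    their descending ranks; with the top gene at rank 0 and G genes,
    ``p = 100 * rank / (G - 1)`` so the most abundant gene scores 0 and the
    least abundant 100. Zero-expression genes stay in the ranking (they tie
    at the bottom).
    """
    G = len(means)
    if G < 2:
        raise ValueError("percentile distribution undefined for < 2 genes")
    ranks = rankdata(-means.to_numpy(dtype=float), method="average") - 1.0
    pct = 100.0 * ranks / (G - 1)
    return PercentileProfile(cohort=cohort, percentiles=pd.Series(pct, index=means.index))


def delta_percentile(
    a: PercentileProfile, b: PercentileProfile
) -> DeltaPercentileTable:
    """Per-gene |p_a - p_b| over the genes present in both profiles."""
    shared = a.percentiles.index.intersection(b.percentiles.index)
    n_only = (len(a.percentiles) - len(shared)) + (len(b.percentiles) - len(shared))
    if n_only:
        logger.info("delta_percentile: %d genes present in only one profile", n_only)
    if len(shared) == 0:
        raise ValueError("profiles share no genes; Δ percentile undefined")
    delta = (a.percentiles.loc[shared] - b.percentiles.loc[shared]).abs()
    return DeltaPercentileTable(cohort_a=a.cohort, cohort_b=b.cohort, delta=delta)
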