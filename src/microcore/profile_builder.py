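"""Assembly of a species core microglia profile.

Candidates are the union of (i) DE-enriched genes, (ii) genes in the top
expression decile of both sorted-microglia cohorts, and (iii) genes in the
top decile of the second (more specific) cohort only — (ii) and (iii) each
after removal of genes also in the tissue top decile. Candidates are then
retained only if their percentile rank is concordant between the two
microglia cohorts (Δ percentile < 20) and their expression is
microglia-specific (> 60% of the summed mean expression over the three
sample groups falls in the two microglia cohorts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .expression_stats import DeltaPercentileTable, PercentileProfile

logger = logging.getLogger(__name__)

__all__ = [
    "TopDecileSet",
    "VennPartition",
    "TriangleTable",
    "SpeciesProfile",
    "top_decile",
    "microglia_unique",
    "venn_partition",
    "triangle_fractions",
    "build_core_profile",
]


@dataclass
class TopDecileSet:
    cohort: str
    genes: set[str]
    cutoff: float


@dataclass
class VennPartition:
    label_a: str
    label_b: str
    a_only: set[str]
    shared: set[str]
    b_only: set[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "a_only": len(self.a_only),
            "shared": len(self.shared),
            "b_only": len(self.b_only),
        }


@dataclass
class TriangleTable:
    """Per-gene expression distribution (%) over tissue / cohort-1 / cohort-2.

    The three columns sum to 100 per gene; genes with zero mean in all three
    groups carry no information and are dropped (count logged and stored).
    """

    fractions: pd.DataFrame  # columns pct_tissue, pct_c1, pct_c2
    n_dropped_all_zero: int = 0

    def microglia_fraction(self) -> pd.Series:
        return self.fractions["pct_c1"] + self.fractions["pct_c2"]


@dataclass
class SpeciesProfile:
    """Final core profile with per-gene provenance flags."""

    species: str
    genes: set[str]
    flags: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_candidates: int = 0
    n_uncovered: int = 0
    attrition: dict[str, int] = field(default_factory=dict)


def top_decile(profile: PercentileProfile, cutoff: float = 10.0) -> TopDecileSet:
    """Genes with percentile < cutoff (0 = most abundant orientation)."""
    return TopDecileSet(cohort=profile.cohort, genes=profile.top(cutoff), cutoff=cutoff)


def microglia_unique(mg_set: set[str], tissue_set: set[str]) -> set[str]:
    """Remove genes that are also highly expressed in total tissue."""
    return set(mg_set) - set(tissue_set)


def venn_partition(a: set[str], b: set[str], label_a: str = "A", label_b: str = "B") -> VennPartition:
    a, b = set(a), set(b)
    return VennPartition(
        label_a=label_a, label_b=label_b,
        a_only=a - b, shared=a & b, b_only=b - a,
    )


def triangle_fractions(
    mean_tissue: pd.Series, mean_c1: pd.Series, mean_c2: pd.Series
) -> TriangleTable:
    """Percentage distribution of each gene's mean expression over the three
    sample groups; computed on genes present in all three maps."""
    shared = mean_tissue.index.intersection(mean_c1.index).intersection(mean_c2.index)
    df = pd.DataFrame(
        {
            "pct_tissue": mean_tissue.loc[shared],
            "pct_c1": mean_c1.loc[shared],
            "pct_c2": mean_c2.loc[shared],
        }
    )
    total = df.sum(axis=1)
    nonzero = total > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("triangle_fractions: dropped %d all-zero genes", n_dropped)
    df = df.loc[nonzero].div(total[nonzero], axis=0) * 100.0
    return TriangleTable(fractions=df, n_dropped_all_zero=n_dropped)


def build_core_profile(
    de_enriched: set[str],
    shared_top: set[str],
    c2_only_top: set[str],
    delta: DeltaPercentileTable,
    triangle: TriangleTable,
    delta_max: float = 20.0,
    microglia_min_pct: float = 60.0,
    species: str = "",
) -> SpeciesProfile:
    """Union the candidate sources, then apply the concordance and
    specificity filters (both strict inequalities).

    Candidate genes not covered by both the Δ table and the triangle table
    cannot be evaluated and are excluded (counted in ``n_uncovered``).
    """
    de_enriched = set(de_enriched)
    shared_top = set(shared_top)
    c2_only_top = set(c2_only_top)
    candidates = de_enriched | shared_top | c2_only_top
    if not candidates:
        logger.warning("build_core_profile: empty candidate set")
        return SpeciesProfile(species=species, genes=set())
    covered = sorted(
        candidates
        & set(delta.delta.index)
        & set(triangle.fractions.index)
    )
    n_uncovered = len(candidates) - len(covered)
    if n_uncovered:
        logger.info(
            "build_core_profile: %d candidates lack Δ or triangle coverage",
            n_uncovered,
        )
    mg_frac = triangle.microglia_fraction()
    flags = pd.DataFrame(
        {
            "in_de_enriched": [g in de_enriched for g in covered],
            "in_top_decile_shared": [g in shared_top for g in covered],
            "in_top_decile_c2_only": [g in c2_only_top for g in covered],
            "delta_lt_threshold": delta.delta.loc[covered] < delta_max,
            "microglia_fraction_ge_threshold": mg_frac.loc[covered] > microglia_min_pct,
        },
        index=pd.Index(covered, name="gene"),
    )
    flags["retained"] = (
        flags["delta_lt_threshold"] & flags["microglia_fraction_ge_threshold"]
    )
    retained = set(flags.index[flags["retained"]])
    attrition = {
        "candidates": len(candidates),
        "uncovered": n_uncovered,
        "fail_delta": int((~flags["delta_lt_threshold"]).sum()),
        "fail_microglia_fraction": int(
            (~flags["microglia_fraction_ge_threshold"]).sum()
        ),
        "retained": len(retained),
    }
    return SpeciesProfile(
        species=species,
        genes=retained,
        flags=flags,
        n_candidates=len(candidates),
        n_uncovered=n_uncovered,
        attrition=attrition,
    )
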