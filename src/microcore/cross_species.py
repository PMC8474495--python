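"""Cross-species intersection of core microglia profiles.

Profiles are expressed in shared-symbol space through an ortholog map, then
intersected pairwise and by membership count: the "lenient" subset holds
symbols present in at least k (default 3) of the species, the "evolutionary
preserved core" symbols present in every species. Species-private,
unmappable identifiers (ORF-like, LOC-style) are excluded from the counts
but reported per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .io_formats import OrthologMap
from .profile_builder import SpeciesProfile, VennPartition, venn_partition

__all__ = [
    "ProfileCollection",
    "ConservationResult",
    "harmonize_symbols",
    "pairwise_overlap",
    "conservation",
    "signature_overlap",
]

TIERS = ("high", "intermediate", "low")


@dataclass
class ProfileCollection:
    """species -> profile gene set in shared-symbol space."""

    profiles: dict[str, set[str]]
    unmapped: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.profiles) < 2:
            raise ValueError("a profile collection needs >= 2 species")

    @property
    def species(self) -> list[str]:
        return list(self.profiles)


@dataclass
class ConservationResult:
    membership: dict[str, frozenset[str]]  # symbol -> species containing it
    lenient_k: int
    n_species: int

    @property
    def union(self) -> set[str]:
        return set(self.membership)

    @property
    def lenient(self) -> set[str]:
        return {s for s, sp in self.membership.items() if len(sp) >= self.lenient_k}

    @property
    def core(self) -> set[str]:
        return {s for s, sp in self.membership.items() if len(sp) == self.n_species}

    def membership_table(self) -> dict[str, int]:
        """Counts per species-combination (the 2^S Venn regions, empty ones
        omitted)."""
        out: dict[str, int] = {}
        for sp_set in self.membership.values():
            key = "&".join(sorted(sp_set))
            out[key] = out.get(key, 0) + 1
        return out


def harmonize_symbols(
    profiles: dict[str, SpeciesProfile | set[str]],
    ortholog_map: OrthologMap | None = None,
) -> ProfileCollection:
    """Express every species profile in shared-symbol space.

    A gene with no map entry is flagged unmapped for its species and left
    out of the comparable set. With no map, genes are taken to be symbols
    already.
    """
    mapped: dict[str, set[str]] = {}
    unmapped: dict[str, set[str]] = {}
    for sp, prof in profiles.items():
        genes = prof.genes if isinstance(prof, SpeciesProfile) else set(prof)
        if ortholog_map is None:
            mapped[sp] = set(genes)
            unmapped[sp] = set()
            continue
        syms: set[str] = set()
        miss: set[str] = set()
        for g in genes:
            s = ortholog_map.symbol(sp, g)
            if s is None:
                miss.add(g)
            else:
                syms.add(s)
        mapped[sp] = syms
        unmapped[sp] = miss
    return ProfileCollection(profiles=mapped, unmapped=unmapped)


def pairwise_overlap(
    collection: ProfileCollection, species_a: str, species_b: str
) -> VennPartition:
    for sp in (species_a, species_b):
        if sp not in collection.profiles:
            raise KeyError(f"unknown species {sp!r}")
    return venn_partition(
        collection.profiles[species_a],
        collection.profiles[species_b],
        label_a=species_a,
        label_b=species_b,
    )


def all_pairwise_overlaps(
    collection: ProfileCollection,
) -> dict[tuple[str, str], VennPartition]:
    return {
        (a, b): pairwise_overlap(collection, a, b)
        for a, b in combinations(collection.species, 2)
    }


def conservation(collection: ProfileCollection, lenient_k: int = 3) -> ConservationResult:
    n_species = len(collection.profiles)
    if lenient_k > n_species:
        raise ValueError(
            f"lenient_k={lenient_k} exceeds the {n_species} species present"
        )
    membership: dict[str, set[str]] = {}
    for sp, syms in collection.profiles.items():
        for s in syms:
            membership.setdefault(s, set()).add(sp)
    return ConservationResult(
        membership={s: frozenset(v) for s, v in membership.items()},
        lenient_k=lenient_k,
        n_species=n_species,
    )


def signature_overlap(
    gene_set: set[str], signature: dict[str, str]
) -> dict[str, dict[str, float]]:
    """Overlap of a gene set with an externally published tiered signature.

    Returns per tier (plus ``unassigned`` for symbols absent from the
    signature) the count and the percentage relative to |gene_set|.
    """
    gene_set = set(gene_set)
    counts = {t: 0 for t in TIERS}
    unassigned = 0
    for g in gene_set:
        tier = signature.get(g)
        if tier is None:
            unassigned += 1
        elif tier not in counts:
            raise ValueError(f"unknown tier {tier!r} for symbol {g!r}")
        else:
            counts[tier] += 1
    n = len(gene_set)
    out: dict[str, dict[str, float]] = {}
    for tier, k in {**counts, "unassigned": unassigned}.items():
        out[tier] = {"count": k, "pct": (100.0 * k / n) if n else 0.0}
    return out
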