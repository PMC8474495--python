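"""Hypergeometric GO enrichment and structural parent-collapse.

Enrichment is the upper hypergeometric tail with BH adjustment; the kept
terms then get re-annotated to a small layer of "reference" terms — the
descendants of the ontology root within two is_a steps — by walking each
enriched term's ancestry upward to the nearest reference term. Gene hits of
terms that collapse onto the same reference are unioned into a unique-gene
count per reference term, the quantity a circos ribbon plot displays per
species.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_adjust
from .io_formats import AnnotationTable, OntologyGraph

__all__ = [
    "EnrichmentResult",
    "CollapsedGOResult",
    "enrich",
    "hit_lists",
    "reference_nodes",
    "collapse_terms",
    "unique_gene_counts",
    "circos_export",
]


@dataclass
class EnrichmentResult:
    """Per-term hypergeometric enrichment.

    ``tested`` covers every term with >= 1 hit; ``significant`` the subset
    passing the p and q thresholds. ``hits`` maps each tested term to the
    gene-set members annotated to it (with propagation if it was on).
    """

    tested: pd.DataFrame  # index term; columns k, K, n, N, p, q
    significant: pd.DataFrame
    hits: dict[str, frozenset[str]] = field(default_factory=dict)


@dataclass
class CollapsedGOResult:
    """original enriched term -> chosen reference term."""

    mapping: pd.DataFrame  # index term; columns reference, distance, deep
    contributors: dict[str, set[str]]  # reference term -> original terms

    @property
    def reference_terms(self) -> set[str]:
        return set(self.contributors)


def _propagated(
    annotation: AnnotationTable, ontology: OntologyGraph, genes: Iterable[str]
) -> dict[str, set[str]]:
    """term -> annotated genes, each direct annotation propagated to all
    ancestors."""
    term_genes: dict[str, set[str]] = {}
    cache: dict[str, frozenset[str]] = {}
    for g in genes:
        for t in annotation.terms_of(g):
            if t not in cache:
                cache[t] = frozenset({t} | ontology.ancestors(t))
            for anc in cache[t]:
                term_genes.setdefault(anc, set()).add(g)
    return term_genes


def _direct(annotation: AnnotationTable, genes: Iterable[str]) -> dict[str, set[str]]:
    term_genes: dict[str, set[str]] = {}
    for g in genes:
        for t in annotation.terms_of(g):
            term_genes.setdefault(t, set()).add(g)
    return term_genes


def hit_lists(
    gene_set: set[str],
    annotation: AnnotationTable,
    ontology: OntologyGraph,
    propagate: bool = False,
) -> dict[str, frozenset[str]]:
    """term -> members of ``gene_set`` annotated to it."""
    raw = (
        _propagated(annotation, ontology, gene_set)
        if propagate
        else _direct(annotation, gene_set)
    )
    return {t: frozenset(g) for t, g in raw.items()}


def enrich(
    gene_set: set[str],
    background: set[str],
    annotation: AnnotationTable,
    ontology: OntologyGraph,
    propagate: bool = True,
    p_max: float = 0.05,
    q_max: float = 0.1,
) -> EnrichmentResult:
    """Hypergeometric term enrichment of ``gene_set`` against ``background``.

    For a term with K annotated background genes and k hits in the n-gene
    set drawn from an N-gene background, p = P(X >= k) for X ~
    Hypergeom(N, K, n); q is BH over the tested terms. Terms are kept when
    p < p_max and q < q_max (both strict).
    """
    gene_set, background = set(gene_set), set(background)
    stray = gene_set - background
    if stray:
        raise ValueError(
            f"gene set not contained in background; e.g. {sorted(stray)[:5]}"
        )
    if not annotation.annotations:
        raise ValueError("empty annotation table")
    if propagate:
        bg_terms = _propagated(annotation, ontology, background)
        hit_terms = _propagated(annotation, ontology, gene_set)
    else:
        bg_terms = _direct(annotation, background)
        hit_terms = _direct(annotation, gene_set)
    if propagate:
        # root term annotates everything annotated at all; drop it from tests
        hit_terms.pop(ontology.root, None)
    N, n = len(background), len(gene_set)
    rows = []
    hits: dict[str, frozenset[str]] = {}
    for term in sorted(hit_terms):
        k = len(hit_terms[term])
        K = len(bg_terms[term])
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, p))
        hits[term] = frozenset(hit_terms[term])
    tested = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "p"]
    ).set_index("term")
    tested["q"] = bh_adjust(tested["p"].to_numpy())
    significant = tested[(tested["p"] < p_max) & (tested["q"] < q_max)]
    return EnrichmentResult(tested=tested, significant=significant.copy(), hits=hits)


def reference_nodes(ontology: OntologyGraph, max_distance: int = 2) -> set[str]:
    """Terms whose shortest is_a path to the root has length 1..max_distance
    (the root itself is excluded)."""
    out = set()
    for term in ontology.terms:
        if term == ontology.root:
            continue
        d = ontology.distance_to_root(term)
        if d <= max_distance:
            out.add(term)
    return out


def collapse_terms(
    enriched: EnrichmentResult | Iterable[str],
    ontology: OntologyGraph,
    reference: set[str],
    term_sizes: Mapping[str, int] | None = None,
) -> CollapsedGOResult:
    """Re-annotate each enriched term to a reference term.

    A term already in the reference set maps to itself. Otherwise its
    ancestry is walked upward breadth-first; the first level containing a
    reference term wins. Terms whose nearest reference ancestor lies more
    than two is_a steps away are still collapsed but flagged ``deep``.
    Ties within a level break by largest annotated-background size (most
    general term, if sizes are known), then lexicographically smallest id.
    """
    terms = (
        list(enriched.significant.index)
        if isinstance(enriched, EnrichmentResult)
        else list(enriched)
    )
    if term_sizes is None and isinstance(enriched, EnrichmentResult):
        term_sizes = enriched.tested["K"].to_dict()
    sizes = dict(term_sizes or {})
    rows = []
    contributors: dict[str, set[str]] = {}
    for term in terms:
        if term not in ontology.terms:
            raise KeyError(f"term {term!r} absent from ontology")
        chosen, dist = _nearest_reference(term, ontology, reference, sizes)
        if chosen is None:
            raise ValueError(f"term {term!r} has no reference ancestor")
        rows.append((term, chosen, dist, dist > 2))
        contributors.setdefault(chosen, set()).add(term)
    mapping = pd.DataFrame(
        rows, columns=["term", "reference", "distance", "deep"]
    ).set_index("term")
    return CollapsedGOResult(mapping=mapping, contributors=contributors)


def _nearest_reference(
    term: str,
    ontology: OntologyGraph,
    reference: set[str],
    sizes: Mapping[str, int],
) -> tuple[str | None, int]:
    if term in reference:
        return term, 0
    frontier = {term}
    seen = {term}
    dist = 0
    while frontier:
        dist += 1
        frontier = {
            p for t in frontier for p in ontology.parents(t) if p not in seen
        }
        seen |= frontier
        matches = frontier & reference
        if matches:
            best = sorted(matches, key=lambda t: (-sizes.get(t, 0), t))[0]
            return best, dist
    return None, -1


def unique_gene_counts(
    collapsed: CollapsedGOResult, hits: Mapping[str, frozenset[str]]
) -> dict[str, int]:
    """Per reference term, the number of distinct genes across its
    contributing original terms' hit lists."""
    out: dict[str, int] = {}
    for ref, terms in collapsed.contributors.items():
        genes: set[str] = set()
        for t in terms:
            genes |= set(hits.get(t, frozenset()))
        out[ref] = len(genes)
    return out


def circos_export(
    counts_per_species: Mapping[str, Mapping[str, int]],
    ontology: OntologyGraph | None = None,
) -> pd.DataFrame:
    """Long-format ribbon table (species, reference term, unique gene count,
    relative width). Widths sum to 1 within each species; zero-count terms
    are omitted."""
    if not counts_per_species:
        raise ValueError("need at least one species result")
    rows = []
    for sp in sorted(counts_per_species):
        counts = {t: c for t, c in counts_per_species[sp].items() if c > 0}
        total = sum(counts.values())
        for term in sorted(counts):
            rows.append(
                (
                    sp,
                    term,
                    ontology.name(term) if ontology is not None else term,
                    counts[term],
                    counts[term] / total,
                )
            )
    return pd.DataFrame(
        rows, columns=["species", "reference_term", "name", "unique_genes", "width"]
    )
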