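"""End-to-end orchestration: simulate or load, normalize, rank, filter,
intersect, collapse — and emit one deterministic JSON report.

Every number in the report is produced by the stage functions themselves;
the report is a view over their outputs, not a second implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import cross_species, differential, expression_stats, go_collapse
from . import profile_builder as pb
from .io_formats import (
    CountTable,
    GeneLengthTable,
    read_annotations,
    read_count_table,
    read_gene_lengths,
    read_obo,
    read_ortholog_map,
    write_json,
)
from .synthetic_data import (
    MICROGLIA_COHORTS,
    TISSUE_COHORT,
    SimBundle,
    SimConfig,
    simulate_bundle,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Thresholds and paths for a full pipeline run.

    With ``input_dir`` unset, data come from the synthetic generator seeded
    by ``seed``; otherwise the directory must follow the layout written by
    ``microcore simulate`` (per-species ``<sp>.counts.tsv``,
    ``<sp>.cohorts.tsv``, ``<sp>.lengths.tsv`` plus ``orthologs.tsv``,
    ``ontology.obo``, ``annotations.tsv`` and optional ``signature.tsv``).
    """

    seed: int = 0
    outdir: str | None = None
    input_dir: str | None = None
    species: tuple[str, ...] | None = None
    fdr_max: float = 0.001
    lfc_min: float = 3.0
    top_cutoff: float = 10.0
    delta_max: float = 20.0
    mg_min_pct: float = 60.0
    go_p: float = 0.05
    go_q: float = 0.1
    lenient_k: int = 3
    run_go: bool = True
    sim: SimConfig | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.fdr_max <= 1 and 0 <= self.go_p <= 1 and 0 <= self.go_q <= 1):
            raise ValueError("probability thresholds must lie in [0, 1]")
        if self.top_cutoff < 0 or self.delta_max < 0:
            raise ValueError("percentile thresholds must be non-negative")
        if not (0 <= self.mg_min_pct <= 100):
            raise ValueError("mg_min_pct must lie in [0, 100]")
        if self.lenient_k < 1:
            raise ValueError("lenient_k must be >= 1")


def _load_bundle(config: PipelineConfig) -> SimBundle:
    indir = Path(config.input_dir)
    if config.species:
        species = tuple(config.species)
    else:
        species = tuple(
            sorted(p.name.removesuffix(".counts.tsv") for p in indir.glob("*.counts.tsv"))
        )
    if not species:
        raise FileNotFoundError(f"no *.counts.tsv files under {indir}")
    counts: dict[str, CountTable] = {}
    lengths: dict[str, GeneLengthTable] = {}
    for sp in species:
        counts[sp] = read_count_table(
            indir / f"{sp}.counts.tsv", indir / f"{sp}.cohorts.tsv"
        )
        lengths[sp] = read_gene_lengths(indir / f"{sp}.lengths.tsv")
    omap = None
    if (indir / "orthologs.tsv").exists():
        omap = read_ortholog_map(indir / "orthologs.tsv")
    ontology = annotations = None
    if (indir / "ontology.obo").exists():
        ontology = read_obo(indir / "ontology.obo")
        if (indir / "annotations.tsv").exists():
            annotations = read_annotations(indir / "annotations.tsv", ontology)
    signature = None
    if (indir / "signature.tsv").exists():
        df = pd.read_csv(indir / "signature.tsv", sep="\t", dtype=str)
        signature = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    from .synthetic_data import SimTruth  # local to avoid cycle at import

    truth = SimTruth(tier_of={}, species_of={}, enriched_by_species={},
                     ortholog_map=omap)
    sim = config.sim or SimConfig(seed=config.seed)
    return SimBundle(
        config=sim, counts=counts, lengths=lengths, truth=truth,
        ontology=ontology, annotations=annotations, signature=signature,
    )


def _species_stage(
    sp: str,
    counts: CountTable,
    lengths: GeneLengthTable,
    config: PipelineConfig,
) -> tuple[pb.SpeciesProfile, dict]:
    """Run the within-species stages and return (profile, report fragment).

    A species with two sorted-microglia cohorts gets the full quantitative
    procedure; a species with a single microglia cohort contributes its
    DE-enriched gene list, matching how external comparison species enter
    the analysis.
    """
    cohorts = counts.cohorts
    mg_cohorts = [c for c in cohorts if c != TISSUE_COHORT]
    tpm = expression_stats.tpm_normalize(counts, lengths)
    de = differential.de_test_builtin(counts, mg_cohorts[0], TISSUE_COHORT)
    de_set = differential.filter_enriched(de, config.fdr_max, config.lfc_min)
    frag: dict = {
        "cohorts": list(cohorts),
        "n_genes_tested": int(len(de.table)),
        "n_not_expressed": len(de.untested),
        "n_de_enriched": len(de_set),
    }
    if len(mg_cohorts) < 2:
        profile = pb.SpeciesProfile(species=sp, genes=de_set)
        frag["profile_size"] = len(de_set)
        frag["profile_source"] = "de_only"
        return profile, frag

    c1, c2 = mg_cohorts[0], mg_cohorts[1]
    means = {
        c: expression_stats.cohort_mean(tpm, c) for c in (TISSUE_COHORT, c1, c2)
    }
    pcts = {
        c: expression_stats.percentile_rank(means[c], cohort=c)
        for c in (TISSUE_COHORT, c1, c2)
    }
    delta = expression_stats.delta_percentile(pcts[c1], pcts[c2])
    tops = {c: pb.top_decile(pcts[c], config.top_cutoff) for c in (TISSUE_COHORT, c1, c2)}
    mg1_unique = pb.microglia_unique(tops[c1].genes, tops[TISSUE_COHORT].genes)
    mg2_unique = pb.microglia_unique(tops[c2].genes, tops[TISSUE_COHORT].genes)
    venn = pb.venn_partition(mg1_unique, mg2_unique, label_a=c1, label_b=c2)
    triangle = pb.triangle_fractions(means[TISSUE_COHORT], means[c1], means[c2])
    profile = pb.build_core_profile(
        de_enriched=de_set,
        shared_top=venn.shared,
        c2_only_top=venn.b_only,
        delta=delta,
        triangle=triangle,
        delta_max=config.delta_max,
        microglia_min_pct=config.mg_min_pct,
        species=sp,
    )
    frag.update(
        {
            "median_delta_percentile": delta.median,
            "venn_top_decile": venn.counts,
            "n_quantitative_candidates": len(venn.shared | venn.b_only),
            "triangle_dropped_all_zero": triangle.n_dropped_all_zero,
            "attrition": profile.attrition,
            "profile_size": len(profile.genes),
            "profile_source": "full",
        }
    )
    return profile, frag


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the JSON-serializable report.

    With ``config.outdir`` set, stage tables (profiles, conservation
    membership, circos ribbons) and ``report.json`` are written there.
    Identical config and seed give an identical report.
    """
    if config.input_dir:
        bundle = _load_bundle(config)
    else:
        sim = config.sim or SimConfig(seed=config.seed)
        bundle = simulate_bundle(sim)

    profiles: dict[str, pb.SpeciesProfile] = {}
    report: dict = {"parameters": _parameters(config), "species": {}}
    for sp in bundle.counts:
        profile, frag = _species_stage(
            sp, bundle.counts[sp], bundle.lengths[sp], config
        )
        profiles[sp] = profile
        report["species"][sp] = frag

    collection = cross_species.harmonize_symbols(
        profiles, bundle.truth.ortholog_map
    )
    report["unmapped_per_species"] = {
        sp: len(v) for sp, v in collection.unmapped.items()
    }
    overlaps = cross_species.all_pairwise_overlaps(collection)
    report["pairwise_overlaps"] = {
        f"{a}&{b}": v.counts | {"overlap": len(v.shared)}
        for (a, b), v in overlaps.items()
    }
    cons = cross_species.conservation(collection, lenient_k=config.lenient_k)
    report["conservation"] = {
        "union": len(cons.union),
        "lenient": len(cons.lenient),
        "core": len(cons.core),
        "membership_table": cons.membership_table(),
    }

    if bundle.signature is not None:
        report["signature_overlap_lenient"] = cross_species.signature_overlap(
            cons.lenient, bundle.signature
        )
        report["signature_overlap_core"] = cross_species.signature_overlap(
            cons.core, bundle.signature
        )

    circos_df = None
    if config.run_go and bundle.ontology is not None and bundle.annotations is not None:
        go_frag, circos_df = _go_stage(profiles, collection, bundle, config)
        report["go"] = go_frag

    if bundle.truth.tier_of:
        report["recovery"] = _recovery(cons, bundle)

    if config.outdir:
        _write_outputs(config, profiles, cons, circos_df, report)
    return report


def _go_stage(profiles, collection, bundle, config):
    ontology = bundle.ontology
    annotations = bundle.annotations
    reference = go_collapse.reference_nodes(ontology)
    annotated = annotations.genes()
    frag: dict = {"n_reference_terms": len(reference), "per_species": {}}
    counts_per_species: dict[str, dict[str, int]] = {}
    for sp in collection.profiles:
        background = {
            s for s in (
                bundle.truth.ortholog_map.by_species.get(sp, {}).values()
                if bundle.truth.ortholog_map is not None
                else annotated
            )
        } & annotated
        gene_set = collection.profiles[sp] & background
        if not gene_set:
            frag["per_species"][sp] = {"n_enriched_terms": 0}
            continue
        result = go_collapse.enrich(
            gene_set, background, annotations, ontology,
            p_max=config.go_p, q_max=config.go_q,
        )
        collapsed = go_collapse.collapse_terms(result, ontology, reference)
        raw_hits = go_collapse.hit_lists(gene_set, annotations, ontology)
        counts = go_collapse.unique_gene_counts(collapsed, raw_hits)
        counts_per_species[sp] = counts
        frag["per_species"][sp] = {
            "n_tested_terms": int(len(result.tested)),
            "n_enriched_terms": int(len(result.significant)),
            "n_reference_terms_hit": len(counts),
            "unique_genes_per_reference": {
                ontology.name(t): c for t, c in sorted(counts.items())
            },
        }
    circos_df = (
        go_collapse.circos_export(counts_per_species, ontology)
        if counts_per_species
        else None
    )
    return frag, circos_df


def _recovery(cons: cross_species.ConservationResult, bundle: SimBundle) -> dict:
    """Planted-truth recovery metrics (only meaningful for synthetic runs)."""
    truth = bundle.truth
    true_core = truth.symbols_in_tier("core")
    true_lenient_all = true_core | truth.symbols_in_tier("lenient")
    all_symbols = set(truth.tier_of)
    rec_core = cons.core
    rec_lenient = cons.lenient
    tp = len(rec_core & true_core)
    fp = len(rec_core - true_core)
    neg = all_symbols - true_core
    return {
        "core_sensitivity": tp / len(true_core) if true_core else 0.0,
        "core_specificity": (len(neg) - fp) / len(neg) if neg else 1.0,
        "lenient_sensitivity": (
            len(rec_lenient & true_lenient_all) / len(true_lenient_all)
            if true_lenient_all
            else 0.0
        ),
        "n_true_core": len(true_core),
        "n_recovered_core": len(rec_core),
        "n_recovered_lenient": len(rec_lenient),
        "core_subset_of_lenient": rec_core <= rec_lenient,
    }


def _parameters(config: PipelineConfig) -> dict:
    d = asdict(config)
    # paths are run bookkeeping, not analysis parameters; keeping them out
    # makes reports with identical settings byte-identical
    for key in ("sim", "outdir", "input_dir"):
        d.pop(key, None)
    return d


def _write_outputs(config, profiles, cons, circos_df, report) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, profile in profiles.items():
        if len(profile.flags):
            profile.flags.sort_index().to_csv(
                outdir / f"{sp}.profile.tsv", sep="\t"
            )
        else:
            pd.DataFrame(
                {"gene": sorted(profile.genes)}
            ).to_csv(outdir / f"{sp}.profile.tsv", sep="\t", index=False)
    rows = [
        (sym, len(spp), ";".join(sorted(spp)))
        for sym, spp in sorted(cons.membership.items())
    ]
    pd.DataFrame(rows, columns=["symbol", "n_species", "species"]).to_csv(
        outdir / "conservation.tsv", sep="\t", index=False
    )
    if circos_df is not None:
        circos_df.to_csv(outdir / "circos_ribbons.tsv", sep="\t", index=False)
    write_json(report, outdir / "report.json")
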