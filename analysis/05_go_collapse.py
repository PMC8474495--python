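"""Functional comparison of the species profiles: hypergeometric GO
enrichment (p < 0.05, q < 0.1), collapse of enriched terms onto the
reference layer (terms within two is_a steps of the root) and unique-gene
counting per reference term — the table a circos ribbon plot draws.
"""

from pathlib import Path

import pandas as pd

from microcore import go_collapse
from microcore.io_formats import read_annotations, read_obo, read_ortholog_map

RESULTS = Path(__file__).resolve().parents[1] / "results"


def _read_profile(path: Path) -> set[str]:
    df = pd.read_csv(path, sep="\t")
    if "retained" in df.columns:
        return set(df.loc[df["retained"], df.columns[0]])
    return set(df.iloc[:, 0])


def main() -> None:
    data = RESULTS / "data"
    ontology = read_obo(data / "ontology.obo")
    annotations = read_annotations(data / "annotations.tsv", ontology)
    omap = read_ortholog_map(data / "orthologs.tsv")
    reference = go_collapse.reference_nodes(ontology)
    print(f"reference layer: {len(reference)} terms within 2 steps of the root")

    annotated = annotations.genes()
    counts_per_species = {}
    for path in sorted(RESULTS.glob("*.profile.tsv")):
        sp = path.name.removesuffix(".profile.tsv")
        mapping = omap.by_species.get(sp, {})
        background = set(mapping.values()) & annotated
        gene_set = {
            mapping[g] for g in _read_profile(path) if g in mapping
        } & background
        if not gene_set:
            continue
        result = go_collapse.enrich(gene_set, background, annotations, ontology)
        collapsed = go_collapse.collapse_terms(result, ontology, reference)
        hits = go_collapse.hit_lists(gene_set, annotations, ontology)
        counts = go_collapse.unique_gene_counts(collapsed, hits)
        counts_per_species[sp] = counts
        top = sorted(((t, c) for t, c in counts.items() if c > 0),
                     key=lambda kv: -kv[1])[:3]
        named = ", ".join(f"{ontology.name(t)} ({c})" for t, c in top)
        print(f"{sp}: {len(result.significant)} enriched terms collapse onto "
              f"{len(counts)} reference terms; top: {named}")

    ribbons = go_collapse.circos_export(counts_per_species, ontology)
    out = RESULTS / "circos_ribbons.tsv"
    ribbons.to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
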