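"""Derive the core microglia profile of every species.

The focal species (two sorted cohorts) gets the full quantitative
procedure: top-decile sets after tissue subtraction, Δ-percentile
concordance filter (< 20) and microglia-specificity filter (> 60% of the
three-group expression), unioned with the DE-enriched genes
(FDR < 0.001, log2FC > 3). Single-cohort species contribute their
DE-enriched gene lists at the same thresholds.
"""

import json
from pathlib import Path

from microcore.pipeline import PipelineConfig, _species_stage
from microcore.io_formats import read_count_table, read_gene_lengths

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = RESULTS / "data"
    config = PipelineConfig()
    species = sorted(p.name.removesuffix(".counts.tsv")
                     for p in data.glob("*.counts.tsv"))
    summary = {}
    for sp in species:
        counts = read_count_table(
            data / f"{sp}.counts.tsv", data / f"{sp}.cohorts.tsv"
        )
        lengths = read_gene_lengths(data / f"{sp}.lengths.tsv")
        profile, frag = _species_stage(sp, counts, lengths, config)
        summary[sp] = frag
        out = RESULTS / f"{sp}.profile.tsv"
        if len(profile.flags):
            profile.flags.sort_index().to_csv(out, sep="\t")
        else:
            out.write_text("gene\n" + "\n".join(sorted(profile.genes)) + "\n")
        src = frag["profile_source"]
        print(f"{sp}: {frag['profile_size']} profile genes ({src}; "
              f"{frag['n_de_enriched']} DE-enriched)")
        if "attrition" in frag:
            print(f"  candidate attrition: {frag['attrition']}")
    (RESULTS / "species_profiles.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    print(f"wrote per-species profiles and {RESULTS / 'species_profiles.json'}")


if __name__ == "__main__":
    main()
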