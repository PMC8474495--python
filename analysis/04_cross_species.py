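"""Intersect the species profiles into pairwise overlaps, the lenient
subset (>= 3 of 4 species) and the evolutionary preserved core (all
species), and score the overlap with the tiered external signature.
"""

import json
from pathlib import Path

import pandas as pd

from microcore import cross_species
from microcore.io_formats import read_gene_set, read_ortholog_map

RESULTS = Path(__file__).resolve().parents[1] / "results"


def _read_profile(path: Path) -> set[str]:
    df = pd.read_csv(path, sep="\t")
    if "retained" in df.columns:
        return set(df.loc[df["retained"], df.columns[0]])
    return set(df.iloc[:, 0])


def main() -> None:
    data = RESULTS / "data"
    profiles = {
        p.name.removesuffix(".profile.tsv"): _read_profile(p)
        for p in sorted(RESULTS.glob("*.profile.tsv"))
    }
    omap = read_ortholog_map(data / "orthologs.tsv")
    coll = cross_species.harmonize_symbols(profiles, omap)
    cons = cross_species.conservation(coll)

    print("pairwise profile overlaps (shared symbols):")
    for (a, b), v in cross_species.all_pairwise_overlaps(coll).items():
        print(f"  {a} & {b}: {len(v.shared)}")
    print(f"lenient subset (>= 3 of {len(profiles)} species): {len(cons.lenient)}")
    print(f"evolutionary preserved core (all species): {len(cons.core)}")

    sig_df = pd.read_csv(data / "signature.tsv", sep="\t", dtype=str)
    signature = dict(zip(sig_df.iloc[:, 0], sig_df.iloc[:, 1]))
    overlap = cross_species.signature_overlap(cons.lenient, signature)
    assigned = 100 - overlap["unassigned"]["pct"]
    print(f"lenient subset vs external tiered signature: {assigned:.0f}% overlap "
          f"(high {overlap['high']['pct']:.0f}%, "
          f"intermediate {overlap['intermediate']['pct']:.0f}%, "
          f"low {overlap['low']['pct']:.0f}%)")

    out = RESULTS / "conservation.json"
    out.write_text(json.dumps(
        {
            "membership_table": cons.membership_table(),
            "lenient": sorted(cons.lenient),
            "core": sorted(cons.core),
            "signature_overlap_lenient": overlap,
        },
        indent=2, sort_keys=True,
    ) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
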