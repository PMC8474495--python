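"""Readers and writers for every external representation the pipeline touches.

All tabular formats are tab-separated UTF-8 with a header row; lines starting
with ``#`` are comments. Gene identity is the symbol string (exact,
case-sensitive); species-local identifiers are aliased to shared symbols
through an :class:`OrthologMap`.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "CountTable",
    "GeneLengthTable",
    "OrthologMap",
    "OntologyGraph",
    "AnnotationTable",
    "read_count_table",
    "write_count_table",
    "read_cohort_map",
    "read_gene_lengths",
    "write_gene_lengths",
    "gene_lengths_from_gff",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_obo",
    "write_obo",
    "read_annotations",
    "write_annotations",
    "read_de_table",
    "write_de_table",
    "read_gene_set",
    "write_gene_set",
]


class FormatError(ValueError):
    """An external file violates its format contract."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Gene-by-sample integer counts with a cohort label per sample.

    ``counts`` is a genes x samples DataFrame of non-negative integers;
    ``cohort_of`` maps every sample id to its cohort label.
    """

    counts: pd.DataFrame
    cohort_of: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        missing = [s for s in cols if s not in self.cohort_of]
        if missing:
            raise FormatError(f"sample {missing[0]!r} has no cohort label")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("count matrix contains non-numeric values")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count at gene {idx[g]!r}, sample {cols[s]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            g, s = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
            raise FormatError(
                f"non-integral count at gene {idx[g]!r}, sample {cols[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def cohorts(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.cohort_of[s], None)
        return list(seen)

    def samples_in(self, cohort: str) -> list[str]:
        out = [s for s in self.sample_ids if self.cohort_of[s] == cohort]
        if not out:
            raise KeyError(f"unknown cohort {cohort!r}")
        return out


@dataclass
class GeneLengthTable:
    """gene id -> length in base pairs (exon-union convention)."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for g, length in self.lengths.items():
            if length <= 0:
                raise FormatError(f"non-positive length for gene {g!r}")

    def __getitem__(self, gene: str) -> int:
        return self.lengths[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.lengths

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass
class OrthologMap:
    """Per-species one-to-one aliasing of local gene ids to shared symbols."""

    by_species: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for sp, m in self.by_species.items():
            rev: dict[str, str] = {}
            for gene, sym in m.items():
                if sym in rev and rev[sym] != gene:
                    raise FormatError(
                        f"species {sp!r}: symbol {sym!r} maps to both "
                        f"{rev[sym]!r} and {gene!r}"
                    )
                rev[sym] = gene

    def symbol(self, species: str, gene: str) -> str | None:
        return self.by_species.get(species, {}).get(gene)

    @classmethod
    def identity(cls, species: Iterable[str], genes: Iterable[str]) -> "OrthologMap":
        genes = list(genes)
        return cls({sp: {g: g for g in genes} for sp in species})


@dataclass
class OntologyGraph:
    """Rooted DAG of ontology terms; edges run child -> parent (is_a)."""

    graph: nx.DiGraph  # nodes carry a "name" attribute
    root: str

    def __post_init__(self) -> None:
        if self.root not in self.graph:
            raise FormatError(f"root term {self.root!r} absent from ontology")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise FormatError(f"ontology contains a cycle: {cycle}")
        no_path = [
            t
            for t in self.graph
            if t != self.root and not nx.has_path(self.graph, t, self.root)
        ]
        if no_path:
            raise FormatError(
                f"term {no_path[0]!r} has no path to root {self.root!r}"
            )

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def distance_to_root(self, term: str) -> int:
        return nx.shortest_path_length(self.graph, term, self.root)

    def ancestors_at(self, term: str, distance: int) -> set[str]:
        """Terms reachable from ``term`` in exactly ``distance`` is_a steps."""
        frontier = {term}
        for _ in range(distance):
            frontier = {p for t in frontier for p in self.graph.successors(t)}
        return frontier

    def ancestors(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term)  # child->parent orientation


@dataclass
class AnnotationTable:
    """Direct gene symbol -> ontology term annotations."""

    annotations: dict[str, frozenset[str]]

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.annotations.get(gene, frozenset())

    def genes(self) -> set[str]:
        return set(self.annotations)

    def validate_against(self, ontology: OntologyGraph) -> None:
        for gene, terms in self.annotations.items():
            unknown = terms - ontology.terms
            if unknown:
                raise FormatError(
                    f"gene {gene!r} annotated to unknown term {sorted(unknown)[0]!r}"
                )


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def read_cohort_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, cohort)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: cohort map needs two columns")
    sample_col, cohort_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        dup = df[sample_col][df[sample_col].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r} in cohort map")
    return dict(zip(df[sample_col], df[cohort_col]))


def _check_header_duplicates(path: Path) -> None:
    # pandas silently mangles duplicate column names; inspect the raw header
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")[1:]
            seen: set[str] = set()
            for c in cols:
                if c in seen:
                    raise FormatError(f"{path}: duplicate sample id {c!r}")
                seen.add(c)
            return


def read_count_table(
    path: str | Path, cohort_map_path: str | Path
) -> CountTable:
    """Read a genes x samples count matrix (TSV or MatrixMarket triplet).

    A ``.mtx`` path is read as a MatrixMarket file with sidecar ``rows.txt``
    and ``cols.txt`` id lists in the same directory.
    """
    path = Path(path)
    cohort_of = read_cohort_map(cohort_map_path)
    if path.suffix == ".mtx":
        rows = (path.parent / "rows.txt").read_text().split()
        cols = (path.parent / "cols.txt").read_text().split()
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        df = pd.DataFrame(np.asarray(mat), index=rows, columns=cols)
    else:
        _check_header_duplicates(path)
        try:
            df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        bad = df.select_dtypes(exclude="number").columns
        if len(bad):
            col = bad[0]
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise FormatError(
                f"{path}: non-numeric cell at gene {row!r}, sample {col!r}"
            )
        df.index = df.index.astype(str)
    df = df.astype(np.int64, errors="ignore")
    df.index.name = None
    df.columns.name = None
    missing = [s for s in df.columns if s not in cohort_of]
    if missing:
        raise FormatError(
            f"{path}: sample {missing[0]!r} present in matrix "
            "but absent from cohort map"
        )
    return CountTable(counts=df, cohort_of={s: cohort_of[s] for s in df.columns})


def write_count_table(
    table: CountTable,
    path: str | Path,
    cohort_map_path: str | Path,
    fmt: str = "tsv",
) -> None:
    path = Path(path)
    if fmt == "tsv":
        table.counts.to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(table.counts.to_numpy()))
        (path.parent / "rows.txt").write_text("\n".join(table.gene_ids) + "\n")
        (path.parent / "cols.txt").write_text("\n".join(table.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    pd.DataFrame(
        {"sample_id": table.sample_ids,
         "cohort": [table.cohort_of[s] for s in table.sample_ids]}
    ).to_csv(cohort_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene lengths
# ---------------------------------------------------------------------------


def read_gene_lengths(path: str | Path) -> GeneLengthTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: gene length table needs two columns")
    gcol, lcol = df.columns[:2]
    if df[gcol].duplicated().any():
        dup = df[gcol][df[gcol].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    return GeneLengthTable(dict(zip(df[gcol], df[lcol].astype(int))))


def write_gene_lengths(table: GeneLengthTable, path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(table.lengths), "length": list(table.lengths.values())}
    ).to_csv(path, sep="\t", index=False)


_GTF_GENE_ID = re.compile(r'gene_id[ =]"?([^";]+)"?')


def gene_lengths_from_gff(path: str | Path) -> GeneLengthTable:
    """Exon-union length per gene from a GFF3/GTF file.

    Overlapping exon intervals of one gene are merged before summing, so
    shared exons across transcript isoforms are counted once.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "exon":
                continue
            m = _GTF_GENE_ID.search(parts[8])
            if m is None:
                raise FormatError(f"exon record without gene_id: {line.strip()!r}")
            start, end = int(parts[3]), int(parts[4])
            exons.setdefault(m.group(1), []).append((start, end))
    lengths: dict[str, int] = {}
    for gene, ivals in exons.items():
        ivals.sort()
        total, cur_start, cur_end = 0, *ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_end + 1:
                cur_end = max(cur_end, e)
            else:
                total += cur_end - cur_start + 1
                cur_start, cur_end = s, e
        lengths[gene] = total + cur_end - cur_start + 1
    return GeneLengthTable(lengths)


# ---------------------------------------------------------------------------
# ortholog maps
# ---------------------------------------------------------------------------


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Three-column TSV: species, gene_id, symbol."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    by_species: dict[str, dict[str, str]] = {}
    for sp, gene, sym in df.itertuples(index=False):
        m = by_species.setdefault(sp, {})
        if gene in m and m[gene] != sym:
            raise FormatError(
                f"species {sp!r}: gene {gene!r} maps to both "
                f"{m[gene]!r} and {sym!r}"
            )
        m[gene] = sym
    return OrthologMap(by_species)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    rows = [
        (sp, gene, sym)
        for sp, m in omap.by_species.items()
        for gene, sym in m.items()
    ]
    pd.DataFrame(rows, columns=["species", "gene_id", "symbol"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# ontology + annotations
# ---------------------------------------------------------------------------


def read_obo(path: str | Path, root: str | None = None) -> OntologyGraph:
    """Load an OBO 1.2 ontology keeping [Term] stanzas and is_a edges.

    Obsolete terms are dropped (obonet's default). If ``root`` is None the
    unique term without an is_a parent is taken as root.
    """
    multi = obonet.read_obo(path)
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        g.add_node(node, name=data.get("name", node))
    for child, parent, key in multi.edges(keys=True):
        if key != "is_a":
            continue
        if parent not in multi.nodes or "name" not in multi.nodes[parent]:
            raise FormatError(f"is_a target {parent!r} is not a declared term")
        g.add_edge(child, parent)
    if root is None:
        sinks = [n for n in g if g.out_degree(n) == 0]
        if len(sinks) != 1:
            raise FormatError(
                f"expected a single root term, found {sorted(sinks)!r}"
            )
        root = sinks[0]
    return OntologyGraph(graph=g, root=root)


def write_obo(ontology: OntologyGraph, path: str | Path) -> None:
    lines = ["format-version: 1.2", f"ontology: {Path(path).stem}", ""]
    for term in sorted(ontology.graph.nodes):
        lines += ["[Term]", f"id: {term}", f"name: {ontology.name(term)}"]
        for parent in sorted(ontology.graph.successors(term)):
            lines.append(f"is_a: {parent} ! {ontology.name(parent)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_annotations(
    path: str | Path, ontology: OntologyGraph | None = None
) -> AnnotationTable:
    """Gene->term annotations from GAF 2.x (columns 2 and 5) or 2-column TSV."""
    path = Path(path)
    ann: dict[str, set[str]] = {}
    if path.suffix == ".gaf" or _looks_like_gaf(path):
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5:
                    raise FormatError(f"{path}: short GAF line {line.strip()!r}")
                ann.setdefault(parts[1], set()).add(parts[4])
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        gcol, tcol = df.columns[:2]
        for gene, term in zip(df[gcol], df[tcol]):
            ann.setdefault(gene, set()).add(term)
    table = AnnotationTable({g: frozenset(t) for g, t in ann.items()})
    if ontology is not None:
        table.validate_against(ontology)
    return table


def _looks_like_gaf(path: Path) -> bool:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return first.startswith("!gaf")


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    rows = [
        (gene, term)
        for gene in sorted(table.annotations)
        for term in sorted(table.annotations[gene])
    ]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DE tables and gene sets
# ---------------------------------------------------------------------------

_DE_ALIASES = {
    "gene": ("gene", "gene_id", "symbol"),
    "log2fc": ("log2fc", "log2foldchange", "logfc", "lfc"),
    "p": ("p", "pvalue", "p_value", "pval"),
    "fdr": ("fdr", "padj", "qvalue", "q", "adj_p"),
}


def read_de_table(
    path: str | Path, aliases: Mapping[str, tuple[str, ...]] | None = None
) -> pd.DataFrame:
    """Per-gene DE records as a DataFrame indexed by gene with columns
    ``log2fc``, ``p``, ``fdr``. Column-name aliases are case-insensitive."""
    alias = dict(_DE_ALIASES)
    if aliases:
        alias.update({k: tuple(v) for k, v in aliases.items()})
    df = pd.read_csv(path, sep="\t", comment="#")
    lower = {c.lower(): c for c in df.columns}
    resolved = {}
    for canon, names in alias.items():
        for n in names:
            if n.lower() in lower:
                resolved[canon] = lower[n.lower()]
                break
        else:
            raise FormatError(f"{path}: missing required column {canon!r}")
    out = df[[resolved[c] for c in ("gene", "log2fc", "p", "fdr")]].copy()
    out.columns = ["gene", "log2fc", "p", "fdr"]
    out = out.set_index("gene")
    out = out.astype(float)
    for col in ("p", "fdr"):
        bad = out.index[(out[col] < 0) | (out[col] > 1)]
        if len(bad):
            raise FormatError(
                f"{path}: {col} outside [0,1] for gene {bad[0]!r}"
            )
    return out


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index_label="gene")


def read_gene_set(path: str | Path) -> set[str]:
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split("\t")[0])
    return out


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer used for all report artifacts."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
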