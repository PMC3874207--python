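"""Position weight matrix library and motif-to-gene resolution.

A PWM library aggregated from several catalogues (JASPAR, UniPROBE,
HT-SELEX, custom) is the substrate for interpreting de novo enriched
motifs: each library motif resolves to one or more transcription factor
genes, genes resolve across species through an ortholog map, and genes
carry a structural classification (superclass / class / family /
optional subclass) parsed from an OBO ontology.

Matrices are stored as given (counts or frequencies, 4 x L, rows in
fixed A,C,G,T order). No scanning or scoring is performed here, so no
pseudocounts are applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from trmkit._util import warn

ALPHABET = ("A", "C", "G", "T")
SOURCES = ("jaspar", "uniprobe", "htselex", "custom")


class PWMParseError(ValueError):
    """Raised for structurally invalid matrix files (names file and motif)."""


@dataclass(frozen=True)
class PWMatrix:
    """One position weight matrix: 4 x L nonnegative counts/frequencies."""

    motif_id: str
    source: str
    matrix: np.ndarray
    species: str

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4:
            raise PWMParseError(
                f"motif {self.motif_id!r}: matrix must have 4 rows (A,C,G,T), "
                f"got shape {m.shape}"
            )
        if m.shape[1] < 1:
            raise PWMParseError(f"motif {self.motif_id!r}: zero-length matrix")
        if (m < 0).any():
            raise PWMParseError(f"motif {self.motif_id!r}: negative matrix entry")
        object.__setattr__(self, "matrix", m)
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PWMCollection:
    """A keyed set of PWMs with per-source bookkeeping."""

    matrices: dict[str, PWMatrix] = field(default_factory=dict)

    @property
    def per_source_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.matrices.values():
            counts[m.source] = counts.get(m.source, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.matrices)

    def __contains__(self, motif_id: str) -> bool:
        return motif_id in self.matrices

    def __getitem__(self, motif_id: str) -> PWMatrix:
        return self.matrices[motif_id]


@dataclass
class MotifGeneMap:
    """motif_id -> set of (gene, species) pairs.

    The species tag per gene lets downstream mapping decide which genes
    need routing through the ortholog map to reach the target species.
    """

    pairs: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def genes_for(self, motif_id: str) -> set[tuple[str, str]]:
        return set(self.pairs.get(motif_id, set()))


@dataclass
class OrthologMap:
    """(gene, source species) -> set of (gene, target species).

    Lookups for unmapped genes return the empty set; no symmetric
    closure is assumed.
    """

    pairs: dict[tuple[str, str], set[tuple[str, str]]] = field(default_factory=dict)

    def lookup(self, gene: str, species: str, target_species: str) -> set[str]:
        hits = self.pairs.get((gene, species), set())
        return {g for g, sp in hits if sp == target_species}


@dataclass
class TFClassAnnotation:
    """gene -> (superclass, class, family, subclass-or-None) lineage."""

    hierarchy: dict[str, tuple[str, str, str, str | None]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.hierarchy)


# ---------------------------------------------------------------------------
# Matrix file parsing

def _parse_number_row(line: str):
    toks = line.replace("[", " ").replace("]", " ").split()
    # JASPAR rows may be prefixed with the base letter: "A [ 3 5 0 ]"
    if toks and toks[0].upper() in ALPHABET:
        toks = toks[1:]
    return [float(t) for t in toks]


def _parse_jaspar_pfm(path: Path) -> list[tuple[str, list[list[float]]]]:
    """Parse a JASPAR PFM file: '>' header then 4 nucleotide rows per motif."""
    motifs: list[tuple[str, list[list[float]]]] = []
    name = None
    rows: list[list[float]] = []

    def flush():
        if name is None:
            return
        if len(rows) != 4:
            raise PWMParseError(
                f"{path}: motif {name!r} has {len(rows)} rows, expected 4"
            )
        if len({len(r) for r in rows}) != 1:
            raise PWMParseError(f"{path}: motif {name!r} has ragged rows")
        motifs.append((name, [list(r) for r in rows]))

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0]
            rows = []
        else:
            if name is None:
                raise PWMParseError(f"{path}: matrix rows before any '>' header")
            try:
                rows.append(_parse_number_row(line))
            except ValueError as exc:
                raise PWMParseError(f"{path}: motif {name!r}: bad row {line!r}") from exc
    flush()
    return motifs


def _parse_matrix_tsv(path: Path) -> list[tuple[str, list[list[float]]]]:
    """Parse a generic PWM TSV: columns motif_id, base, p1..pL."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise PWMParseError(f"{path}: expected columns motif_id, base, p1..pL")
    id_col, base_col = df.columns[0], df.columns[1]
    motifs = []
    for motif_id, grp in df.groupby(id_col, sort=False):
        bases = [str(b).upper() for b in grp[base_col]]
        if sorted(bases) != sorted(ALPHABET) or list(bases) != list(ALPHABET):
            raise PWMParseError(
                f"{path}: motif {motif_id!r}: rows must be exactly A,C,G,T in order, "
                f"got {bases}"
            )
        vals = grp.iloc[:, 2:].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise PWMParseError(f"{path}: motif {motif_id!r}: ragged or missing cells")
        motifs.append((str(motif_id), vals.tolist()))
    return motifs


def load_pwm_set(files: Sequence[str | Path], source: str, species: str) -> PWMCollection:
    """Load PWM files (JASPAR PFM or generic 4-row TSV) into one collection.

    Duplicate motif ids within one call are an error; cross-source
    collisions are handled later by :func:`merge_pwm_sources`.
    """
    coll = PWMCollection()
    for f in files:
        path = Path(f)
        text_head = path.read_text().lstrip()
        parsed = (
            _parse_jaspar_pfm(path) if text_head.startswith(">") else _parse_matrix_tsv(path)
        )
        for motif_id, rows in parsed:
            if motif_id in coll.matrices:
                raise PWMParseError(f"{path}: duplicate motif id {motif_id!r}")
            try:
                pwm = PWMatrix(motif_id=motif_id, source=source,
                               matrix=np.asarray(rows, dtype=float), species=species)
            except PWMParseError as exc:
                raise PWMParseError(f"{path}: {exc}") from exc
            coll.matrices[motif_id] = pwm
    return coll


def merge_pwm_sources(collections: Sequence[PWMCollection]) -> PWMCollection:
    """Union of collections keyed by motif_id.

    An id present in more than one source is kept under both
    source-suffixed keys ``<id>@<source>`` so that no catalogue silently
    overwrites another. Total size equals the sum of the inputs.
    """
    if not collections:
        raise ValueError("no collections to merge")
    # Which ids collide across sources?
    seen: dict[str, int] = {}
    for coll in collections:
        for mid in coll.matrices:
            seen[mid] = seen.get(mid, 0) + 1
    merged = PWMCollection()
    for coll in collections:
        for mid, pwm in coll.matrices.items():
            key = f"{mid}@{pwm.source}" if seen[mid] > 1 else mid
            if key in merged.matrices:
                raise ValueError(f"motif id collision within one source: {key!r}")
            merged.matrices[key] = pwm
    return merged


# ---------------------------------------------------------------------------
# TFClass ontology

_LEVELS = ("superclass", "class", "family", "subclass", "gene", "factor_species")


def _term_level(data: Mapping) -> str | None:
    subs = data.get("subset", [])
    for s in subs:
        if s in _LEVELS:
            return s
    return None


def parse_tfclass_obo(obo: str | Path) -> TFClassAnnotation:
    """Parse a TF structural-classification ontology (OBO 1.2).

    Terms carry their classification level in the ``subset`` tag
    (superclass, class, family, subclass, gene, factor_species).
    Factor-species terms (protein isoforms) are removed before gene
    resolution — the gene is the basic analysis unit. Cyclic ``is_a``
    links are an error; orphan non-root terms are skipped with a warning.
    """
    graph = obonet.read_obo(obo, ignore_obsolete=True)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("cyclic is_a relationship in ontology")

    # drop isoform-level records entirely
    drop = [n for n, d in graph.nodes(data=True) if _term_level(d) == "factor_species"]
    graph.remove_nodes_from(drop)

    ann = TFClassAnnotation()
    for node, data in graph.nodes(data=True):
        level = _term_level(data)
        if level is None:
            warn(f"term {node} has no recognized level annotation; skipped")
            continue
        if level != "superclass" and graph.out_degree(node) == 0:
            warn(f"orphan term {node} ({level}) has no is_a parent; skipped")
            continue
        if level != "gene":
            continue
        lineage: dict[str, str] = {}
        for anc in nx.descendants(graph, node):  # edges point child -> parent
            anc_level = _term_level(graph.nodes[anc])
            if anc_level in ("superclass", "class", "family", "subclass"):
                lineage[anc_level] = graph.nodes[anc].get("name", anc)
        if "superclass" not in lineage or "class" not in lineage:
            warn(f"gene term {node} lacks a complete lineage; skipped")
            continue
        gene = data.get("name", node)
        ann.hierarchy[gene] = (
            lineage["superclass"],
            lineage["class"],
            lineage.get("family", ""),
            lineage.get("subclass"),
        )
    return ann


# ---------------------------------------------------------------------------
# Mapping tables

def read_motif_gene_map(path: str | Path) -> MotifGeneMap:
    """Read a motif->gene TSV with columns motif_id, gene, species."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"motif_id", "gene", "species"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    gm = MotifGeneMap()
    for row in df.itertuples(index=False):
        gm.pairs.setdefault(row.motif_id, set()).add((row.gene, row.species))
    return gm


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read an ortholog TSV with columns gene, species, ortholog, ortholog_species."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "species", "ortholog", "ortholog_species"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    om = OrthologMap()
    for row in df.itertuples(index=False):
        om.pairs.setdefault((row.gene, row.species), set()).add(
            (row.ortholog, row.ortholog_species)
        )
    return om


def map_motifs_to_genes(
    motifs: Iterable[str],
    gene_map: MotifGeneMap,
    ortho: OrthologMap,
    target_species: str,
) -> set[str]:
    """Resolve motif ids to target-species genes.

    Genes annotated in the target species pass through directly; genes of
    other species are translated via the ortholog map (one-to-many
    mappings expand to all targets — over-inclusion is corrected by the
    downstream expression filter). Motifs with no mapping, and foreign
    genes with no ortholog, are reported with a warning, never an error.
    """
    motifs = set(motifs)
    if not motifs:
        raise ValueError("empty motif set")
    out: set[str] = set()
    unmapped: list[str] = []
    for m in sorted(motifs):
        hits = gene_map.genes_for(m)
        if not hits:
            unmapped.append(m)
            continue
        mapped_any = False
        for gene, sp in hits:
            if sp == target_species:
                out.add(gene)
                mapped_any = True
            else:
                orthos = ortho.lookup(gene, sp, target_species)
                if orthos:
                    out |= orthos
                    mapped_any = True
        if not mapped_any:
            unmapped.append(m)
    if unmapped:
        warn(f"motifs with no {target_species} gene mapping: {sorted(set(unmapped))}")
    return out


def annotate_tf_class(
    genes: Iterable[str],
    ann: TFClassAnnotation,
    ortho: OrthologMap,
    species: str = "mouse",
    ann_species: str = "human",
) -> dict[str, tuple[str, str, str, str | None] | str]:
    """Assign each gene a structural-class lineage, directly or via ortholog.

    Genes without a direct entry are looked up through their
    ``ann_species`` orthologs; genes still unresolved are flagged
    ``"unclassified"``.
    """
    table: dict[str, tuple[str, str, str, str | None] | str] = {}
    for g in sorted(set(genes)):
        if g in ann.hierarchy:
            table[g] = ann.hierarchy[g]
            continue
        lineage = None
        for og in sorted(ortho.lookup(g, species, ann_species)):
            if og in ann.hierarchy:
                lineage = ann.hierarchy[og]
                break
        table[g] = lineage if lineage is not None else "unclassified"
    return table


def db_summary(collection: PWMCollection, gene_map: MotifGeneMap) -> dict:
    """Counts of motifs per source, total motifs and distinct genes covered."""
    genes = set()
    for mid in collection.matrices:
        base = mid.split("@")[0]
        for key in (mid, base):
            genes |= {g for g, _sp in gene_map.genes_for(key)}
    return {
        "per_source": collection.per_source_counts,
        "total_motifs": len(collection),
        "distinct_genes": len(genes),
    }


def summary_to_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
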