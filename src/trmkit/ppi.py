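"""Assembly of the cleaned physical protein-protein interaction graph.

Interaction tables (BioGRID TAB3-style TSV) are filtered down to
physical interactions, stripped of the promiscuous ubiquitination and
sumoylation moieties (Ubc, Sumo1-3), collapsed to a simple undirected
graph with per-edge evidence multiplicity, and finally restricted to the
proteins whose genes are expressed in the cell type under study.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from trmkit._util import warn

#: Ubiquitin/SUMO moieties attached to many proteins as modifications,
#: not genuine complex partners.
DEFAULT_EXCLUDED_NODES = frozenset({"Ubc", "Sumo1", "Sumo2", "Sumo3"})

#: Default column names for BioGRID TAB3 exports. Use ``symbol`` variants
#: to key the graph by official symbols instead of Entrez ids.
BIOGRID_TAB3_COLUMNS = {
    "gene_a": "Entrez Gene Interactor A",
    "gene_b": "Entrez Gene Interactor B",
    "system_type": "Experimental System Type",
    "organism_a": "Organism ID Interactor A",
    "organism_b": "Organism ID Interactor B",
}


@dataclass(frozen=True)
class InteractionRecord:
    gene_a: str
    gene_b: str
    system_type: str  # physical | genetic | other labels (dropped downstream)
    source_line: int

    def __post_init__(self):
        if not self.gene_a or not self.gene_b:
            raise ValueError("empty interactor id")


def parse_interactions(
    path: str | Path,
    organism: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> list[InteractionRecord]:
    """Read a BioGRID TAB-style TSV into interaction records.

    With an ``organism`` filter, a row is kept only when both interactors
    belong to that organism. Rows with an empty interactor id are dropped
    with a warning; missing required columns are an error.
    """
    cols = dict(BIOGRID_TAB3_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [cols["gene_a"], cols["gene_b"], cols["system_type"]]
    if organism is not None:
        required += [cols["organism_a"], cols["organism_b"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    records: list[InteractionRecord] = []
    n_empty = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        rec = dict(zip(df.columns, row))
        a, b = rec[cols["gene_a"]], rec[cols["gene_b"]]
        if pd.isna(a) or pd.isna(b) or not str(a).strip() or not str(b).strip():
            n_empty += 1
            continue
        if organism is not None and not (
            str(rec[cols["organism_a"]]) == str(organism)
            and str(rec[cols["organism_b"]]) == str(organism)
        ):
            continue
        records.append(
            InteractionRecord(
                gene_a=str(a).strip(),
                gene_b=str(b).strip(),
                system_type=str(rec[cols["system_type"]]).strip().lower(),
                source_line=i,
            )
        )
    if n_empty:
        warn(f"{path}: dropped {n_empty} row(s) with empty interactor id")
    return records


def filter_physical(records: Iterable[InteractionRecord]) -> list[InteractionRecord]:
    """Keep physical interactions only; genetic and unrecognized labels are dropped."""
    records = list(records)
    kept = [r for r in records if r.system_type == "physical"]
    unknown = sorted({r.system_type for r in records} - {"physical", "genetic"})
    if unknown:
        warn(f"dropped records with unknown system type(s): {unknown}")
    if records and not kept:
        warn("no physical interactions remain after filtering")
    return kept


def remove_excluded_nodes(
    records: Iterable[InteractionRecord],
    excluded: set[str] | frozenset[str] = DEFAULT_EXCLUDED_NODES,
) -> list[InteractionRecord]:
    """Drop any record touching an excluded gene (default: Ubc, Sumo1-3)."""
    return [r for r in records if r.gene_a not in excluded and r.gene_b not in excluded]


def build_graph(records: Iterable[InteractionRecord]) -> nx.Graph:
    """Collapse records to a simple undirected graph with multiplicity.

    A-B and B-A records collapse onto one unordered edge whose
    ``multiplicity`` attribute counts the supporting records. Self
    records (A-A) are stored as edges flagged ``self_loop`` and are never
    traversed by the module search.
    """
    g = nx.Graph()
    for r in records:
        if g.has_edge(r.gene_a, r.gene_b):
            g[r.gene_a][r.gene_b]["multiplicity"] += 1
        else:
            g.add_edge(r.gene_a, r.gene_b, multiplicity=1, self_loop=(r.gene_a == r.gene_b))
    return g


def restrict_to_expressed(graph: nx.Graph, expressed: set[str]) -> nx.Graph:
    """Induced subgraph on expressed genes; edge multiplicities preserved."""
    return graph.subgraph(set(graph.nodes) & set(expressed)).copy()


def without_self_loops(graph: nx.Graph) -> nx.Graph:
    g = graph.copy()
    g.remove_edges_from(list(nx.selfloop_edges(g)))
    return g


def write_edgelist_tsv(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tmultiplicity\n")
        for a, b, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{a}\t{b}\t{data.get('multiplicity', 1)}\n")


def read_edgelist_tsv(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(
            row.gene_a, row.gene_b,
            multiplicity=int(getattr(row, "multiplicity", 1)),
            self_loop=(row.gene_a == row.gene_b),
        )
    return g


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))
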