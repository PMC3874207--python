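"""Hypergeometric enrichment of annotation terms in module gene sets.

Given an annotation table (term -> genes, e.g. mouse knockout phenotype
annotations), the over-representation of each term among a module's
genes is scored with the upper tail of the hypergeometric distribution:
P(X >= k) for X ~ Hypergeometric(N, K, n), where N is the universe size,
K the annotated genes in the universe, n the query size and k the
overlap. This is the classic one-sided over-representation test
(equivalent to ``phyper(k-1, K, N-K, n, lower.tail=FALSE)`` in R).

P-values are reported raw by default (significance at p < alpha,
strict); an optional Benjamini-Hochberg correction is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from trmkit._util import warn


@dataclass
class AnnotationTable:
    term_to_genes: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        empty = [t for t, g in self.term_to_genes.items() if not g]
        if empty:
            raise ValueError(f"terms with empty gene sets: {empty}")

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.term_to_genes.values():
            out |= genes
        return out


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    k: int  # annotated genes in the query
    K: int  # annotated genes in the universe
    n: int  # query genes in the universe
    N: int  # universe size
    p_value: float
    significant: bool
    p_adjusted: float | None = None


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a sample of ``n`` drawn without
    replacement from a universe of ``N`` genes of which ``K`` are
    annotated. Computed via the survival function (log-space internally),
    so it is stable for large parameters. ``k = 0`` returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent parameters K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    query: Iterable[str],
    annotations: AnnotationTable,
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Score every term overlapping the query; sorted by ascending p-value.

    The universe defaults to all genes in the annotation table. Query
    genes outside the universe are dropped with a warning. Terms with no
    query overlap (k = 0) are omitted. With ``adjust=True`` a
    Benjamini-Hochberg adjusted p-value is added; the significance flag
    always uses the raw p-value (strict p < alpha).
    """
    universe = set(universe) if universe is not None else annotations.all_genes
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query)
    outside = query - universe
    if outside:
        warn(f"{len(outside)} query gene(s) outside the universe dropped")
    query &= universe
    N, n = len(universe), len(query)

    results = []
    for term in sorted(annotations.term_to_genes):
        term_genes = annotations.term_to_genes[term] & universe
        K = len(term_genes)
        k = len(term_genes & query)
        if k == 0:
            continue
        p = hypergeom_upper(k, K, n, N)
        results.append(
            EnrichmentResult(
                term=term, name=annotations.term_names.get(term, ""),
                k=k, K=K, n=n, N=N, p_value=p, significant=p < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    if adjust and results:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        results = [
            EnrichmentResult(**{**r.__dict__, "p_adjusted": float(q)})
            for r, q in zip(results, p_adj)
        ]
    return results


def count_annotated(
    query: Iterable[str], annotations: AnnotationTable, terms: Iterable[str]
) -> tuple[int, float]:
    """Count (and fraction of) query genes annotated to at least one term."""
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")
    annotated: set[str] = set()
    for t in terms:
        annotated |= annotations.term_to_genes.get(t, set())
    k = len(query & annotated)
    return k, k / len(query)


# ---------------------------------------------------------------------------
# IO

def load_annotation_tsv(
    path: str | Path, names_path: str | Path | None = None
) -> AnnotationTable:
    """Load a 2-column (term, gene) annotation TSV, plus optional term names."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"term", "gene"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'term' and 'gene'")
    table: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        table.setdefault(row.term, set()).add(row.gene)
    names: dict[str, str] = {}
    if names_path is not None:
        nd = pd.read_csv(names_path, sep="\t", dtype=str)
        names = dict(zip(nd.iloc[:, 0], nd.iloc[:, 1]))
    return AnnotationTable(term_to_genes=table, term_names=names)


#: Phenotype categories in the bundled curated tables, keyed by the
#: shorthand used in the source tables.
PHENOTYPE_TERMS = {
    "esc": {
        "Complete": "MP:0011096",  # complete embryonic lethality, implantation-somites
        "Partial": "MP:0011106",   # partial embryonic lethality, implantation-somites
    },
    "hsc": {
        "Hematopoiesis": "MP:0001606",  # impaired/abnormal hematopoiesis
        "Lymphopoiesis": "MP:0002401",  # abnormal lymphopoiesis
        "Morphology": "MP:0002429",     # abnormal blood cell morphology/development
    },
}

PHENOTYPE_TERM_NAMES = {
    "MP:0011096": "complete embryonic lethality between implantation and somite formation",
    "MP:0011106": "partial embryonic lethality between implantation and somite formation",
    "MP:0001606": "impaired hematopoiesis",
    "MP:0002123": "abnormal hematopoiesis",
    "MP:0002401": "abnormal lymphopoiesis",
    "MP:0002429": "abnormal blood cell morphology/development",
}


def load_bundled_phenotypes(which: str) -> tuple[AnnotationTable, pd.DataFrame]:
    """Load a bundled curated phenotype table ('esc' or 'hsc').

    Returns the annotation table (terms keyed by MP ids) and the raw
    curated table (Entrez id, symbol, phenotype categories). The ESC
    table lists embryonic-lethal knockouts among ESC-module proteins; the
    HSC table lists knockouts with impaired/abnormal hematopoiesis among
    HSC-module proteins.
    """
    if which not in PHENOTYPE_TERMS:
        raise ValueError(f"unknown table {which!r}; expected 'esc' or 'hsc'")
    fname = {"esc": "esc_embryonic_lethal.tsv", "hsc": "hsc_hematopoietic.tsv"}[which]
    with resources.files("trmkit.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    term_map = PHENOTYPE_TERMS[which]
    table: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        for category in str(row.phenotype).split("/"):
            term = term_map[category]
            table.setdefault(term, set()).add(row.entrez)
    return (
        AnnotationTable(term_to_genes=table, term_names=dict(PHENOTYPE_TERM_NAMES)),
        df,
    )


def write_results_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tname\tk\tK\tn\tN\tp\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_value:.6g}\t{str(r.significant).lower()}\n"
            )
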