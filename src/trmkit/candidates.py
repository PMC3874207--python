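"""Candidate co-factor selection from ChIP-seq summits, replicate motif
enrichment, motif matching and expression filtering.

The starting evidence is a set of ChIP-seq peak summits. Each summit is
extended into a fixed-width region (default 400 bp: summit +/- 200 bp);
enrichment analysis on those regions is run externally in replicates
(background sequence sampling makes single runs unstable), and only
motifs enriched (q < 0.05) in at least 80% of the replicates are kept.
The consensus de novo motifs are matched to library PWMs (q < 0.05),
resolved to genes, and filtered to those expressed in the cell type
(CPM > 1 for RNA-seq, or a user-chosen log2-intensity cutoff for
microarray data). All inequalities are strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from trmkit._util import warn
from trmkit.motif_library import MotifGeneMap, OrthologMap, map_motifs_to_genes


@dataclass(frozen=True)
class GenomicRegion:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EnrichmentRecord:
    run_id: int
    motif_id: str
    q_value: float

    def __post_init__(self):
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q-value out of [0,1]: {self.q_value}")


@dataclass(frozen=True)
class MotifMatch:
    denovo_id: str
    library_motif_id: str
    q_value: float

    def __post_init__(self):
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q-value out of [0,1]: {self.q_value}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale."""

    values: pd.DataFrame  # rows: genes, columns: samples
    scale: str  # log2_intensity | raw_counts | cpm

    SCALES = ("log2_intensity", "raw_counts", "cpm")

    def __post_init__(self):
        if self.scale not in self.SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "raw_counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw counts must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CandidateSet:
    """Expression-filtered candidate TF genes with motif provenance."""

    genes: set[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)
    expression_cutoff_used: float | str | None = None

    def __post_init__(self):
        if not set(self.provenance).issubset(self.genes):
            raise ValueError("provenance keys must be a subset of genes")


# ---------------------------------------------------------------------------
# Regions

def extend_summits(
    summits: Sequence[tuple[str, int]], flank: int = 200
) -> list[GenomicRegion]:
    """Extend each summit ``flank`` bp on either side (clipped at position 0).

    With the default flank of 200 bp each region is 400 bp wide
    (half-open coordinates), except where clipped at the chromosome start.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    regions = []
    for i, (chrom, pos) in enumerate(summits):
        if pos < 0:
            raise ValueError(f"negative summit position {pos} on {chrom}")
        regions.append(
            GenomicRegion(chrom, max(0, pos - flank), pos + flank, name=f"region_{i + 1}")
        )
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\n")


# ---------------------------------------------------------------------------
# Replicate enrichment

def parse_enrichment_runs(
    files: Sequence[str | Path],
    motif_col: str = "motif_id",
    q_col: str = "q_value",
) -> list[EnrichmentRecord]:
    """Parse per-replicate enrichment tables; run_id follows file order (1-based).

    Rows with an unparsable q-value are dropped with a warning; a file
    missing a required column is an error naming that file.
    """
    records: list[EnrichmentRecord] = []
    for run_id, f in enumerate(files, start=1):
        df = pd.read_csv(f, sep="\t", dtype={motif_col: str} if motif_col else None)
        for col in (motif_col, q_col):
            if col not in df.columns:
                raise ValueError(f"{f}: missing required column {col!r}")
        q_numeric = pd.to_numeric(df[q_col], errors="coerce")
        bad = q_numeric.isna()
        if bad.any():
            warn(f"{f}: dropped {int(bad.sum())} row(s) with unparsable q-value")
        for motif, q in zip(df.loc[~bad, motif_col], q_numeric[~bad]):
            records.append(EnrichmentRecord(run_id=run_id, motif_id=str(motif), q_value=float(q)))
    return records


def consensus_enriched_motifs(
    records: Iterable[EnrichmentRecord],
    n_runs: int,
    q_thresh: float = 0.05,
    min_frac: float = 0.8,
) -> set[str]:
    """Motifs enriched (q strictly below threshold) in >= ceil(min_frac * n_runs) runs.

    With the defaults this is the 8-of-10 replicate consensus rule. Runs
    are counted as distinct run_ids, so duplicated records are harmless.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    # guard against float artifacts: 0.8*10 == 8.000000000000002
    needed = math.ceil(min_frac * n_runs - 1e-9)
    runs_by_motif: dict[str, set[int]] = {}
    for rec in records:
        if rec.run_id > n_runs:
            raise ValueError(f"record references run_id {rec.run_id} > n_runs {n_runs}")
        if rec.q_value < q_thresh:
            runs_by_motif.setdefault(rec.motif_id, set()).add(rec.run_id)
    return {m for m, runs in runs_by_motif.items() if len(runs) >= needed}


def filter_motif_matches(
    matches: Iterable[MotifMatch], q_thresh: float = 0.05
) -> dict[str, set[str]]:
    """Keep library matches with q strictly below threshold, per de novo motif.

    De novo motifs whose matches all fail the threshold get an empty
    entry and a warning.
    """
    out: dict[str, set[str]] = {}
    for m in matches:
        out.setdefault(m.denovo_id, set())
        if m.q_value < q_thresh:
            out[m.denovo_id].add(m.library_motif_id)
    empty = sorted(d for d, libs in out.items() if not libs)
    if empty:
        warn(f"de novo motifs with no surviving library match: {empty}")
    return out


def parse_motif_matches(
    path: str | Path,
    denovo_col: str = "denovo_id",
    library_col: str = "library_motif_id",
    q_col: str = "q_value",
) -> list[MotifMatch]:
    """Read a motif-match table (Tomtom-style TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (denovo_col, library_col, q_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return [
        MotifMatch(str(d), str(m), float(q))
        for d, m, q in zip(df[denovo_col], df[library_col], df[q_col])
    ]


# ---------------------------------------------------------------------------
# Expression

def read_expression_tsv(path: str | Path, scale: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df.astype(float), scale=scale)


def compute_cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Scale raw counts to counts per million; each column then sums to 1e6."""
    if counts.scale != "raw_counts":
        raise ValueError(f"compute_cpm requires raw_counts, got {counts.scale!r}")
    libsize = counts.values.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero.index)}")
    cpm = counts.values * 1e6 / libsize
    return ExpressionMatrix(values=cpm, scale="cpm")


def expressed_genes(
    expr: ExpressionMatrix, cutoff: float, mode: str = "all"
) -> set[str]:
    """Genes with expression strictly above ``cutoff`` in all (or any) samples."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    above = expr.values > cutoff
    keep = above.all(axis=1) if mode == "all" else above.any(axis=1)
    return set(expr.values.index[keep])


def expression_histogram(expr: ExpressionMatrix, bins: int = 50) -> pd.DataFrame:
    """Histogram of all expression values, to aid manual cutoff choice.

    A bimodal log-intensity distribution separates background from
    expressed genes; the cutoff itself is always a user decision and is
    never auto-selected here.
    """
    counts, edges = np.histogram(expr.values.to_numpy().ravel(), bins=bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


# ---------------------------------------------------------------------------
# Candidate assembly

def select_candidates(
    consensus: Iterable[str],
    match_map: Mapping[str, set[str]],
    gene_map: MotifGeneMap,
    ortho: OrthologMap,
    expressed: set[str],
    target_species: str,
    expression_cutoff_used: float | str | None = None,
) -> CandidateSet:
    """Resolve consensus de novo motifs to expressed candidate TF genes.

    Consensus motifs missing from the match map are allowed but reported.
    Provenance records, per candidate gene, the library motifs that
    supported it.
    """
    consensus = set(consensus)
    unmatched = sorted(consensus - set(match_map))
    if unmatched:
        warn(f"consensus motifs with no library match entry: {unmatched}")
    library_motifs: set[str] = set()
    for d in consensus & set(match_map):
        library_motifs |= match_map[d]
    provenance: dict[str, set[str]] = {}
    genes: set[str] = set()
    if library_motifs and expressed:
        for lm in sorted(library_motifs):
            mapped = map_motifs_to_genes([lm], gene_map, ortho, target_species)
            for g in mapped & expressed:
                genes.add(g)
                provenance.setdefault(g, set()).add(lm)
    return CandidateSet(
        genes=genes, provenance=provenance, expression_cutoff_used=expression_cutoff_used
    )


def write_candidates_tsv(cands: CandidateSet, path: str | Path, species: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tmotifs\tspecies\n")
        for g in sorted(cands.genes):
            motifs = ",".join(sorted(cands.provenance.get(g, set())))
            fh.write(f"{g}\t{motifs}\t{species}\n")
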