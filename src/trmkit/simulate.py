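"""Synthetic study generation: every input format, with known ground truth.

The generator emulates one ChIP-seq-style study end to end at the
results-table level: replicate motif-enrichment tables (mimicking
replicate runs of an external enrichment tool whose background sampling
makes single runs unstable), a motif-match table, motif-to-gene and
ortholog maps, a bimodal expression matrix (separated high/low modes,
as in log-intensity distributions used to pick expression cutoffs), and
a BioGRID-style interaction table containing a random background graph
plus a planted target-bridge-query component. Because the planted
component is wired as its own connected component with only the intended
edges, the module-finding search must recover it exactly, which gives an
analytically known ground truth for end-to-end tests.

All randomness derives from one seed fanned out to fixed per-stage
offsets, so a study is byte-reproducible from its config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from trmkit._util import stage_seed


@dataclass(frozen=True)
class PlantedModule:
    """A target-bridge-query component wired into the synthetic PPI graph.

    Query i connects to the target through bridge ``i % len(bridges)``;
    with no bridges, queries attach directly to the target.
    """

    target: str = "TGT"
    queries: tuple[str, ...] = ("QRY1", "QRY2", "QRY3")
    bridges: tuple[str, ...] = ("BRG1",)

    @property
    def nodes(self) -> set[str]:
        return {self.target, *self.queries, *self.used_bridges()}

    def used_bridges(self) -> tuple[str, ...]:
        if not self.bridges:
            return ()
        return tuple(sorted({self.bridges[i % len(self.bridges)]
                             for i in range(len(self.queries))}))

    def edges(self) -> set[frozenset]:
        out: set[frozenset] = set()
        for i, q in enumerate(self.queries):
            if self.bridges:
                b = self.bridges[i % len(self.bridges)]
                out.add(frozenset((self.target, b)))
                out.add(frozenset((b, q)))
            else:
                out.add(frozenset((self.target, q)))
        return out


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 40                  # background graph size
    n_tfs: int = 3                     # planted query TFs when no explicit module given
    graph_model: str = "erdos_renyi"   # or barabasi_albert
    edge_param: float = 0.08           # ER edge probability / BA attachment count
    planted_module: PlantedModule | None = None
    expressed_fraction: float = 0.7    # of background genes
    n_enrichment_runs: int = 10        # replicate enrichment tables
    noise_rate: float = 0.0            # per-run q-value flip probability

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0 < self.expressed_fraction <= 1):
            raise ValueError("expressed_fraction must be in (0, 1]")
        if self.n_enrichment_runs < 1:
            raise ValueError("n_enrichment_runs must be >= 1")
        if not (0 <= self.noise_rate <= 1):
            raise ValueError("noise_rate must be in [0, 1]")

    def module(self) -> PlantedModule:
        if self.planted_module is not None:
            return self.planted_module
        return PlantedModule(queries=tuple(f"QRY{i+1}" for i in range(self.n_tfs)))


@dataclass
class GroundTruth:
    """What a correct end-to-end run must reconstruct."""

    module_nodes: set[str]
    module_edges: set[frozenset]
    candidate_tfs: set[str]
    expressed_genes: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "module_nodes": sorted(self.module_nodes),
            "module_edges": sorted(sorted(e) for e in self.module_edges),
            "candidate_tfs": sorted(self.candidate_tfs),
            "expressed_genes": sorted(self.expressed_genes),
        }, indent=2) + "\n")


MOUSE_TAXON = "10090"


def _background_graph(config: SimulationConfig) -> nx.Graph:
    seed = stage_seed(config.seed, "ppi")
    n = config.n_genes
    if config.graph_model == "erdos_renyi":
        p = config.edge_param
        if not (0 < p <= 1):
            raise ValueError(f"erdos_renyi edge_param must be in (0,1], got {p}")
        g = nx.gnp_random_graph(n, p, seed=seed)
    elif config.graph_model == "barabasi_albert":
        m = int(config.edge_param)
        if not (1 <= m < n):
            raise ValueError(f"barabasi_albert edge_param must be in [1, n), got {m}")
        g = nx.barabasi_albert_graph(n, m, seed=seed)
    else:
        raise ValueError(f"unknown graph model {config.graph_model!r}")
    return nx.relabel_nodes(g, {i: f"BG{i+1:04d}" for i in range(n)})


def simulate_ppi(config: SimulationConfig, out_path: str | Path) -> tuple[Path, GroundTruth]:
    """Write a BioGRID-style interaction TSV with a planted module.

    The planted component is disjoint from the random background, so the
    default search recovers exactly the planted nodes and edges. Records
    include duplicated rows (to exercise multiplicity collapse), genetic
    interactions, rows touching the excluded Ubc moiety and rows from a
    foreign organism — all of which a correct assembly discards.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "ppi"))
    bg = _background_graph(config)
    planted = config.module()
    if planted.nodes & set(bg.nodes):
        raise ValueError("planted node names collide with background names")

    rows: list[tuple[str, str, str, str, str]] = []

    def add(a: str, b: str, system: str = "physical", org: str = MOUSE_TAXON, times: int = 1):
        for _ in range(times):
            rows.append((a, b, system, org, org))

    for a, b in sorted(bg.edges):
        add(a, b, times=int(rng.integers(1, 4)))
    for e in sorted(sorted(e) for e in planted.edges()):
        add(e[0], e[1], times=int(rng.integers(1, 4)))

    # decoy rows that correct filtering removes
    bg_nodes = sorted(bg.nodes)
    add(planted.target, bg_nodes[0], system="genetic")   # genetic: dropped
    add(planted.target, "Ubc")                           # excluded moiety: dropped
    add(bg_nodes[0], bg_nodes[1], org="9606")            # wrong organism: dropped

    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write(
            "Entrez Gene Interactor A\tEntrez Gene Interactor B\t"
            "Experimental System Type\tOrganism ID Interactor A\t"
            "Organism ID Interactor B\n"
        )
        for a, b, sys_t, oa, ob in rows:
            fh.write(f"{a}\t{b}\t{sys_t}\t{oa}\t{ob}\n")

    truth = GroundTruth(
        module_nodes=set(planted.nodes),
        module_edges=planted.edges(),
        candidate_tfs=set(planted.queries),
    )
    return out_path, truth


def simulate_enrichment_runs(
    true_motifs: set[str],
    decoy_motifs: set[str],
    config: SimulationConfig,
    out_dir: str | Path,
) -> list[Path]:
    """Write replicate enrichment tables (motif_id, q_value).

    True motifs are guaranteed q < 0.05 in at least 80% of runs (exactly
    all runs at noise_rate 0); decoys are guaranteed to fail the 80%
    consensus. noise_rate flips individual runs within those guarantees.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "enrichment"))
    n = config.n_enrichment_runs
    needed = int(np.ceil(0.8 * n - 1e-9))

    def q_good() -> float:
        return round(float(rng.uniform(0.001, 0.04)), 6)

    def q_bad() -> float:
        return round(float(rng.uniform(0.06, 0.9)), 6)

    good_runs: dict[str, set[int]] = {}
    for m in sorted(true_motifs):
        good = {r for r in range(n) if rng.random() >= config.noise_rate}
        while len(good) < needed:  # clamp: true motifs must pass consensus
            good.add(int(rng.integers(0, n)))
        good_runs[m] = good
    for m in sorted(decoy_motifs):
        good = {r for r in range(n) if rng.random() < config.noise_rate}
        while len(good) >= needed:  # clamp: decoys must fail consensus
            good.discard(max(good))
        good_runs[m] = good

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in range(n):
        path = out_dir / f"enrichment_run_{r+1:02d}.tsv"
        with open(path, "w") as fh:
            fh.write("motif_id\tq_value\n")
            for m in sorted(true_motifs | decoy_motifs):
                q = q_good() if r in good_runs[m] else q_bad()
                fh.write(f"{m}\t{q}\n")
        paths.append(path)
    return paths


def simulate_expression(
    genes: set[str],
    expressed_fraction: float,
    config: SimulationConfig,
    out_path: str | Path,
    force_expressed: set[str] = frozenset(),
    force_not_expressed: set[str] = frozenset(),
    n_samples: int = 2,
) -> tuple[Path, set[str]]:
    """Write a bimodal log2-intensity matrix; returns the expressed labels.

    Expressed genes draw from N(10, 0.5), non-expressed from N(2, 0.5):
    the two modes are far enough apart that any midpoint cutoff recovers
    the generating labels. Forced sets pin specific genes to a mode.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "expression"))
    genes_sorted = sorted(genes)
    free = [g for g in genes_sorted if g not in force_expressed | force_not_expressed]
    n_expr = int(round(expressed_fraction * len(free)))
    chosen = set(rng.choice(free, size=n_expr, replace=False)) if free and n_expr else set()
    expressed = (set(force_expressed) | chosen) & set(genes)

    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write("gene\t" + "\t".join(f"S{i+1}" for i in range(n_samples)) + "\n")
        for g in genes_sorted:
            mu = 10.0 if g in expressed else 2.0
            vals = rng.normal(mu, 0.5, size=n_samples)
            fh.write(g + "\t" + "\t".join(f"{v:.4f}" for v in vals) + "\n")
    return out_path, expressed


def simulate_study(config: SimulationConfig, out_dir: str | Path) -> tuple[dict, GroundTruth]:
    """Generate a complete synthetic study directory.

    Writes the PPI table, replicate enrichment tables, motif-match table,
    motif-to-gene and ortholog maps, an expression matrix, a ready-to-run
    pipeline config (YAML) and the ground truth (JSON). One planted query
    gene is annotated through a foreign-species ortholog, and one
    consensus-enriched motif maps to a deliberately non-expressed gene,
    so a correct run exercises ortholog routing and expression filtering.

    Returns (paths dict, GroundTruth).
    """
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    planted = config.module()

    ppi_path, truth = simulate_ppi(config, out_dir / "ppi.tsv")

    # motif scaffolding: one true de novo motif per query (+ one mapping to
    # a non-expressed gene), plus decoys that must fail the consensus rule
    queries = sorted(planted.queries)
    denovo_true = [f"denovo_{q}" for q in queries] + ["denovo_nex"]
    denovo_decoy = ["denovo_decoy1", "denovo_decoy2"]
    lib_for = {f"denovo_{q}": f"LIB_{q}" for q in queries}
    lib_for["denovo_nex"] = "LIB_NEX"
    decoy_lib = {d: d.replace("denovo", "LIB") for d in denovo_decoy}

    run_paths = simulate_enrichment_runs(
        set(denovo_true), set(denovo_decoy), config, out_dir / "enrichment"
    )

    match_path = out_dir / "motif_matches.tsv"
    with open(match_path, "w") as fh:
        fh.write("denovo_id\tlibrary_motif_id\tq_value\n")
        for d in denovo_true:
            fh.write(f"{d}\t{lib_for[d]}\t0.01\n")
        for d in denovo_decoy:
            fh.write(f"{d}\t{decoy_lib[d]}\t0.01\n")

    # the first query gene is annotated in 'human' and must be routed
    # back to mouse through the ortholog map
    nex_gene = "BG0001"  # forced non-expressed below
    genes_path = out_dir / "motif_genes.tsv"
    with open(genes_path, "w") as fh:
        fh.write("motif_id\tgene\tspecies\n")
        for i, q in enumerate(queries):
            if i == 0:
                fh.write(f"LIB_{q}\tHS_{q}\thuman\n")
            else:
                fh.write(f"LIB_{q}\t{q}\tmouse\n")
        fh.write(f"LIB_NEX\t{nex_gene}\tmouse\n")
        for d in denovo_decoy:
            fh.write(f"{decoy_lib[d]}\tDECOYGENE_{d}\tmouse\n")

    ortho_path = out_dir / "orthologs.tsv"
    with open(ortho_path, "w") as fh:
        fh.write("gene\tspecies\tortholog\tortholog_species\n")
        fh.write(f"HS_{queries[0]}\thuman\t{queries[0]}\tmouse\n")

    graph_nodes = set(_background_graph(config).nodes) | planted.nodes
    expr_path, expressed = simulate_expression(
        graph_nodes,
        config.expressed_fraction,
        config,
        out_dir / "expression.tsv",
        force_expressed=planted.nodes,
        force_not_expressed={nex_gene},
    )
    truth.expressed_genes = expressed
    truth.to_json(out_dir / "ground_truth.json")

    pipeline_config = {
        "inputs": {
            "enrichment_runs": [str(p) for p in run_paths],
            "motif_matches": str(match_path),
            "motif_genes": str(genes_path),
            "orthologs": str(ortho_path),
            "expression": str(expr_path),
            "ppi": str(ppi_path),
        },
        "params": {
            "targets": [planted.target],
            "species": "mouse",
            "organism": MOUSE_TAXON,
            "q_enrich": 0.05,
            "min_frac": 0.8,
            "q_match": 0.05,
            "expression_scale": "log2_intensity",
            "expression_cutoff": 6.0,
            "expression_mode": "all",
            "max_bridge": 1,
        },
        "output_dir": str(out_dir / "results"),
    }
    config_path = out_dir / "config.yaml"
    config_path.write_text(yaml.safe_dump(pipeline_config, sort_keys=True))

    paths = {
        "ppi": ppi_path,
        "enrichment_runs": run_paths,
        "motif_matches": match_path,
        "motif_genes": genes_path,
        "orthologs": ortho_path,
        "expression": expr_path,
        "config": config_path,
        "ground_truth": out_dir / "ground_truth.json",
    }
    return paths, truth
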