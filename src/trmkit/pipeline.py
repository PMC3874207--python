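"""End-to-end pipeline driver: candidate selection -> PPI restriction ->
module search -> exports, from a single YAML config.

Every stage failure is wrapped in :class:`PipelineError` naming the
stage and the offending config key or file. All warnings raised by the
stages (dropped rows, unmapped motifs, absent targets) are mirrored into
a machine-readable run log next to the outputs. The run log carries the
package version, parameters and warnings but no timestamps, so reruns of
the same config produce identical output bytes.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping

import yaml

from trmkit._util import TRMWarning
from trmkit import candidates as cand
from trmkit import motif_library as ml
from trmkit import ppi
from trmkit.finder import TRMSearchParams, find_trm, module_stats, write_module_tsv, \
    write_module_graphml


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


DEFAULT_PARAMS = {
    "q_enrich": 0.05,
    "min_frac": 0.8,
    "q_match": 0.05,
    "expression_scale": "log2_intensity",
    "expression_cutoff": 1.0,
    "expression_mode": "all",
    "max_bridge": 1,
    "species": "mouse",
    "organism": None,
    "include_neighbors": False,
}


def _require_input(inputs: Mapping, key: str, stage: str):
    if key not in inputs:
        raise PipelineError(stage, f"config key inputs.{key} is missing")
    paths = inputs[key] if isinstance(inputs[key], list) else [inputs[key]]
    for p in paths:
        if not Path(p).exists():
            raise PipelineError(stage, f"input file for config key inputs.{key} not found: {p}")
    return inputs[key]


def run_pipeline(config: str | Path | Mapping) -> Path:
    """Run the full reconstruction described by a config mapping or YAML path.

    Returns the output directory, which contains candidates.tsv,
    module.tsv, module.graphml, summary.json and run_log.json.
    """
    if not isinstance(config, Mapping):
        config_path = Path(config)
        if not config_path.exists():
            raise PipelineError("config", f"config file not found: {config_path}")
        config = yaml.safe_load(config_path.read_text())

    inputs = config.get("inputs", {})
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    if "targets" not in params or not params["targets"]:
        raise PipelineError("config", "config key params.targets is missing or empty")
    out_dir = Path(config.get("output_dir", "trmkit_results"))
    out_dir.mkdir(parents=True, exist_ok=True)

    log: dict = {"package": "trmkit", "version": _version(), "params": params,
                 "warnings": [], "stages": []}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", TRMWarning)

        def stage(name: str):
            log["stages"].append(name)

        try:
            stage("enrichment")
            run_files = _require_input(inputs, "enrichment_runs", "enrichment")
            records = cand.parse_enrichment_runs(run_files)
            consensus = cand.consensus_enriched_motifs(
                records, n_runs=len(run_files),
                q_thresh=params["q_enrich"], min_frac=params["min_frac"],
            )

            stage("motif_matching")
            matches = cand.parse_motif_matches(
                _require_input(inputs, "motif_matches", "motif_matching")
            )
            match_map = cand.filter_motif_matches(matches, q_thresh=params["q_match"])

            stage("motif_gene_mapping")
            gene_map = ml.read_motif_gene_map(
                _require_input(inputs, "motif_genes", "motif_gene_mapping")
            )
            ortho = (
                ml.read_ortholog_map(_require_input(inputs, "orthologs", "motif_gene_mapping"))
                if "orthologs" in inputs
                else ml.OrthologMap()
            )

            stage("expression")
            expr = cand.read_expression_tsv(
                _require_input(inputs, "expression", "expression"),
                scale=params["expression_scale"],
            )
            if expr.scale == "raw_counts":
                expr = cand.compute_cpm(expr)
            expressed = cand.expressed_genes(
                expr, cutoff=params["expression_cutoff"], mode=params["expression_mode"]
            )

            stage("candidates")
            candidate_set = cand.select_candidates(
                consensus, match_map, gene_map, ortho,
                expressed=expressed, target_species=params["species"],
                expression_cutoff_used=params["expression_cutoff"],
            )
            cand.write_candidates_tsv(
                candidate_set, out_dir / "candidates.tsv", species=params["species"]
            )

            stage("ppi")
            ppi_records = ppi.parse_interactions(
                _require_input(inputs, "ppi", "ppi"), organism=params["organism"]
            )
            ppi_records = ppi.filter_physical(ppi_records)
            ppi_records = ppi.remove_excluded_nodes(ppi_records)
            graph = ppi.build_graph(ppi_records)
            graph = ppi.restrict_to_expressed(graph, expressed)

            stage("module_search")
            search = TRMSearchParams(
                max_bridge=params["max_bridge"],
                include_neighbors=params["include_neighbors"],
            )
            module = find_trm(graph, params["targets"], candidate_set.genes, search)
            write_module_tsv(module, out_dir / "module.tsv")
            write_module_graphml(module, out_dir / "module.graphml")
            summary = module_stats(module, set(params["targets"]))
            summary["candidates"] = sorted(candidate_set.genes)
            summary["consensus_motifs"] = sorted(consensus)
            (out_dir / "summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True) + "\n"
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(log["stages"][-1] if log["stages"] else "config", str(exc)) from exc

        log["warnings"] = sorted(str(w.message) for w in caught
                                 if issubclass(w.category, TRMWarning))

    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return out_dir


def _version() -> str:
    from trmkit import __version__

    return __version__
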