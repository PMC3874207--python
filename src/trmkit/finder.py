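"""The module-finding algorithm: bounded all-shortest-paths local search.

Given the cleaned, expression-restricted PPI graph, a set of target TFs
(the ChIP-seq'd factors) and a set of query TFs (motif-enriched,
expressed candidates), the search computes ALL shortest paths between
each target and each query. A target-query pair is admissible when its
shortest-path length is at most ``max_bridge + 1`` edges; the default
``max_bridge = 1`` admits paths of at most three nodes (network distance
2), i.e. one bridge protein between two TFs. The module is the subgraph
induced on the union of nodes of all admissible pairs' shortest paths,
so interactions among queries and among bridges that exist in the PPI
graph are part of the module.

Node roles: ``target`` (ChIP-seq'd TF) takes precedence over
``enriched`` (query TF), which takes precedence over ``bridge`` (path
node with no motif evidence of its own).

An empty module is a valid, flagged outcome — a target absent from the
PPI network, or no admissible pair, simply yields no module rather than
an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from trmkit._util import warn
from trmkit.ppi import without_self_loops

ROLE_PRECEDENCE = {"target": 0, "enriched": 1, "bridge": 2}


@dataclass(frozen=True)
class TRMSearchParams:
    """Search parameters.

    max_bridge
        Maximum number of bridge proteins on a target-query path; the
        admissible shortest-path length is ``max_bridge + 1`` edges
        (``max_bridge + 2`` nodes). Default 1: at most three-node paths.
    include_neighbors
        Looser variant that additionally keeps all direct PPI neighbors
        of each target, even when they lie on no admissible path.
    target_pairs
        Treat target-target pairs like target-query pairs (both
        endpoints are TFs of interest).
    """

    max_bridge: int = 1
    include_neighbors: bool = False
    target_pairs: bool = True

    def __post_init__(self):
        if self.max_bridge < 0:
            raise ValueError("max_bridge must be >= 0")


@dataclass
class TRModule:
    """A reconstructed transcriptional regulatory module."""

    graph: nx.Graph
    roles: dict[str, str]
    target_ids: set[str]
    query_ids: set[str]
    empty_flag: bool = False

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges if a != b}

    def role_counts(self) -> dict[str, int]:
        counts = {"target": 0, "enriched": 0, "bridge": 0}
        for r in self.roles.values():
            counts[r] += 1
        return counts


@dataclass
class CombinedTRM:
    """Union of member modules with node/edge presence frequencies."""

    graph: nx.Graph
    node_freq: dict[str, int]
    edge_freq: dict[frozenset, int]
    roles: dict[str, str]
    n_members: int = 0


def _empty_module(targets: set[str], queries: set[str]) -> TRModule:
    return TRModule(graph=nx.Graph(), roles={}, target_ids=set(targets),
                    query_ids=set(queries), empty_flag=True)


def shortest_path_nodes(graph: nx.Graph, u: str, v: str) -> list[list[str]]:
    """All minimal-length node paths between u and v (self-loops ignored).

    Directly connected nodes yield one two-node path (network distance
    1). A disconnected pair yields an empty list; an absent endpoint is
    an error. Paths are returned sorted for determinism.
    """
    if u not in graph or v not in graph:
        missing = [n for n in (u, v) if n not in graph]
        raise KeyError(f"node(s) not in graph: {missing}")
    g = without_self_loops(graph)
    try:
        paths = [list(p) for p in nx.all_shortest_paths(g, u, v)]
    except nx.NetworkXNoPath:
        return []
    return sorted(paths)


def find_trm(
    graph: nx.Graph,
    targets: Iterable[str],
    queries: Iterable[str],
    params: TRMSearchParams = TRMSearchParams(),
) -> TRModule:
    """Reconstruct the module around ``targets`` from candidate ``queries``.

    Genes in both sets are treated as targets. Targets or queries absent
    from the graph are dropped with a warning; if all targets are absent,
    or no target-query pair is admissible, an empty flagged module is
    returned.
    """
    targets = set(targets)
    queries = set(queries) - targets
    g = without_self_loops(graph)

    present_t = sorted(t for t in targets if t in g)
    present_q = sorted(q for q in queries if q in g)
    missing = sorted((targets | queries) - set(g.nodes))
    if missing:
        warn(f"targets/queries not found in the PPI network: {missing}")
    if not present_t:
        return _empty_module(targets, queries)

    max_len = params.max_bridge + 1
    pairs = [(t, q) for t in present_t for q in present_q]
    if params.target_pairs:
        pairs += list(combinations(present_t, 2))

    nodes: set[str] = set()
    lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=max_len)) if pairs else {}
    for u, v in pairs:
        dist = lengths.get(u, {}).get(v)
        if dist is None or dist > max_len:
            continue
        for path in nx.all_shortest_paths(g, u, v):
            nodes.update(path)

    if params.include_neighbors:
        # looser reading: retrieve every direct neighbor of each target,
        # even those on no admissible target-query path
        for t in present_t:
            nodes.add(t)
            nodes.update(g.neighbors(t))

    if not nodes:
        return _empty_module(targets, queries)

    sub = g.subgraph(nodes).copy()
    roles = {}
    for n in sub.nodes:
        if n in targets:
            roles[n] = "target"
        elif n in queries:
            roles[n] = "enriched"
        else:
            roles[n] = "bridge"
    return TRModule(graph=sub, roles=roles, target_ids=targets,
                    query_ids=queries, empty_flag=False)


def module_stats(module: TRModule, all_targets: Iterable[str]) -> dict:
    """Role counts plus the fraction of designated TFs recovered by the module."""
    all_targets = set(all_targets)
    stats: dict = {
        "n_nodes": module.graph.number_of_nodes(),
        "n_edges": module.graph.number_of_edges(),
        "roles": module.role_counts(),
        "empty": module.empty_flag,
    }
    if not all_targets:
        stats["recovered_targets"] = None
        stats["recovered_target_fraction"] = None
    else:
        recovered = module.nodes & all_targets
        stats["recovered_targets"] = sorted(recovered)
        stats["recovered_target_fraction"] = len(recovered) / len(all_targets)
    return stats


def combine_trms(modules: Sequence[TRModule]) -> CombinedTRM:
    """Amalgamate per-target modules into one combined module.

    Node and edge frequencies count the member modules containing each
    node/edge (the basis for size-scaled plotting); roles merge with
    target > enriched > bridge precedence across members.
    """
    if not modules:
        raise ValueError("no modules to combine")
    union = nx.Graph()
    node_freq: dict[str, int] = {}
    edge_freq: dict[frozenset, int] = {}
    roles: dict[str, str] = {}
    for mod in modules:
        for n in mod.graph.nodes:
            node_freq[n] = node_freq.get(n, 0) + 1
            r = mod.roles[n]
            if n not in roles or ROLE_PRECEDENCE[r] < ROLE_PRECEDENCE[roles[n]]:
                roles[n] = r
            union.add_node(n)
        for a, b, data in mod.graph.edges(data=True):
            key = frozenset((a, b))
            edge_freq[key] = edge_freq.get(key, 0) + 1
            if union.has_edge(a, b):
                union[a][b]["multiplicity"] = max(
                    union[a][b].get("multiplicity", 1), data.get("multiplicity", 1)
                )
            else:
                union.add_edge(a, b, multiplicity=data.get("multiplicity", 1))
    for n in union.nodes:
        union.nodes[n]["freq"] = node_freq[n]
        union.nodes[n]["role"] = roles[n]
    for a, b in union.edges:
        union[a][b]["freq"] = edge_freq[frozenset((a, b))]
    return CombinedTRM(graph=union, node_freq=node_freq, edge_freq=edge_freq,
                       roles=roles, n_members=len(modules))


# ---------------------------------------------------------------------------
# Export

def write_module_tsv(module: TRModule, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tmultiplicity\trole_a\trole_b\n")
        for a, b, data in sorted(
            module.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))
        ):
            fh.write(
                f"{a}\t{b}\t{data.get('multiplicity', 1)}\t"
                f"{module.roles[a]}\t{module.roles[b]}\n"
            )


def write_module_graphml(module: TRModule, path: str | Path) -> None:
    g = module.graph.copy()
    for n in g.nodes:
        g.nodes[n]["role"] = module.roles[n]
    nx.write_graphml(g, str(path))


def write_module_summary(module: TRModule, all_targets: Iterable[str], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(module_stats(module, all_targets), indent=2, sort_keys=True) + "\n"
    )
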