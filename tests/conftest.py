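import random

import networkx as nx
import pytest

from trmkit.finder import TRModule
from trmkit.ppi import without_self_loops


def module_from_edges(edges, targets=(), queries=()):
    """Build a TRModule directly from an edge list (test helper)."""
    g = nx.Graph()
    g.add_edges_from(edges)
    targets, queries = set(targets), set(queries)
    roles = {}
    for n in g.nodes:
        roles[n] = "target" if n in targets else ("enriched" if n in queries else "bridge")
    return TRModule(graph=g, roles=roles, target_ids=targets, query_ids=queries)


def brute_force_trm_nodes(graph, targets, queries, max_bridge, target_pairs=True):
    """Independent oracle: enumerate ALL simple paths of <= max_bridge+1 edges
    per pair, keep only the minimal-length ones, union their nodes."""
    g = without_self_loops(graph)
    targets = set(targets)
    queries = set(queries) - targets
    present_t = [t for t in targets if t in g]
    present_q = [q for q in queries if q in g]
    pairs = [(t, q) for t in present_t for q in present_q]
    if target_pairs:
        pairs += [(a, b) for i, a in enumerate(present_t) for b in present_t[i + 1:]]
    max_len = max_bridge + 1
    nodes = set()
    for u, v in pairs:
        paths = list(nx.all_simple_paths(g, u, v, cutoff=max_len))
        if not paths:
            continue
        min_len = min(len(p) - 1 for p in paths)
        for p in paths:
            if len(p) - 1 == min_len:
                nodes.update(p)
    return nodes


def random_search_instance(seed):
    """Seeded random PPI graph (<= 30 nodes, both models) with targets/queries."""
    rng = random.Random(seed)
    n = rng.randint(5, 30)
    if rng.random() < 0.5:
        g = nx.gnp_random_graph(n, rng.uniform(0.08, 0.35), seed=seed)
    else:
        g = nx.barabasi_albert_graph(n, rng.randint(1, 3), seed=seed)
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    nx.set_edge_attributes(g, 1, "multiplicity")
    nodes = sorted(g.nodes)
    targets = set(rng.sample(nodes, rng.randint(1, 2)))
    queries = set(rng.sample(nodes, rng.randint(1, 4)))
    return g, targets, queries


@pytest.fixture
def toy_ppi_graph():
    """T-B-Q path plus dangling neighbors X (of T) and Y (of Q)."""
    g = nx.Graph()
    g.add_edges_from([("T", "B"), ("B", "Q"), ("T", "X"), ("Q", "Y")],
                     multiplicity=1)
    return g
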