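"""Reconstruct a module on a toy PPI graph and combine two modules.

The search keeps only nodes on admissible target-query shortest paths
(at most one bridge by default); dangling neighbors of the target are
excluded unless the looser include_neighbors variant is requested.
"""

import networkx as nx

from trmkit import TRMSearchParams, combine_trms, find_trm, module_stats

ppi = nx.Graph()
ppi.add_edges_from([
    ("Pou5f1", "Sox2"),        # target adjacent to a query
    ("Pou5f1", "Sall4"),       # bridge toward Nanog
    ("Sall4", "Nanog"),
    ("Pou5f1", "Hspa8"),       # dangling neighbor: on no target-query path
    ("Nanog", "Esrrb"),        # too far from the target for max_bridge=1
    ("Esrrb", "Tcf3"),
], multiplicity=1)

module = find_trm(ppi, targets={"Pou5f1"}, queries={"Sox2", "Nanog", "Esrrb"})
print("module nodes and roles:")
for node in sorted(module.nodes):
    print(f"  {node:8s} {module.roles[node]}")
stats = module_stats(module, all_targets={"Pou5f1", "Sox2"})
print(f"recovered designated TFs: {stats['recovered_target_fraction']:.0%}")
# Esrrb sits 3 edges from Pou5f1 (two bridges), beyond the one-bridge
# default; Hspa8 touches the target but lies on no target-query path.

loose = find_trm(ppi, {"Pou5f1"}, {"Sox2", "Nanog"},
                 TRMSearchParams(include_neighbors=True))
print(f"with include_neighbors: {sorted(loose.nodes)}  (Hspa8 now kept)")

second = find_trm(ppi, targets={"Sox2"}, queries={"Pou5f1", "Nanog"})
combined = combine_trms([module, second])
print("combined module edge frequencies (presence in the 2 member modules):")
for edge, freq in sorted(combined.edge_freq.items(), key=lambda kv: sorted(kv[0])):
    print(f"  {'-'.join(sorted(edge)):16s} {freq}")
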