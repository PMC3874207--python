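# trmkit

Reconstruction of **transcriptional regulatory modules (TRMs)** from
protein–protein interaction (PPI) networks.

Transcription factors (TFs) do not act alone: cell type-specific gene
expression is driven by physical complexes of TFs and co-factors
assembled at genomic sites. ChIP-seq locates the binding sites of one
*target* TF, and motif analysis of those sites suggests which other TFs
may co-occupy them — but motif evidence alone misses every co-factor
that does not bind DNA directly (chromatin remodelers, signaling
adaptors, tethered TFs). trmkit is for computational biologists who
want to turn a single ChIP-seq experiment plus public expression and
interaction data into a concrete, testable protein module.

## Method

Given peak summits for a target TF *t*:

1. **Candidate TFs.** Summits are extended ±200 bp into 400 bp regions.
   Replicate runs of an external motif-enrichment tool on those regions
   are combined by a consensus rule: a motif is *enriched* iff
   q < 0.05 in ≥ ⌈0.8·R⌉ of R replicate runs. Enriched de novo motifs
   are matched to a PWM library (q < 0.05), resolved to genes (through
   ortholog tables across species), and filtered to genes expressed in
   the cell type (CPM > 1 for RNA-seq, a user-chosen log₂-intensity
   cutoff for microarrays; strict inequalities throughout). The
   survivors are the *query* TFs Q.
2. **PPI graph.** Interaction tables are reduced to physical
   interactions, the Ubc/Sumo1-3 modification moieties are removed,
   parallel records are collapsed to single edges carrying their record
   count as a `multiplicity` attribute, and the graph is restricted to
   expressed genes.
3. **Module search.** For every pair (t, q), *all* shortest paths are
   computed on the unweighted graph. A pair is admissible iff its
   distance d(t, q) ≤ b + 1, where b is the maximum number of *bridge*
   proteins allowed (default b = 1, i.e. paths of at most three nodes).
   The TRM is the subgraph induced on the union of all admissible
   shortest-path nodes; nodes are labeled target / enriched / bridge.
4. **Comparison & enrichment.** Modules are compared by the Jaccard
   index of their unordered edge sets, J(A,B) = |E_A ∩ E_B| / |E_A ∪ E_B|,
   clustered with complete linkage on Pearson distance (d = 1 − r) of
   the Jaccard-matrix rows; annotation-term enrichment uses the
   hypergeometric upper tail P(X ≥ k) for a universe of N genes, K
   annotated, and a query of n.

## Worked example

```python
import networkx as nx
from trmkit import find_trm, module_stats

ppi = nx.Graph([("Pou5f1", "Sox2"), ("Pou5f1", "Sall4"), ("Sall4", "Nanog"),
                ("Pou5f1", "Hspa8"), ("Nanog", "Esrrb"), ("Esrrb", "Tcf3")])
module = find_trm(ppi, targets={"Pou5f1"}, queries={"Sox2", "Nanog", "Esrrb"})
for node in sorted(module.nodes):
    print(node, module.roles[node])
```

prints

```
Nanog enriched
Pou5f1 target
Sall4 bridge
Sox2 enriched
```

Sox2 is adjacent to the target (distance 1) and Nanog is reachable via
the bridge Sall4 (distance 2), so both join the module. Esrrb sits
three edges away — beyond the one-bridge default — and Hspa8, though a
direct neighbor of the target, lies on no target–query shortest path,
so both are excluded. `module_stats(module, all_targets)` then reports
role counts and the fraction of designated TFs the module recovered.

The `examples/` directory holds one short script per capability (PWM
library, candidate selection, module search, module comparison,
phenotype enrichment, simulated end-to-end study); each prints the
numbers it computes and a line on what they mean. `trmkit --help`
exposes the same stages as a command-line tool.

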