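"""From replicate enrichment evidence to an expression-filtered candidate set.

Three replicate runs score three motifs; only the motif enriched
(q < 0.05) in >= 80% of runs survives, and its genes are then filtered
by a CPM > 1 expression rule.
"""

import pandas as pd

from trmkit import (
    EnrichmentRecord, ExpressionMatrix, MotifGeneMap, OrthologMap,
    compute_cpm, consensus_enriched_motifs, expressed_genes, select_candidates,
)

records = []
for run in (1, 2, 3):
    records += [
        EnrichmentRecord(run, "denovo_good", 0.01),      # enriched in all runs
        EnrichmentRecord(run, "denovo_flaky", 0.01 if run == 1 else 0.3),
        EnrichmentRecord(run, "denovo_never", 0.8),
    ]
consensus = consensus_enriched_motifs(records, n_runs=3)
print(f"consensus motifs ({len(consensus)} of 3 survive the 80% rule): {sorted(consensus)}")

counts = ExpressionMatrix(
    pd.DataFrame({"rep1": [90.0, 5.0, 5.0], "rep2": [80.0, 15.0, 5.0]},
                 index=["Klf4", "Sox2", "Gata1"]),
    scale="raw_counts",
)
cpm = compute_cpm(counts)
expressed = expressed_genes(cpm, cutoff=1e5)  # CPM cutoff on a 3-gene toy library
print(f"expressed genes (CPM > 1e5 in all samples): {sorted(expressed)}")

gene_map = MotifGeneMap(pairs={"LIB_A": {("Klf4", "mouse"), ("Gata1", "mouse")}})
candidates = select_candidates(
    consensus, {"denovo_good": {"LIB_A"}}, gene_map, OrthologMap(),
    expressed=expressed, target_species="mouse",
)
print(f"candidate TFs: {sorted(candidates.genes)} "
      f"(Gata1 mapped but failed the expression filter)")
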