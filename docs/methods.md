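# Methods

## Model and assumptions

A transcriptional regulatory module (TRM) is modeled as a connected
neighborhood of a physical PPI graph around one or more *target* TFs,
populated by *enriched* (query) TFs with motif and expression evidence
and by *bridge* proteins that connect them. The method assumes that
(i) physically interacting proteins reported in interaction databases
can form complexes in the cell type of interest provided both genes are
expressed there, (ii) motif enrichment in a target TF's binding regions
is evidence of co-occupancy by the motif's TF, and (iii) regulatory
complexes are compact, so members lie within a small network distance
of the target. Interaction direction, affinity and condition
specificity are not modeled; the graph is unweighted for the search and
edge multiplicity (number of supporting records) is carried as metadata
only — no statistic or filter is attached to it, since no principled
threshold exists for it.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `flank` | 200 bp | summit extension on each side; regions are 2·flank wide in half-open coordinates |
| `q_enrich` | 0.05 | per-run motif enrichment q-value threshold (strict `<`) |
| `min_frac` | 0.8 | fraction of replicate runs in which a motif must be enriched; the required count is ⌈min_frac·R⌉ (8 of 10 at defaults) |
| `q_match` | 0.05 | motif-to-library match q-value threshold (strict `<`) |
| `expression_cutoff` | 1 (CPM) | genes are expressed iff value strictly above the cutoff; for log₂-intensity data the cutoff is study-specific (bimodal-distribution inspection, e.g. 5.5–7.0) and is always user-supplied — a histogram helper assists but never auto-selects |
| `expression_mode` | `all` | require the cutoff in all samples (`any` available for single-replicate or permissive designs) |
| `max_bridge` | 1 | maximum bridge proteins per path; admissible distance is `max_bridge + 1` edges |
| `alpha` | 0.05 | enrichment significance on the raw p-value (strict `<`) |

## Numerical and design choices

- **Coordinates** are 0-based half-open. A ±200 bp extension therefore
  yields exactly 400 bp; regions are clipped at position 0 and no
  chromosome-length bound is enforced.
- **Consensus counting** uses ⌈min_frac·R⌉ computed as
  `ceil(x − 1e−9)` to neutralize binary-float artifacts (0.8·10 is not
  exactly 8 in floating point). Runs are counted as distinct run ids,
  so duplicated records cannot inflate a motif's support.
- **Node inclusion rule.** Only nodes on admissible target–query (and
  target–target) *shortest* paths enter the module; the module graph is
  the induced subgraph on those nodes, so query–query and bridge–bridge
  edges present in the PPI graph are retained. Dangling neighbors of
  the target that lie on no such path are excluded by default: extra
  module members are meaningful precisely as bridges between TFs. The
  looser variant that also keeps all direct target neighbors is
  available as `include_neighbors=True`. Longer-than-minimal admissible
  detours between a pair are never added; all co-minimal paths are kept
  with no sampling.
- **Empty modules** (target absent from the network, or no admissible
  pair) are valid flagged results, not errors — a real outcome for
  poorly connected targets.
- **Self-loops** (homodimer records) are stored flagged but never
  traversed and never counted as edges of a module or of an edge key
  set.
- **Cross-source motif id collisions** are kept under `<id>@<source>`
  keys; silently overwriting one catalogue with another would lose
  provenance. One-to-many ortholog mappings expand to all targets; the
  expression filter downstream corrects over-inclusion.
- **Motif-to-gene tables carry a species tag per gene** so the mapper
  knows which genes must be routed through the ortholog table to reach
  the target species; the classification ontology marks each term's
  level (superclass/class/family/subclass/gene/factor-species) in its
  `subset` tag, and isoform-level (factor-species) records are dropped
  before gene resolution.
- **Jaccard of two empty edge sets** is defined as 0 with a warning so
  empty modules cannot inject NaN into a similarity matrix.
- **Clustering** computes Pearson distances on Jaccard-matrix rows
  including the diagonal (an option excludes the two self-similarities
  per comparison) and agglomerates with complete linkage implemented
  directly, breaking ties lexicographically by smallest member label.
  The explicit tie-break makes results invariant to input order even on
  tied Jaccard values, which generic linkage implementations do not
  guarantee; agreement with SciPy's complete linkage on tie-free
  matrices is verified in the test suite. A constant similarity row
  makes Pearson correlation undefined and raises an error naming the
  module.
- **Hypergeometric tail.** The upper tail P(X ≥ k) is computed via the
  survival function at k − 1 (log-space internally); the k = 0 case
  returns exactly 1. The off-by-one between P(X ≥ k) and P(X > k) is
  the classic bug here, so the convention is fixed in the function
  contract and pinned by exhaustive-enumeration tests. No
  multiple-testing correction is applied by default (raw p < 0.05
  reporting); Benjamini–Hochberg is available as an option. The
  universe defaults to all annotated genes and should be chosen
  deliberately — whole genome, expressed genes and network nodes give
  different baselines.

## Synthetic data generator

`trmkit.simulate` emulates one study at the results-table level:
replicate enrichment tables (true motifs guaranteed under the q
threshold in ≥ 80% of runs, decoys guaranteed to fail the consensus;
`noise_rate` flips individual runs within those guarantees), a
motif-match table, motif-gene/ortholog maps (one planted query is
annotated in a foreign species to exercise ortholog routing, and one
consensus motif maps to a deliberately non-expressed gene to exercise
the expression filter), a two-mode expression matrix (N(10, 0.5) vs
N(2, 0.5) log₂ intensities — 16σ separation, so any midpoint cutoff
recovers the generating labels), and a BioGRID-style table holding an
Erdős–Rényi or Barabási–Albert background graph plus a planted
target–bridge–query component, with duplicated rows, genetic-type rows,
Ubc rows and foreign-organism rows included as filter fodder. Default
sizes (40 background genes, 3 query TFs, 1 bridge, 10 replicate runs,
expressed fraction 0.7) keep one study in tens of milliseconds while
exercising every pipeline stage; tests sweep 200 seeds.

The planted component is disjoint from the background graph and
contains no extra internal edges, so the exact module it implies is
known analytically — that is what makes end-to-end recovery testable.
The generator does **not** emulate real data's hard parts: overlapping
evidence (background genes never share edges with planted nodes),
motif-resolution ambiguity (families of near-identical PWMs), noisy
many-to-many ortholog tables, or interaction false positives/negatives.
Passing the recovery suite therefore shows the plumbing and the search
are correct, not that the method's biological error rate is small.

One global seed fans out to fixed per-stage offsets (`_util.stage_seed`),
so each stage is independently reproducible; all derived seeds stay
below 2³¹.

## Bundled data

`trmkit/data/` ships two small curated tables of mouse knockout
phenotypes: 13 embryonic-lethal proteins of the 77-protein combined ESC
module and 22 hematopoiesis-phenotype proteins of the 96-protein
combined HSC module, keyed by Entrez id with their phenotype categories
(MP:0011096/MP:0011106 and MP:0001606/MP:0002123/MP:0002401/MP:0002429).
They serve as worked-example inputs for `count_annotated`; the full
module membership lists are not shipped, so the remaining module
members are represented by filler identifiers when the tables are used
as overlap examples.

## Known limitations

- All-shortest-paths enumeration is exponential in pathological dense
  graphs for large `max_bridge`; at the default distance bound of 2 it
  is cheap even on organism-scale networks.
- The PWM store performs no motif scanning, trimming or clustering;
  matrices are stored as given with no pseudocounts, since enrichment
  and matching happen in external tools whose result tables are parsed.
- Gene identifiers are opaque strings; no validation against a live
  identifier service is attempted, and identifier-space mismatches
  between inputs (symbols vs Entrez) are the caller's responsibility.
- Clustering output includes merge heights, but no significance is
  attached to cluster membership; no null model for edge overlap is
  provided.
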