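"""Hypergeometric phenotype enrichment on the bundled curated tables.

Counts how many proteins of a combined module carry lethal/hematopoietic
knockout phenotypes and scores the over-representation of one term.
"""

from trmkit import count_annotated, enrich_terms, hypergeom_upper, load_bundled_phenotypes

ann, table = load_bundled_phenotypes("esc")
module = set(table["entrez"]) | {f"FILL{i:03d}" for i in range(77 - len(table))}

count, frac = count_annotated(module, ann, {"MP:0011096", "MP:0011106"})
print(f"{count}/{len(module)} module proteins (~{frac:.0%}) are embryonic lethal "
      "on knockout")

# enrichment against a 5000-gene universe in which only the module
# proteins carry the annotation
universe = module | {f"GENOME{i:04d}" for i in range(5000 - len(module))}
results = enrich_terms(module, ann, universe=universe)
top = results[0]
print(f"top term {top.term} ({top.name}): k={top.k}, K={top.K}, "
      f"n={top.n}, N={top.N}, p={top.p_value:.3g}")

p = hypergeom_upper(4, 5, 4, 10)
print(f"worked tail example P(X>=4 | N=10, K=5, n=4) = {p:.5f}  (= 5/210)")
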