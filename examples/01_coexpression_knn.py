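"""Quantile-normalize an expression panel and extract each gene's KNN set.

Builds a small synthetic panel with three planted co-expression modules,
normalizes it, computes the gene-gene Pearson matrix, and prints the top
neighbors of one module gene. Most neighbors should be module-mates with
r near the planted within-module correlation (0.85)."""

import guiltnet as gn

scen = gn.demo_scenario(seed=0)
expr = gn.quantile_normalize(scen["expression"])
corr = gn.correlation_matrix(expr)
nn = gn.knn_neighbors(corr, k=10)

module = scen["truth"].modules[0]
gene = module.gene_ids[0]
print(f"gene {gene} (module {module.module_id}, rho={module.rho}):")
for rank, (neighbor, r) in enumerate(nn[gene], start=1):
    tag = "module-mate" if neighbor in module.gene_ids else "background"
    print(f"  {rank:2d}. {neighbor}  r={r:+.3f}  ({tag})")
in_module = sum(nb in module.gene_ids for nb, _ in nn[gene])
print(f"{in_module}/10 neighbors come from the planted module: the KNN set "
      "recovers the co-expression structure.")
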