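"""Recognize thesaurus terms in abstracts and build the co-occurrence network.

Generates a synthetic corpus in which module genes co-occur with a planted
disease concept, builds the document-level co-occurrence network, and prints
edge weights. The planted concept should share many more documents with its
module's genes than any decoy concept does."""

import guiltnet as gn

scen = gn.demo_scenario(seed=0)
net = gn.build_network(scen["corpus"], scen["thesaurus"])

print(f"network: {net.graph.number_of_nodes()} terms, "
      f"{net.graph.number_of_edges()} edges "
      f"from {len(scen['corpus'])} abstracts")

module = scen["truth"].modules[0]
planted = module.linked_concepts[0]
print(f"\ndocument co-occurrence counts with module {module.module_id} genes:")
print(f"{'gene':>8} {planted:>8} {'PHE01 (decoy)':>14}")
for gene in module.gene_ids[:6]:
    print(f"{gene:>8} {net.weight(gene, planted):>8} "
          f"{net.weight(gene, 'PHE01'):>14}")
print("\nThe planted concept co-occurs with module genes far above the "
      "background rate; that asymmetry is the literature evidence the "
      "commonality score exploits.")
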