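"""Rank hub genes by Maximal Clique Centrality on a planted network.

Builds a confidence-filtered interaction network containing two planted
hub cliques plus random background edges, ranks nodes by MCC and checks
that the planted hubs top the list.
"""

import etplineage as el

net, truth = el.generate_network(
    n_nodes=80, planted_hubs=2, clique_size=6,
    background_edge_prob=0.03, seed=3,
)
ranking = el.mcc_scores(net)
top = el.top_hubs(ranking, k=10)

print(f"network: {net.number_of_nodes()} nodes, "
      f"{net.number_of_edges()} edges")
print("gene      MCC  degree")
for gene, mcc, degree, rank in ranking.as_rows()[:10]:
    marker = " <- planted hub" if gene in truth.planted_hubs else ""
    print(f"{gene:8s} {mcc:4d} {degree:6d}{marker}")
print(f"planted hubs recovered in top-10: "
      f"{truth.planted_hubs <= set(top)}")
print("-> a clique of size k contributes (k-1)! to each member; "
      "(6-1)! = 120 dwarfs what sparse background edges can accumulate.")
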