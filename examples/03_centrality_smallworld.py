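"""Centrality (strength, closeness, betweenness, expected influence) and
the small-world index of an estimated symptom network."""

import symptomnet as sn

data = sn.paper_like_cohorts(n_mde=871, n_ppd=486, seed=1)["PPD"]
net = sn.fit_ising(data)

table = sn.centrality_table(net)
print("z-standardized centralities (PPD network):")
print(table.z.round(2).to_string())

sw = sn.small_world(net, n_random=1000, seed=2)
print(f"\nclustering C = {sw.clustering:.3f} (random reference {sw.c_random:.3f})")
print(f"mean path  L = {sw.avg_path_length:.3f} (random reference {sw.l_random:.3f})")
print(f"small-world index = {sw.index:.2f} -> "
      f"{'small world' if sw.is_small_world else 'not a small world'}")

# A node with high strength/expected influence is densely connected;
# an index above 1 means more clustering per unit path length than an
# Erdos-Renyi graph with the same number of nodes and edges.
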