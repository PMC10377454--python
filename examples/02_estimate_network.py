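"""Estimate a regularized Ising symptom network (eLASSO with EBIC).

Fits a sparse conditional-dependence network on one simulated group and
prints the selected edges next to the descriptive Pearson (phi)
correlations for the same pairs.
"""

import symptomnet as sn

data = sn.paper_like_cohorts(n_mde=871, n_ppd=486, seed=1)["PPD"]
net = sn.fit_ising(data, gamma=0.25, rule="AND")
phi = sn.pearson_matrix(data).to_dataframe()

print(f"PPD network: {len(net.edge_list())} edges (gamma=0.25, AND rule)\n")
print(f"{'edge':<38s} {'ising w':>8s} {'phi r':>8s}")
for _, row in net.edge_list().iterrows():
    r = phi.loc[row.node_i, row.node_j]
    print(f"{row.node_i + ' -- ' + row.node_j:<38s} {row.weight:8.3f} {r:8.3f}")

# Edge weights are conditional log-odds interactions: the association
# between two symptoms controlling for the other seven. The phi column is
# the marginal correlation; the two can differ in size and even sign.
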