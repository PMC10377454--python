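# symptomnet

Comparative **symptom-network analysis for binary clinical data**:
estimation of regularized Ising networks over DSM-5 depressive symptoms,
centrality and small-world inference, bootstrap stability, permutation
network comparison, and severity-adjusted symptom-frequency comparison.
Written for psychiatric-epidemiology settings such as contrasting
postpartum depression (PPD) with non-perinatal major depressive episodes
(MDE), where each participant contributes nine present/absent diagnostic
criteria and a group label.

## The model and statistics

Symptom profiles x ∈ {0,1}⁹ are modeled as an Ising (pairwise Markov
random field) distribution

&nbsp;&nbsp;&nbsp;&nbsp;P(x) ∝ exp( Σᵢ τᵢxᵢ + Σ_{i<j} wᵢⱼxᵢxⱼ ),

estimated nodewise by **eLASSO**: per-symptom L1-penalized logistic
regressions over a 100-point penalty path, model selection by the extended
BIC (γ = 0.25), AND-rule symmetrization. On the estimated network the
package computes:

- **Centrality** — strength Σⱼ|wᵢⱼ|, expected influence Σⱼwᵢⱼ, and
  closeness/betweenness on geodesics with edge length 1/|wᵢⱼ|, each raw
  and z-standardized;
- **Small-world index** — σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩) against
  Erdős–Rényi graphs with matched node/edge counts (σ > 1 ⇒ small world);
- **CS-coefficient** — case-dropping bootstrap: the largest fraction of
  participants droppable while subsample centralities correlate ≥ 0.70
  with the full sample in ≥ 95% of replicates;
- **NCT** — permutation test of network invariance
  (M = max |w⁽ᵃ⁾ − w⁽ᵇ⁾|) and global strength invariance
  (S = |Σ|w⁽ᵃ⁾| − Σ|w⁽ᵇ⁾||);
- **Adjusted frequency comparison** — per-symptom logistic regression of
  presence on group + total symptom count, reported as odds ratios with
  95% Wald CIs.

A synthetic-cohort module samples *exactly* from small Ising models
(enumeration + renormalization, Gibbs above p = 20), optionally
conditioned on the DSM-5 diagnostic event (≥ 5 symptoms, at least one of
sadness/anhedonia), so the whole pipeline is testable with known ground
truth.

## Worked example

```python
import symptomnet as sn

cohorts = sn.paper_like_cohorts(n_mde=871, n_ppd=486, seed=1)
net = sn.fit_ising(cohorts["PPD"], gamma=0.25, rule="AND")
print(sn.centrality_table(net).z.round(2))
sw = sn.small_world(net, n_random=1000, seed=2)
print(sw.index, sw.is_small_world)
res = sn.nct(cohorts["MDE"], cohorts["PPD"], n_perm=1000, seed=4)
print(res.m_observed, res.p_m, res.s_observed, res.p_s)
```

prints (abridged; see `examples/03_centrality_smallworld.py` and
`examples/05_compare_networks.py`):

```
                    strength  closeness  betweenness  expected_influence
sadness                -1.12      -1.59        -0.64               -0.19
...
suicidal_ideations      2.06       1.00         1.72               -0.39

small-world index = 2.11 -> small world
network structure invariance  M = 0.971  p = 0.023
global strength invariance    S = 2.244  p = 0.178
```

Reading: in this simulated PPD group, *suicidal ideations* is the most
central criterion (z ≈ +2 strength, highest betweenness); the network
clusters more than an equally dense random graph (σ = 2.11 > 1, a "small
world"); and the permutation test detects the structural difference built
into the two groups' generating models (M rejects at p ≈ 0.02) while total
connectivity does not differ significantly (S, p ≈ 0.18).

The `examples/` directory has one short script per capability; a thin CLI
mirrors the stages (`symptomnet simulate | frequencies | estimate |
centrality | stability | compare | run`), with `run` driven by a YAML
config and a master seed for byte-reproducible outputs.

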