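# symptomnet

Symptom-network analysis of psychopathology: why are mental disorders so
comorbid? Because they share symptoms. `symptomnet` treats the diagnostic
system itself as a network — symptoms are nodes, and two symptoms are
linked whenever they are criteria for the same disorder — and provides
the full analysis pipeline around that idea, for researchers in
psychiatric epidemiology and network psychometrics:

1. **Graph construction** — read a symptom × disorder incidence table
   (long-form TSV/CSV or labeled 0/1 matrix) and project it to the
   unipartite symptom graph, in which every disorder induces a clique and
   *bridge symptoms* (criteria of several disorders) connect disorders.
2. **Small-world architecture** — transitivity C, average shortest path
   length L, geodesic counts, degree-tail classification, current-flow
   (random-walk) betweenness, and the small-world index

       SWI = (C / C_rnd) / (L / L_rnd),
       C_rnd = ⟨k⟩/n,   L_rnd = (ln n − γ)/ln⟨k⟩ + 1/2,

   against both sampled G(n,m) random graphs and a degree-preserving
   bipartite permutation null (checkerboard swaps with exact margin
   preservation).
3. **Comorbidity geometry** — the distance between two disorders as the
   mean geodesic length between their symptoms, correlated with an
   empirical comorbidity matrix; positive-manifold checking.
4. **Activation dynamics** — a stochastic simulator in which symptom i
   activates with probability
   `p = a + (1−a)(σ(b_i·A − c_i) − a)` given A active neighbours,
   DSM-style MDE/GAD diagnosis rules applied to simulated years, and the
   population statistics they imply: prevalence, comorbidity odds ratio,
   Cronbach's alpha, plus per-symptom (b, c) estimation by logistic
   regression and a calibration routine that tunes thresholds to target
   symptom rates.

Everything runs on synthetic inputs generated by `symptomnet.synthetic_data`
(including the canonical 14-symptom MDE/GAD network: five core symptoms
per disorder plus four shared bridges), so no restricted survey data is
required.

## Worked example

```python
import symptomnet as sn
from symptomnet.synthetic_data import mde_gad_fixture, calibrated_mde_gad_spec

table, (mde_rule, gad_rule), _ = mde_gad_fixture()
graph = sn.project_to_symptom_graph(table)
s = sn.summarize(graph)
print(s.n, s.m, round(s.transitivity, 3), round(s.avg_path_length, 3))
# 14 66 0.831 1.275

print(round(sn.small_world_index(0.68, 2.6, 208, 1949).swi, 1))
# 6.2

spec = calibrated_mde_gad_spec(seed=11)          # thresholds tuned to target rates
panel = sn.simulate_population(spec, 2000, 365, seed=42)
stats = sn.population_statistics(panel, [mde_rule, gad_rule])
print({k: round(v, 3) for k, v in stats.prevalence.items()},
      round(stats.odds_ratio, 1), round(stats.alpha, 3))
# {'MDE': 0.073, 'GAD': 0.019} 8.7 0.783
```

The first block says the 14-symptom MDE/GAD network is two overlapping
9-cliques: 66 edges, clustering 0.83, average distance 1.27 edges. The
SWI line evaluates the small-world index of a 208-node, 1949-edge
component with observed clustering 0.68 and path length 2.6 — it exceeds
the conservative small-world threshold of 3 roughly twofold. The last
block simulates 2000 persons for a year under calibrated dynamics and
diagnoses them: ≈ 7.3% meet the MDE episode criterion, ≈ 1.9% the
chronic GAD criterion, with strongly associated diagnoses (odds ratio
≈ 9 in this single replicate; it varies widely across replicates) and
internal consistency α ≈ 0.78.

The numbered drivers under `analysis/` run the full narratives
(graph summary, null-model comparison, distance-vs-comorbidity,
original-vs-shuffled replication study) and write their tables to
`results/`:

```
python analysis/01_build_symptom_graph.py
python analysis/02_small_world_nulls.py
python analysis/03_distance_vs_comorbidity.py
python analysis/04_simulate_mde_gad.py
```

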