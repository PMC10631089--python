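# mnscan

Spatial cluster detection for **multinomial (nominal categorical) outcomes** —
disease subtypes, care pathways, survey responses — with data-driven selection
of the **maximum reported cluster size (MRCS)**.

## The problem

The spatial scan statistic finds geographic clusters by sliding circular and
elliptic windows over a study region and testing, in each window *z*, whether
the category distribution inside differs from outside. With counts
*c<sub>ik</sub>* (cases of category *k* in region *i*), inside totals
*a<sub>k</sub>* (sum *A*), outside totals *b<sub>k</sub> = C<sub>k</sub> −
a<sub>k</sub>* (sum *B*), the log likelihood ratio is

```
log λ_z = Σ_k [ a_k log(a_k/A) + b_k log(b_k/B) ] − Σ_k C_k log(C_k/C)
```

The window maximizing log λ<sub>z</sub> is the most likely cluster;
significance comes from Monte Carlo randomization that reshuffles category
labels over cases with both margins fixed.

Scanning is run once with the maximum scanning window size (MSWS) at 50% of
cases, but *reporting* everything up to 50% tends to return clusters much
larger than the truth. This package varies the maximum **reported** cluster
size over a candidate grid (1–50%) and selects the best value with five
criteria:

- **SCIC₁ / SCIC₂** (spatial cluster information criterion): minimize
  `−2 Σ_j log λ_j + K · J_m · log(penalty)` over the grid, where *J<sub>m</sub>*
  is the number of significant clusters at MRCS *m* and the penalty argument
  is the total cases (SCIC₁) or total regions (SCIC₂) inside them;
- **elbow**: maximize the orthogonal distance of the `(m, −Σ log λ)` curve
  from its end-to-end chord;
- **MCS-P / MCHS-P**: maximize a union log likelihood ratio over the merged
  significant clusters, treated as one homogeneous zone (MCS-P) or as
  contiguity-connected heterogeneous zones (MCHS-P).

A simulation framework plants circular, elliptic, or irregular clusters on a
synthetic lattice geography and scores detection by region-level sensitivity,
positive predictive value (PPV), and misclassification.

## Worked example

```python
from mnscan import (MultinomialScan, Scenario, make_grid_geography,
                    plant_true_clusters, simulate_dataset)

rmap = make_grid_geography(8)                          # 64 regions, rook adjacency
truth = plant_true_clusters(rmap, "elliptic", 0.08)    # 5-region planted cluster
scenario = Scenario(rmap, tuple(truth), p_list=((0.05, 0.15, 0.35, 0.45),))
cases = simulate_dataset(scenario, seed=5)             # 1000 cases, K=4

model = MultinomialScan(cases, rmap, shapes=(1, 2, 3), angles_per_shape=(1, 6, 9))
results = model.fit(replications=99, alpha=0.05, seed=2)
print(results.summary(mrcs=50))

sel = results.select_mrcs("scic1")
print("optimal MRCS:", sel.selected_m)
print("reported:", [r.window.regions for r in sel.clusters])
print("true cluster:", sorted(truth[0]))
```

Output:

```
Multinomial spatial scan statistic
==================================================
regions: 64    categories: 4    cases: 1000
candidate windows: 22137    MSWS: 50% of cases
Monte Carlo replications: 99    alpha: 0.05
max log likelihood ratio: 17.0306

significant clusters at MRCS = 50%: 1
  #1: LLR=17.0306 p=0.01 cases=72 regions=[R16,R17,R18,R19,R20]
optimal MRCS: 8.0
reported: [(16, 17, 18, 19, 20)]
true cluster: [16, 17, 18, 19, 20]
```

SCIC₁ selects an MRCS of 8% — the planted cluster's share of the map — and
the report at that value is exactly the 5 planted regions (72 of 1000 cases,
p = 0.01). On single datasets the unrestricted scan often finds the same
window; the value of selecting the MRCS shows in aggregate: over 100
simulated datasets of this scenario, scoring each dataset at its selected
MRCS raises mean PPV from 0.89 (50% default) to 0.93 and roughly halves the
misclassification rate (`scripts/acceptance.py` recomputes these).

The same pipeline runs from the shell:

```bash
mnscan make-synth --out synth --scenario B --hypothesis 1 --seed 1
mnscan select-mrcs --regions synth/regions.csv --cases synth/cases.csv \
    --adjacency synth/adjacency.csv --method all --seed 2 --out results
mnscan simulate --scenario B --hypothesis 1 --n-reps 100 --seed 0 --out sim-out
```

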