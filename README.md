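# pollinet

Build and compare bipartite plant–pollinator networks from two kinds of
field data: direct **visit surveys** (an observer records which plant each
captured insect was visiting) and **pollen DNA metabarcoding** (the pollen
washed off each insect's body is sequenced, and read counts per plant taxon
reveal where the insect has foraged). Metabarcoding detects many
interactions that visit surveys miss — pollen accumulates over an insect's
whole foraging history, including plants outside the surveyed plots — but
the two data types produce networks of very different size and sampling
depth, so comparing them naively is meaningless. This package implements
the full comparison workflow for ecologists working with paired
visit/metabarcoding data:

* **Interaction calling** from a read-count table: a link between plant *i*
  and insect *j* is called when the read count exceeds a threshold (default
  1,000 reads, strictly `count > 1000`), chosen so that widespread low-level
  background contamination by airborne grass pollen is removed. Wind-
  pollinated taxa and taxa resolved above genus are excluded; insects with
  no super-threshold plant are dropped.
* **Network construction** at three resolution levels from the matrix
  `M = [a_ij]` (plants in rows, pollinators in columns): pollinator-group ×
  floral-morphology-group, species × species, and per-species individual ×
  plant networks.
* **A full index suite** implemented from formulas: connectance
  `C = I/(A·P)`, interaction density `I/(A+P)`, linkage levels `I/P` and
  `I/A`, nestedness `(100−T)/100` from matrix temperature, Barber bipartite
  modularity `Q = (1/F) Σᵢⱼ (a_ij − kᵢdⱼ/F) δ(gᵢ,gⱼ)`, network-level
  specialization `H₂′`, species-level specialization `d′` (standardized
  Kullback–Leibler divergence), interaction evenness `E₂ = H₂/ln(A·P)`,
  extreme specialization (% single-partner species), cumulative
  degree-distribution fits and the log–log regression of links per species
  on interaction frequency.
* **Fixed-marginal null models** (Patefield sampling) with 95% confidence
  intervals to separate ecological structure from what margins alone imply.
* **Size- and effort-matched comparison**: both species networks restricted
  to shared species, the metabarcoding network multinomially rarefied to
  the visit network's interaction total (1,000 replicates), empirical
  p-values with Bonferroni correction.
* **A synthetic-data generator** that emulates the whole study design —
  skewed plant/insect abundances, group-structured floral preferences
  (bees on zygomorphic flowers, hoverflies on open actinomorphic ones),
  multi-visit pollen accumulation, airborne-grass contamination — so every
  stage is testable against known ground truth.

## Worked example

Run the full pipeline on the default synthetic scenario (402 captured
insects, four merged communities, 1,000-read threshold, 100 null networks,
1,000 rarefied replicates; finishes in well under a minute):

```bash
pollinet all --out demo_run --seed 1
cat demo_run/table1.txt
```

```
Index                                         sp-sp N_obs          95% CI      sp-sp N_seq          95% CI
----------------------------------------------------------------------------------------------------------
No. insect species (A)                             87ns a           87-87           87ns b           87-87
No. plant species (P)                              24ns a           24-24           62ns a           62-62
Network size (A x P)                             2088ns a       2088-2088         5394ns b       5394-5394
No. links (I)                                      275* a       277-299.5         1040ns b       1028-1068
Connectance (C = I/(A x P))                      0.132* a     0.133-0.143        0.193ns a     0.191-0.198
Nestedness (100-T)/100                           0.86ns a     0.843-0.878        0.863ns a     0.848-0.881
Modularity (M)                                   0.349* a     0.287-0.337         0.213* a     0.136-0.152
...
```

Reading the output: each column shows an index for the visit-survey
(`N_obs`) and metabarcoding (`N_seq`) species networks with the 95%
confidence interval from 100 fixed-marginal null networks. A `*` marks an
index outside its null interval (structured beyond what the margins
explain — here modularity in both networks), `ns` one inside it. Rows
whose two networks do **not** share a letter differ significantly in the
size-matched rarefaction test: at seed 1 the metabarcoding network keeps
significantly more links (1040 vs 275, letter `b` on the link row) even
after rarefying it to the visit network's sampling effort. The run
directory also contains the built matrices (`matrices/*.tsv`), the full
index reports (`index_reports.tsv`), degree-distribution and f–s
regression fits (`connectivity_fits.json`), the contamination profile
(`contamination.json`), threshold sensitivity (`threshold_sensitivity.tsv`)
and the comparison table with p-values (`comparison.tsv`).

The same stages are available individually (`pollinet simulate / build /
indices / nulls / compare`) and as library functions:

```python
from pollinet import (CommunitySpec, ContaminationSpec, generate_truth,
                      simulate_visits, simulate_pollen_loads,
                      build_obs_matrix, call_interactions, aggregate,
                      compute_index_report)

spec = CommunitySpec(seed=1)
truth = generate_truth(spec)
cont = ContaminationSpec()
registry = truth.registry(cont)
seq_ind = call_interactions(simulate_pollen_loads(truth, spec, cont), registry)
seq_sp = aggregate(seq_ind, registry, "species")
print(compute_index_report(seq_sp, seed=1).as_dict())
```

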