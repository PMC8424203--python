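# assemblyscope

Community-assembly inference for microbial count data: quantify how
much of a community's structure is shaped by deterministic selection
versus stochastic drift and dispersal, and map its co-association
network.

Microbial ecologists routinely ask, for a set of OTU/ASV tables with a
phylogeny and environmental metadata (say, soil fungi under nitrogen
addition): are these communities assembled by environmental filtering,
or by neutral drift and dispersal? `assemblyscope` implements the
standard inference stack for that question as a tested Python library
and CLI:

* **β-nearest taxon index (βNTI)** — the z-score of the abundance-
  weighted β-mean-nearest-taxon-distance (βMNTD) against a
  tip-shuffling phylogenetic null; |βNTI| > 2 flags selection
  (variable if > 2, homogeneous if < −2).
* **Bray–Curtis Raup–Crick (RC_bray)** — observed dissimilarity ranked
  within a null that fixes each sample's richness and abundance and
  draws taxa by regional occupancy; |RC| > 0.95 flags
  dispersal-driven turnover.
* **Five-process classification** — per sample pair: variable
  selection, homogeneous selection, dispersal limitation, homogenizing
  dispersal, or undominated; group-level fractions.
* **Normalized stochasticity ratio (NST)** — pairwise index in [0, 1]
  with 50% as the deterministic/stochastic boundary.
* **Sloan neutral community model** — fits Nm from the occurrence-
  frequency curve F(p) = 1 − I_{1/N}(Nm·p, Nm(1−p)) and flags taxa
  against the 95% prediction band.
* **Levins' niche breadth** (B, community mean Bcom) and a
  **phylogenetic-signal Mantel correlogram** of niche distances
  against phylogenetic distance classes.
* **RMT-thresholded co-association networks** — similarity threshold
  chosen where the eigenvalue spacing distribution turns Poisson,
  topology metrics, Maslov–Sneppen random references, and Zi–Pi
  keystone roles.
* **A synthetic community simulator** with known assembly regimes
  (neutral, homogeneous/variable selection, dispersal-limited) on
  simulated phylogenies, so every stage can be validated against
  ground truth.

## Worked example

```python
import numpy as np
from assemblyscope import (
    RegimeSpec, simulate_tree, simulate_community, match_tree_table,
    NullEnsembleSpec, beta_nti, raup_crick_bray, classify_processes, nst,
)

tree = simulate_tree(1000, seed=777)

# a neutral community: drift + migration around a log-series metacommunity
table, meta = simulate_community(
    tree, RegimeSpec(regime="neutral", n_samples=8,
                     community_size=5000, migration=0.3, seed=900))
table, tree_m, _ = match_tree_table(table, tree)

spec = NullEnsembleSpec(n_null=199, seed=50)
summary = classify_processes(
    beta_nti(table, tree_m, spec), raup_crick_bray(table, spec))
groups = {"g1": table.sample_ids[:4], "g2": table.sample_ids[4:]}
nst_res = nst(table, groups, spec=NullEnsembleSpec(n_null=99, seed=50))

print(f"stochastic fraction: {summary.stochastic_fraction:.2f}")
print(f"process fractions:   { {k: round(v, 2) for k, v in summary.fractions.items()} }")
print(f"group NST (%):       { {k: round(v, 1) for k, v in nst_res.group_nst.items()} }")
```

Output:

```
stochastic fraction: 0.96
process fractions:   {'variable_selection': 0.0, 'homogeneous_selection': 0.04, 'dispersal_limitation': 0.07, 'homogenizing_dispersal': 0.0, 'undominated': 0.89}
group NST (%):       {'g1': 94.0, 'g2': 94.5}
```

The neutral ground truth is read back correctly: 96% of sample pairs
are classified to stochastic processes and group NST sits far above
the 50% boundary. Re-running the same code with
`regime="homogeneous_selection"` (and `community_size=1000`) flips the
picture — homogeneous selection becomes the modal process and NST
drops below 50%.

The same analyses run from the shell:

```bash
assemblyscope simulate --regime study --ntaxa 600 --seed 42 --outdir sim/
assemblyscope nullmodel --table sim/table.tsv --tree sim/tree.nwk \
    --nnull 999 --seed 7 --outdir out/
assemblyscope nst --table sim/table.tsv --groups sim/meta.tsv:cell
assemblyscope network --table sim/table.tsv --scan 0.5:0.95:0.01
assemblyscope run config.yaml     # full pipeline from a YAML config
```

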