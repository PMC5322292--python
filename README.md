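# netdiv — interaction-adjusted community similarity

`netdiv` quantifies β diversity between microbial (or other) communities in
the context of a taxa interaction network.  Classical indices (Jaccard,
Bray–Curtis, Morisita–Horn, …) treat taxa as independent; phylogenetic
indices (UniFrac) weigh shared evolutionary history.  The interaction-adjusted
family implemented here instead asks: *how strongly associated are the taxa of
sample A with the taxa of sample B on an ecological association network?*

Two members of the family are provided, alongside the nine indices they are
usually benchmarked against:

* **TINA** (Taxa INteraction-Adjusted), based on a co-occurrence network
  inferred from the count table itself (SparCC, Spearman, taxa-wise
  Bray–Curtis or weighted Jaccard);
* **PINA** (Phylogenetic INteraction-Adjusted), based on cophenetic
  similarities on a phylogenetic tree.

## The model

A raw interaction matrix I (co-occurrence correlations, or cophenetic
similarities I<sub>φ</sub>) is brought to a common scale by correlating taxa
association *profiles* (rows of I) and rescaling the Pearson correlation:

    C_ij = (1 + pearson(I_i*, I_j*)) / 2

so that C scales from 0 (avoidance) through 0.5 (neutral) to 1 (complete
association), and C = (J + R)/2 is positive semi-definite.  Community
similarity between samples A and B with relative abundances p<sub>A</sub>,
p<sub>B</sub> is then

    TU(A, B) = (1 / N_A N_B) Σ_{i∈A} Σ_{j∈B} C_ij            (unweighted)
    TW(A, B) = (p_Aᵀ C p_B) / sqrt((p_Aᵀ C p_A)(p_Bᵀ C p_B)) (weighted)

and PU/PW are the same forms with the phylogenetic association matrix Φ.
TW is exactly 1 for identical communities; for communities sharing *no* taxa
the indices tend to 0.5 under neutral associations, to 0 under avoidance and
up to 1 under complete association — unlike count-based indices, which are
pinned to 0.

The package also ships the multivariate machinery used to evaluate the
indices — sequential (adonis-style) PERMANOVA, PCoA, distance–gradient
correlations — and generalized Lotka–Volterra simulation engines that
generate habitat-structured count tables with controllable habitat
preference, co-abundance and explicit interaction structure.

## Worked example

Simulate a community with habitat preference but neutral dynamics, then ask
which index best separates the two habitats:

```python
from netdiv.simulate import make_benchmark_scenario
from netdiv.workflows import run_benchmark

res = make_benchmark_scenario("habitat_only", seed=0)   # 50 samples x 200 taxa
df = run_benchmark(res.table, res.labels,
                   indices=["JCI", "BC", "MH", "TU", "TW"],
                   network_method="sparcc", n_perm=999, seed=0)
print(df.to_string(index=False))
```

```
index network            F       R2     p
  JCI  counts 2.206107e+02 0.821303 0.001
   BC  counts 1.838598e+02 0.792978 0.001
   MH  counts 4.748682e+02 0.908199 0.001
   TU  sparcc 1.779045e+03 0.973728 0.001
   TW  sparcc 2.503524e+08 1.000000 0.001
```

Each row is a PERMANOVA of that index's distance matrix against the habitat
grouping: F and R² measure effect size of the separation, p its permutation
significance.  All indices detect the (strong) habitat split, but the
weighted TINA built on a SparCC co-occurrence network separates the groups by
several orders of magnitude more sharply than the count-based indices —
habitat preference alone generates a co-occurrence signal that TINA exploits.

The same workflows are available from the shell:

```sh
netdiv simulate --scenario habitat_only --seed 0 --out-prefix sc
netdiv network  --counts sc.counts.tsv --method sparcc --seed 1 --out C.tsv
netdiv distance --counts sc.counts.tsv --index tw --assoc C.tsv --out D.tsv
netdiv permanova --dist D.tsv --meta sc.labels.tsv --terms habitat --perms 999 --seed 2
```

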