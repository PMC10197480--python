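# traitnet

Plant functional traits are not independent: leaf economics, stem/root
chemistry and leaf structure covary as coordinated strategy axes, and the
*pattern* of that covariation — not just its pairwise strength — carries
ecological signal. `traitnet` implements the trait-network approach to that
pattern for ecologists working with species × trait tables: traits become
nodes, statistically significant pairwise correlations become edges, and
graph-level parameters summarise how integrated or modular a flora's
phenotype is.

## The method

Given an `n × p` table of species records over `p` traits (canonically 16,
partitioned into 6 *economic*, 6 *chemical* and 4 *structural* traits):

1. log-transform all trait values (traits are positive and near-lognormal);
2. compute all pairwise Pearson correlations `r_ij` with two-sided p-values
   from `t = r√(n−2)/√(1−r²) ~ t(n−2)`, on pairwise-complete records;
3. build the adjacency matrix `A = [a_ij]`, `a_ij = 1 ⇔ p_ij < α` (α = 0.05,
   strict; edges unsigned);
4. compute per-trait **degree** `k_i = Σ_j a_ij`, **edge density**
   `m / (p(p−1)/2)`, and **modularity** `Q = Σ_c (e_cc − a_c²)` of a detected
   community partition (deterministic greedy modularity maximisation with
   local refinement; seeded Louvain optional);
5. identify **hub traits** (highest degree) and **category importance**
   (absolute = mean degree per category; relative = that over the total
   degree sum).

Uncertainty comes from a species **bootstrap** (B replicates of ≥ 75% of the
species, summarised as mean/SD/SE/min/max with SE = SD/√B); the dependence on
species richness from a **rarefaction** simulation (R networks per species
count); and group contrasts (woody vs herbaceous life-forms, arid vs
semi-arid regions split at aridity index 0.2) from per-group pipelines with
Welch t-tests on bootstrap distributions and Duncan's multiple range test
letters. A synthetic generator with planted block-modular correlation
structure provides ground-truthable inputs; see `docs/methods.md`.

## Worked example

`examples/01_build_network.py` generates 188 synthetic species records with
the default planted structure, builds the network and prints:

```
records: 188, traits: 16
edges: 52 of 120 possible
edge density: 0.433   (share of trait pairs significantly correlated)
modularity Q: 0.337   (2 modules; higher = tighter within-module coupling)
top hub traits (most connected):
  LCC    degree 9
  LT     degree 9
  A_area degree 8
category importance (mean degree / share of total degree):
  economic    7.67  0.0737
  chemical    6.00  0.0577
  structural  5.50  0.0529
```

43% of trait pairs are significantly correlated; the detected partition
separates two modules at Q = 0.34; leaf carbon concentration (LCC) and leaf
thickness (LT) are the most connected traits of this draw; and economic
traits carry the highest mean connectivity. The other examples cover
bootstrap uncertainty (`02`), the species-richness effect (`03` — density
rises and modularity falls as species are added), group contrasts with
Duncan letters (`04`), and the full orchestrated run (`05`).

The same stages are scriptable from the shell:

```sh
ptn simulate --seed 42 --out traits.csv
ptn build traits.csv --out network/
ptn bootstrap traits.csv --B 5000 --seed 1 --out bootstrap.csv
ptn rarefy traits.csv --counts 10,25,50,100,188 --seed 1
ptn compare traits.csv --group-by life_form
ptn run --config run.yaml
```

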