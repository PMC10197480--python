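# Methods

## The model

`traitnet` analyses the interdependence of plant functional traits as a
network. Given a table of species records by `p` traits (here the canonical
16: six leaf *economic* traits A_area, LMA, LT, LNC, LCC, LPC; six stem/root
*chemical* traits RCC, RNC, RPC, SCC, SNC, SPC; four leaf *structural* traits
LD, LV, LDMC, LA), the pipeline:

1. **log-transforms** every trait value (natural log; trait values are
   strictly positive concentrations, areas and rates, and their marginals are
   near-lognormal, so correlations are computed on the log scale);
2. computes all pairwise **Pearson correlations** with two-sided p-values from
   the exact t-transform `t = r·sqrt(n−2)/sqrt(1−r²)` on `n−2` degrees of
   freedom, over pairwise-complete records;
3. thresholds at `p < α` (default α = 0.05, strict inequality) into a binary,
   symmetric, hollow **adjacency matrix**. Edges are unsigned: a significant
   negative correlation is an edge like a positive one. Signs stay available
   in the correlation result and the exported edge list;
4. computes the three network parameters: per-trait **degree**, **edge
   density** `m / (p(p−1)/2)`, and **modularity** `Q = Σ_c (e_cc − a_c²)`
   (Newman–Girvan) of a detected community partition;
5. ranks **hub traits** by degree and summarises **category importance**
   (absolute = mean degree of a category's traits; relative = absolute divided
   by the total degree sum).

No multiple-testing correction is applied by default — the raw per-pair
threshold is the procedure under study; a Benjamini–Hochberg option exists
behind `adjust="bh"` and is clearly not the default.

## Community detection

The method is deliberately deterministic by default: greedy agglomerative
modularity maximisation (Clauset–Newman–Moore) followed by a deterministic
single-node-move refinement sweep (nodes in index order, a move only on a
strict Q gain, ties to the lowest community label, stop on a moveless sweep).
The refinement exists because plain greedy agglomeration is known to misplace
individual nodes — on planted-block benchmarks it returned a lower-Q partition
than the planted one in roughly one dataset in eight — and a local sweep
repairs exactly that class of error without sacrificing bit-reproducibility.
Seeded Louvain is available as an alternative. Isolated traits always form
singleton modules, and the empty network is assigned Q = 0 with an
all-singleton partition, by convention.

## Resampling designs

**Species bootstrap** (default B = 5000): each replicate draws, without
replacement, a subset whose size is uniform on `[⌈0.75·n⌉, n]` ("at least
three-quarters of the species"), rebuilds the network, and records every
parameter. Summaries report mean, SD (sample, ddof = 1; exactly 0 for a
constant replicate vector), SE = SD/√B, min and max. A fixed-fraction mode
(exactly `⌈0.75·n⌉`) exists because the subset-size rule is a genuine design
ambiguity.

**Rarefaction / species-number simulation** (default R = 500 networks per
count): per species count `c`, draw `c` records — *with replacement* by
default, duplicates kept as rows — and summarise edge density and modularity
against `c`. Caveat stated plainly: duplicate rows inflate the effective
sample size behind each p-value, so under the null the false-edge rate rises
above α at small counts (≈ 0.08 at c = 10 from a 250-record pool, versus
exactly α without replacement). The without-replacement mode exists for that
reason, and the calibration property is asserted in that mode.

## Group contrasts

Records split by life-form (woody / herbaceous) or aridity region (aridity
index < 0.2 → arid; ≥ 0.2 → semi-arid — the boundary itself is assigned to
semi-arid, a convention the data description leaves open). Per group the full
pipeline runs; between two groups a **Welch t-test** compares the bootstrap
distributions of edge density and modularity. Bootstrap replicates are not
independent samples, so these p-values are descriptive measures of
separation, not strict inference — the package mirrors the field's reporting
style without endorsing it. A pooled-variance mode is available behind a flag.

**Duncan's multiple range test** produces the letter groupings over traits'
bootstrap degree distributions (and over category importance). Items are
ranked by mean; the shortest significant range for a span of `s` means is
`q_{s,df}(protection) · sqrt(MSE/n_h)` with the studentized-range quantile at
the classical protection level `1 − (1−α)^{s−1}`, pooled within-item MSE, and
harmonic-mean replicate count `n_h`; ranges are tested step-down so a range
inside a non-significant one is never declared significant. Error degrees of
freedom are capped at 1000 when evaluating the quantile (beyond that the
quantile is flat to numerical precision and the scipy evaluation is slow).
Zero pooled variance with unequal means yields distinct letters.

## Synthetic data

The generator emulates the statistical shape of dryland trait surveys, whose
raw data are typically not deposited: `n` records (default 188, the size of a
pooled species-by-community table; surveys of this kind run ~80–190 records),
16 positive traits with lognormal marginals (log-mean 0, log-sd 0.5 — a
realistic coefficient of variation for trait data), and a block-modular
correlation matrix aligned with the 6/6/4 functional categories: within-block
ρ_in (default 0.4, an intermediate, realistic trait-coupling strength),
between-block ρ_out (default 0.1; ρ_out < ρ_in so modules are detectable in
expectation). Records are multivariate normal on the log scale and
exponentiated, so the pipeline's log-transform recovers the planted
correlations exactly. Optional features:

- a planted **hub** trait (default suggestion SPC) whose correlation with
  every trait outside its block is raised to `hub_rho`; the resulting matrix
  may leave the PSD cone and is repaired by iterated eigenvalue clipping with
  unit-diagonal renormalisation (a warning is raised; failure to repair is an
  error);
- **groups** whose correlation strengths are scaled multiplicatively
  (affecting ρ_in and ρ_out together) — connectivity effects, not mean
  shifts, because the group contrasts of interest are about connectivity;
- aridity indices drawn uniformly on (0.02, 0.51), on the matching side of
  0.2 for labelled aridity groups.

One master seed drives everything through spawned substreams, so any single
group or rarefaction count can be regenerated in isolation.

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: spatial/site structure, phylogenetic
non-independence among species, climate covariates, measurement error
structure, and non-lognormal marginals. Results on synthetic data validate
the machinery, not ecological conclusions.

## Problem sizes and power choices

- Planted-recovery experiments use n = 500 records at ρ_in = 0.9, ρ_out = 0:
  strong enough that the within-block edges are essentially certain while
  spurious cross edges stay near the α level.
- The group-contrast experiment (ρ_in 0.9 vs 0.4) uses 500 records per group.
  This is a power choice: at ρ_in = 0.9 a block behaves like a single latent
  factor, so all 84 cross-block correlations co-fluctuate with sd ≈ n^(−1/2);
  at ~100 records per group that factor noise swamps the planted direction of
  the edge-density contrast, while at 500 the direction is recovered reliably.
- Bootstrap checks run at B = 500 and rarefaction at R = 100 per count;
  summaries scale to the full B = 5000 / R = 500 defaults unchanged.

## Numerical conventions

- Pairs with fewer than 4 pairwise-complete records, or zero variance, get
  r = missing and p = 1: never an edge, never a crash (small bootstrap
  subsamples make this reachable).
- `p = α` exactly is not an edge (strict threshold).
- |r| clipped to 1 before the t-transform; |r| = 1 maps to p = 0.
- Hub ranking breaks degree ties lexicographically by trait name.
- Module labels are consecutive integers ordered by each module's first trait.
- Welch's test with two constant, equal samples returns t = 0, p = 1.
- Aggregation (optional, default off — the unit of analysis is the caller's
  choice) averages on the raw scale before the log-transform; the two orders
  do not commute (arithmetic vs geometric means) and a regression test pins
  the default.
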