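# ldscape

Genome-wide analysis of the recombination landscape, genetic diversity and
linkage disequilibrium (LD) on a SNP linkage map with unphased genotypes —
the situation typical of outcrossing tree species genotyped on medium-density
arrays, where a composite genetic map (a dozen linkage groups, one to two
thousand mapped SNPs) and a dosage matrix for a few hundred unrelated
individuals are all the data there is.

`ldscape` is aimed at population and quantitative geneticists who want, from
those two inputs:

* **Recombination cold/hot spots** per linkage group (LG), from a Gaussian
  kernel density of marker positions with a Sheather–Jones plug-in bandwidth.
  Sampling variability comes from resampling 70% of markers without
  replacement (999 replicates, 2.5/97.5-percentile band); the band is
  compared with the Poisson range for the expected markers per bandwidth
  window, λ = n·h/L. A *cold spot* (marker cluster, little recombination) is
  called where the band's lower limit exceeds the Poisson upper range; a
  *hot spot* (marker paucity) where its upper limit falls below the lower
  range.
* **Per-marker diversity**: allele frequency p, MAF, observed heterozygosity
  Ho, Nei's expected heterozygosity He = 2p(1−p) (max 0.5 for a biallelic
  marker), and an exact conditional Hardy–Weinberg test (enumeration over
  heterozygote counts given allele counts), with Bonferroni bookkeeping,
  ANOVA + Tukey HSD comparison of He across LGs, sample call-rate QC and
  duplicate-sample detection.
* **Spatial structure of diversity**: the empirical variogram
  γ̂(h) = 1/(2N(h)) Σ (z\_i − z\_j)² of He against map distance (within-LG
  pairs only, 0.15 cM lags to 10 cM), classical or Cressie–Hawkins robust
  estimator, with a permutation envelope (He shuffled across map positions,
  1000 permutations).
* **LD**: Rogers–Huff r² for unphased data (squared Pearson correlation of
  dosages over pairwise-complete individuals) for all marker pairs within and
  between chromosomes; a long-distance LD null distribution built by
  filtering out pairs that component maps reveal to be physically close; an
  inter-chromosomal test against the Bonferroni-adjusted upper quantile of
  that null; and a nonlinear fit of the drift–recombination expectation

      E(r²) = (10+C)/((2+C)(11+C)) · [1 + (3+C)(12+12C+C²)/(n(2+C)(11+C))]

  with C replaced by C·d to estimate the population recombination parameter
  C = 4N\_e·c per unit distance from observed decay.
* **Map concordance**: per-LG RMSE and Spearman rank correlation between
  composite and component maps, and paired Wilcoxon signed-rank comparison of
  map-merging methods.

A fully seeded synthetic-data module generates linkage maps with planted
marker clusters and gaps, and genotypes built mechanistically from founder
haplotypes recombined along the map (Haldane mapping function), with a
discovery-panel MAF ascertainment mimic — so every stage of the pipeline is
testable without any external data.

## Worked example

```python
import numpy as np
from ldscape import (ClusterSpec, SimulationConfig, MarkerDensityModel, HeVariogram,
                     simulate_map, simulate_genotypes, diversity_table, fit_decay,
                     simulate_decay_pairs)

cfg = SimulationConfig(n_lg=3, n_markers_per_lg=120, n_individuals=186,
                       clusters={2: [ClusterSpec(40.0, 1.0, 25)]}, seed=42)
rng = np.random.default_rng(cfg.seed)
lmap = simulate_map(cfg, rng)
gm = simulate_genotypes(lmap, cfg, rng)

div = diversity_table(gm)
print(f"mean He = {div['he'].mean():.3f}; markers failing HWE at 5%: "
      f"{(div['hwe_p'] < 0.05).sum()} of {len(div)}")

res = MarkerDensityModel(lmap, bandwidth=2.0, n_rep=499).fit(seed=0)
print(res.summary())
print(res.spots)

vres = HeVariogram(lmap, div.set_index('marker_id')['he']).fit(n_perm=500, seed=0)
print(vres.summary())

tbl = simulate_decay_pairs(0.005, 186, np.linspace(1, 3000, 200), noise_sd=0.03, seed=1)
fit = fit_decay(tbl["distance_bp"], tbl["r2"], 186)
print(fit.summary())
```

Output:

```
mean He = 0.421; markers failing HWE at 5%: 15 of 385
Marker-density landscape
  LG uniformity chi2(2) = 0.006, p = 0.9972
  cold spots: 1    hot spots: 0
  LG  n_mk  length  bandwidth  lambda  range    cold>=  hot<=
  1   98    111.6   2.00       1.76    [0,5]   8       -
  2   130   147.4   2.00       1.76    [0,5]   8       -
  3   157   179.6   2.00       1.75    [0,5]   8       -
   lg  start_cm  end_cm  type
0   2     37.55   42.25  cold
He variogram (classical estimator), lag 0.15 cM up to 10.0 cM
  bins with pairs: 67 / 67    total pairs: 3563
  permutations: 500    fraction of bins inside 95% envelope: 0.985
LD decay fit (drift-recombination equilibrium expectation)
  pairs: 200    sample size n: 186
  C_per_bp: 0.00514896  (SE 0.000128)
  RSS: 0.151121    converged: True
```

Read it as: diversity is high (mean He 0.421 of a 0.5 maximum) and the HWE
rejection count matches the nominal 5% level; the marker cluster planted at
40 cM on LG2 is recovered as the single cold-spot call (37.6–42.3 cM) while
the uniform LGs produce none; the He variogram sits inside its permutation
envelope in 98.5% of distance bins (no spatial structure of diversity, as
simulated); and the decay fit recovers the planted C = 0.005/bp within two
standard errors.

The same analyses run from the shell on TSV/VCF inputs or a simulated
dataset:

```sh
ldscape pipeline --seed 1 --out results/run1       # simulate + all stages
ldscape recomb   --seed 1 --out results/run1       # re-run one stage in place
```

Every stage writes plain TSV/JSON; a run record (config, seed, version)
makes runs reproducible byte for byte.

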