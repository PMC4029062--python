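# Methods

This note documents the statistical procedures implemented in `ldscape`,
their assumptions, the defaults and why, the synthetic-data model, and the
numerical choices made where the design was genuinely open.

## Data model

A **linkage map** is a table (marker\_id, lg, position\_cm) with unique
marker ids, positive integer LG labels and non-negative positions, sorted
within LG. Tied positions are legitimate and preserved: SNPs from the same
contig co-segregate and sit 0 cM apart. Positions are used as given; the
length of an LG is its maximum position. A **genotype matrix** holds unphased
ALT-allele dosages 0/1/2 with a single missing sentinel; VCF half-calls
(`./1`) are conservatively treated as missing. All analyses are
missing-data-aware: statistics use called genotypes only, and pairwise
statistics use pairwise-complete individuals.

## Recombination landscape

Marker density along an LG is estimated by a Gaussian KDE. The bandwidth is
the Sheather–Jones solve-the-equation plug-in, implemented with exact
pairwise sums (the classic two-stage recipe: normal-scale pilot bandwidths
for the fourth- and sixth-derivative functionals, then a Brent root search
for the plug-in equation). It requires at least 10 points; smaller samples
should fall back explicitly to a rule-of-thumb bandwidth. The selector is
scale-equivariant and agrees with an independent reference implementation of
the same algorithm to well within 1% on test samples.

The KDE is evaluated on a 0.1 cM grid over [0, L]. **Boundary handling is by
reflection at both LG ends.** Simple truncation with renormalization was
considered and rejected: the truncated estimate dips systematically within
one bandwidth of each end (half the kernel mass falls outside the LG), which
the spot caller reads as a spurious marker deficit — in calibration runs on
uniform maps it produced a false hot-spot call at an LG edge on essentially
every simulated map. Reflection removes the edge bias; truncation remains
available as an option.

Uncertainty: 999 subsamples of 70% of the markers, drawn without
replacement; each replicate KDE is renormalized and rescaled to the full
marker count, and the pointwise 2.5/97.5 percentiles form the confidence
band. The reference level is the Poisson distribution of the number of
markers per bandwidth window, λ = n·h/L, with range [q(α/2), q(1−α/2)] at
α = 0.05. Cold spots are maximal grid intervals where the band's lower limit
exceeds the Poisson upper range; hot spots where the upper limit falls below
the lower range. Note the asymmetry this implies: hot spots are only
detectable when λ is large enough that the lower Poisson quantile is
positive (λ ≳ 4), i.e. on densely mapped LGs — sparse maps can never show a
significant deficit, only an excess.

Count thresholds ("a cold spot needs at least k markers per window, a hot
spot at most k") are reported as diagnostics: the smallest (largest) count
whose Poisson tail probability stays below α after Bonferroni correction
over the ⌈L/h⌉ windows tiling the LG. The operative caller is always the
band comparison.

Marker-count uniformity across LGs is a χ² goodness-of-fit with expected
counts proportional to LG lengths (df = K−1).

## Diversity and Hardy–Weinberg

Per biallelic marker: reference-allele frequency p from called genotypes,
MAF = min(p, 1−p), Ho = fraction of heterozygous calls, He = 2p(1−p). He is
deliberately the plain product estimator — its maximum for a biallelic locus
is exactly 0.5, which keeps the scale interpretable; the 2n/(2n−1) unbiased
correction (which can exceed 0.5) is available behind a flag.

The Hardy–Weinberg test is exact by default: conditional on the observed
allele counts, the probability of every admissible heterozygote count is
computed (in log space, stable to thousands of genotypes) and the p-value
sums those configurations no more probable than the observed one. This
matches a rational-arithmetic enumeration oracle on every table with n ≤ 20.
A 1-df χ² alternative is available for speed. Under simulated HWE genotypes
the exact test rejects slightly *less* than 5% of markers at the nominal 5%
level — expected, since the discrete exact test is conservative.

Duplicate detection reports all sample pairs with genotype identity above
0.995 over shared non-missing calls, requiring at least 100 shared calls for
a verdict (an identity estimated from a handful of calls is meaningless).
He differences across LGs use one-way ANOVA followed by Tukey HSD, with a
compact letter display derived by insert-and-absorb so that two LGs share a
letter iff they are not significantly different.

## Variogram of He

γ̂(h) = 1/(2N(h)) Σ\_{(i,j)} (z\_i − z\_j)², with pairs formed **within**
LGs only, binned by half-open lags [k·0.15, (k+1)·0.15) cM up to 10 cM;
co-located pairs fall in the first bin. The robust alternative is the
Cressie–Hawkins estimator, 0.5·(mean √|z\_i−z\_j|)⁴ / (0.457 + 0.494/N(h)),
which damps the influence of outlying He differences; the cited geostatistics
literature does not pin the robust variance estimator down further, so
Cressie–Hawkins — the standard robust variogram — is the documented choice,
and the classical estimator is always computable alongside. The pangenomic
variogram pools within-LG pairs across LGs (never pairing across LGs); for
the classical estimator this pooling is exactly the N(h)-weighted mean of
per-LG values.

Significance: He values are permuted across mapped positions genome-wide
(1000 permutations), giving a pointwise 95% envelope per bin and the
exceedance probability of each observed value. Spatially unstructured He
should sit inside the envelope in ≈95% of bins; smoothly varying He breaks
the lower envelope at short lags (low variance among close neighbours).
Kriging is deliberately out of scope.

## Linkage disequilibrium

r² between loci with unknown phase is the squared Pearson correlation of
genotype dosages over pairwise-complete individuals (the Rogers–Huff
composite-LD formulation). It is symmetric, invariant to allele relabelling,
undefined (and excluded from scans) for pairs monomorphic among shared
calls, and validated against haplotype-truth r² computed from the
simulator's phased gametes: the mean absolute error shrinks with sample size
(≈0.008 at n = 400).

The genome-wide scan covers all C(m,2) pairs; intra-chromosomal pairs carry
the composite-map distance (0 cM for co-located markers), inter-chromosomal
pairs carry none. The scan applies no MAF filter by default; filters are
explicit parameters (5% is conventional for within-contig physical-LD work,
20% for the long-distance null, following the critical values used in the
source analyses; the r² > 0.1 retention cutoff is likewise a parameter).

The **long-distance null model** addresses a composite-map artifact: a pair
far apart on the composite map may be an ordering error, with the markers
physically close. Starting from intra-chromosomal pairs at distance > 0 with
r² > 0.1, pairs are dropped when any single component map carrying both
markers places them at 0 cM or within 1 cM, and when the markers never
co-occur on one component map (their distance cannot be verified); finally
pairs with either MAF ≤ 20% are dropped. Every filter's count is recorded in
an audit trail satisfying input = retained + Σ exclusions. When a pair
survives, sibling SNPs from the same contig can corroborate it: agreement of
a sibling's r² with the pair's own within ±0.1 is reported per pair.

The **inter-chromosomal test** compares each between-LG r² with the
empirical (1−α) quantile (linear interpolation) of the null, Bonferroni-
adjusted over the number of inter-chromosomal pairs tested.

The **decay fit** models observed r² at distance d as the drift–
recombination equilibrium expectation E(r² | C·d, n), estimating the per-bp
(or per-cM) population recombination parameter C by unconstrained nonlinear
least squares: a coarse positive log-grid supplies the start, Levenberg–
Marquardt refines it, and the standard error comes from the Gauss–Newton
covariance RSS/(k−1)·(JᵀJ)⁻¹. A negative estimate — which genuinely happens
when r² shows no decay — is flagged, never clipped. Two limits of the
formula worth knowing: at C = 0 and large n, E(r²) → 10/22 ≈ 0.455; as
C → ∞ at fixed n, E(r²) → 1/n (the finite-sample floor), not 0.

## Map concordance

Per LG over shared markers: RMSE of positions and Spearman rank correlation
(ties mid-ranked). An LG has no intrinsic orientation, so each LG is
compared as-is and flipped (length − position), keeping the orientation with
the larger |ρ| — on exact ties, the one with positive ρ — and recording the
choice. Markers assigned to different LGs by the two maps are reported as
conflicts and excluded. Method comparison uses the two-sided Wilcoxon
signed-rank test on paired per-LG metrics, exact null for n ≤ 25; all-zero
differences yield p = 1 with a warning.

## Synthetic data

The generator emulates the archetype study shape: 12 LGs with lengths
evenly spanning 115–182 cM, ~150 SNPs per LG (1,800 total), 186 diploid
individuals, ~92% call rate (missingness 8% completely at random), three
duplicated samples injected under new ids.

* **Map**: background marker counts per LG are multinomial in proportion to
  LG length (uniform placement over the genome; a fixed count per LG is an
  option), positions uniform within the LG; planted Gaussian clusters add
  markers (cold spots) and planted gaps delete them (hot spots).
* **Allele frequencies** are uniform on (0,1), accepted only when a
  simulated discovery panel of 12 gametes shows MAF ≥ 0.33 — the
  ascertainment mimic that shifts the MAF spectrum upward, as array design
  from a small sequencing panel does. Fewer than 2% of simulated markers end
  below 5% MAF.
* **Genotypes**: a pool of founder haplotypes (default 16) carries alleles
  drawn independently at those frequencies; each individual receives two
  gametes formed by a copying walk along the map that redraws the founder
  with the interval's Haldane recombination fraction c = ½(1−e^(−2d/100)).
  Expected genotype frequencies are Hardy–Weinberg, and r² between markers
  decays with genetic distance because nearby markers share founder origin.
  The founder-pool size sets the short-range LD ceiling (r²(0) ≈ 1/K for K
  founders in linkage equilibrium; K = 2 forces r² = 1 at 0 cM).

What this does **not** emulate: population structure and relatedness (the
archetype population is shown unstructured), selection, mutation, interference
(Haldane assumes none), genotyping-error clusters, and the *physical* (bp)
scale of real LD decay — one round of recombination from a founder pool
produces decay on the map scale, not the sub-kilobase decay of a large
outcrossing population. Passing tests therefore demonstrate the estimators'
correctness and calibration, not organism-specific decay rates.

The decay-pair generator is separate and exact: r² values on the E(r² | C·d,
n) curve plus Gaussian noise clipped to [0,1]. In the recovery tests the
noise sd is 0.03 with distances to 3000 bp at C = 0.005/bp, chosen so that
clipping is negligible (<1%): heavy clipping distorts the error model and
with it the nominal 2-SE coverage that the recovery test asserts.

## Problem sizes and determinism

All stochastic procedures take explicit seeds; the pipeline splits one run
seed into per-stage substreams so single-stage re-runs are byte-identical.
Test and acceptance runs use deliberately modest sizes — hundreds of markers
per LG, a few hundred resampling replicates where the default is 999, 20
calibration seeds — which keep every check well under a minute while leaving
the asserted properties (coverage, calibration, recovery) comfortably
resolvable.

## Known limitations

* The exact HWE test enumerates heterozygote configurations; for very large
  n with balanced allele counts this is O(n) per marker — fine in practice,
  and the χ² option exists for bulk screening.
* The long-distance null needs component maps; without them only the MAF
  filter applies, and the audit trail says so.
* Hot spots are undetectable on sparsely mapped LGs (see the Poisson
  lower-bound asymmetry above); this mirrors the behaviour of the original
  band construction rather than a defect.
* The count-threshold diagnostic is one reasonable reading of a
  window-counting construction that is not fully specified in the source
  analyses; it is reported alongside, never used for calling.
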