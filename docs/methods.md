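# Methods

This note documents the statistical models, the synthetic-data
generator, and the numerical choices made in `sdapower`. All quantitative
statements here are computed by the test suite or by
`scripts/acceptance.py`; none are copied from external sources.

## Assignment model

Individuals are scored with the Rannala–Mountain partial-Bayesian
genotype probability: allele frequencies in each candidate population are
given a Dirichlet prior with α = 1/k per allele, where k is the number of
distinct alleles observed at the locus across *all* populations (the
global inventory, recomputed whenever the table is subset). The
posterior-predictive probability of a genotype given the population's
allele counts n₁…n_k (total n) is

- heterozygote (i ≠ j): 2 (nᵢ + 1/k)(nⱼ + 1/k) / ((n + 1)(n + 2))
- homozygote (i = i): (nᵢ + 1/k)(nᵢ + 1 + 1/k) / ((n + 1)(n + 2))

Multilocus log₁₀-likelihoods are sums over called loci (missing loci are
skipped). The prior mass keeps likelihoods finite for alleles never seen
in a candidate population. These single-locus probabilities sum to 1 over
all genotypes by construction; the test suite verifies this by
enumeration and against hand-evaluated values.

Two test statistics are supported: the home-population likelihood `Lh`,
and the ratio `Lh/Lmax` of home likelihood to the maximum over all
sampled populations (the operational default for migrant detection when
all plausible sources are sampled). Significance is judged against a
Monte Carlo null: `n_simulated` genotypes are resampled locus-by-locus
from the home population's observed allele frequencies (two independent
draws per locus — Hardy–Weinberg and linkage equilibrium assumed), scored
identically, and the p-value is `(1 + #{null ≤ observed}) /
(1 + n_simulated)`. An individual is flagged as a first-generation
disperser when p < α (default 0.01).

### Missing-data calibration

A subtle bias was found and fixed during development: an individual with
missing loci has a statistic summed over fewer terms than a null of
complete genotypes, making its p-values systematically conservative and
non-uniform (Kolmogorov–Smirnov distances of 0.06–0.10 against the
uniform on synthetic residents with 1% missingness, versus 0.02–0.05
with complete data). `detect_migrants` therefore rescores the shared null
draws separately for each missing-data pattern, so every individual's
null statistic sums exactly the loci called in that individual. After
the fix, null p-values on 500 synthetic residents give KS ≈ 0.02–0.04
and a type-I error within the binomial 95% confidence band around α
(verified in `tests/test_acceptance.py`).

Calibration checks use the plain `Lh` statistic: the ratio `Lh/Lmax` has
a point mass at 1 (for most true residents the home population *is* the
most likely source), so its p-values cannot be uniform under any
implementation; uniformity is a property of the Monte Carlo machinery,
which `Lh` exposes cleanly.

## Population-genetic statistics

- **PIC** (polymorphic information content):
  `1 − Σpᵢ² − (Σpᵢ²)² + Σpᵢ⁴`, computed on pooled allele frequencies.
- **Weir–Cockerham θ**: method-of-moments variance components a, b, c
  per allele per locus; the multilocus estimate is Σa / Σ(a+b+c) over all
  loci and alleles. Verified against an independent transcription of the
  component formulas.
- **Shannon mutual information** between allele identity and population
  label, in nats, averaged over loci, with population weights
  proportional to called allele counts. Zero iff the two populations have
  identical frequencies everywhere.
- **Hardy–Weinberg exact test**: Monte Carlo shuffling of the allele
  array, with the Levene conditional probability of a genotype array
  given its allele counts as the ordering statistic; verified against
  full enumeration on biallelic tables (agreement within 3 Monte Carlo
  standard errors).

## Synthetic-data generator

Genotypes are drawn under the Balding–Nichols model: subpopulation
frequencies are Dirichlet-distributed around an ancestral vector p with
concentration (1−F)/F, so the expected Weir–Cockerham θ between two
independent subpopulations is ≈ F. The acceptance suite verifies
recovery: over 50 replicates the mean estimated θ is within 10% of the
configured F.

The **starling-like preset** reproduces the structure of a three-colony
microsatellite study (30/32/32 individuals × 29 loci): one distant
population is drawn at F = 0.069 from the ancestral vector, and a close
pair is drawn at F = 0.026 around a shared cluster vector itself drawn
at F = 0.069, giving expected pairwise θ ≈ 0.082 for the distant pairs
and ≈ 0.026 within the close pair. Realised single-dataset values
scatter substantially at these sample sizes (e.g. 0.073/0.064/0.036 at
seed 1); tests assert a 0.01–0.13 band and the ordering (close pair less
differentiated), not point values.

Generator realism and limits: loci are independent (no linkage),
populations are at Hardy–Weinberg equilibrium by construction, allele
counts per locus are uniform on [2, 20], missingness is
missing-completely-at-random, and there is no genotyping error,
null-allele structure, or inbreeding. Planted dispersers are fresh draws
from a source population's latent frequencies relabelled into another
population — true first-generation migrants with no admixture.

## Simulated Disperser Analysis

One candidate per population is chosen among individuals that look
resident (assignment p-value above a membership threshold, default
0.05). All kᵐ placements of the m candidates into the k populations are
enumerated (27 treatments for 3 populations, treatment 0 being the
identity), and each treatment is evaluated on 2L−1 nested panels (L
prefixes of the highest-PIC-first ranking plus L−1 proper prefixes of
the lowest-PIC-first ranking; 57 panels for L = 29). Outcomes are
classified as correct resident / correct disperser / false positive /
false negative / wrong source. The **minimal panel** for a candidate and
ranking direction is the smallest size from which every larger panel
yields correct outcomes across all treatments (infinite when none does).
The **worst-case quick check** moves every candidate to the population
with minimal pairwise mutual information (θ as fallback) and ranks loci
least-informative-first.

## Power model

Grid cells are flattened to one row per (treatment, candidate,
direction, panel), with the binary response `correct`, and modelled with
a binomial GLM (logit link) via iteratively reweighted least squares;
optional random intercepts are delegated to a variational-Bayes mixed
binomial model. Rank-deficient designs are reported with the aliased
column names; complete separation falls back to an L2-regularised fit
and flags the result. Marginal and conditional R² follow
Nakagawa–Schielzeth with logit distribution variance π²/3, e.g.
σ²_fixed = σ²_random = 1 gives R²m = 1/(2 + π²/3) ≈ 0.18904 and
R²c ≈ 0.37808.

## Numerical and reproducibility choices

- All stochastic components take explicit seeds; sub-seeds are derived
  with BLAKE2b over (seed, context tokens), so grid cells, null draws and
  permutation tests are independent yet reproducible, and reruns are
  byte-identical.
- Likelihood scoring uses precomputed per-(population, locus) log₁₀
  genotype tables and fancy indexing; a full 27 × 57 grid with
  1,000-draw nulls runs in well under a minute on one CPU.
- Null distributions use 1,000 draws in tests and the acceptance script
  (the operational default is 10,000); the Monte Carlo p-value includes
  the +1 correction so p is never 0.
- Monte Carlo HWE p-values are compared to enumeration with a 3-SE plus
  1-ULP-of-discreteness allowance (2/n_permutations).

## Limitations

- Calibration of p-values is demonstrated for the `Lh` statistic; the
  `Lh/Lmax` ratio is deliberately anti-conservative as a detection
  statistic and its p-values are not uniform under the null.
- The generator's independence and equilibrium assumptions mean SDA
  results on synthetic data are best-case with respect to linkage and
  scoring error.
- Minimal panel sizes are step functions of a finite Monte Carlo grid;
  with weakly differentiated pairs a candidate may show an infinite
  minimal panel purely because a single cell near the decision boundary
  flips — report them alongside the grid curves, not in isolation.
- Mixed-model (random-intercept) fits use a variational approximation;
  fixed-effect GLM fits are exact IRLS solutions.
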