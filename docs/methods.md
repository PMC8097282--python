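# Methods

## The problem

After two diverged populations admix, recombination progressively shreds the
introgressed (donor) haplotypes in the recipient population.  Under neutral
admixture the donor ancestry frequency stays near the pulse fraction *m* and
donor tracts are short; if an introgressed allele is positively selected, its
neighbourhood shows (i) an elevated donor-ancestry frequency and (ii)
unusually long donor tracts.  `introscan` turns both signatures into a
per-site likelihood-ratio test and a maximum-likelihood estimate of the
selection coefficient, using a hidden Markov model of local ancestry whose
transition rates are distorted by selection at a focal site.

## Model

**Demography.** A single ("one-pulse") admixture event: a fraction *m* of a
recipient population of effective size *Ne* diploids is replaced by donor
individuals *t* generations before sampling.  *Ne*, *m* and *t* are inputs,
assumed estimated beforehand by standard local-ancestry tooling.

**Selection and trajectory.** The selection coefficient *s* is genic: a
diploid carrying *d* copies of the selected donor allele has fitness
`1 + s d` (a heterozygote experiences half the selective strength of a
homozygote).  The deterministic frequency trajectory solves
`x' = x(1+s)/(1+sx)` exactly:

    x_g = m (1+s)^g / (1 - m + m (1+s)^g),

the familiar logistic curve (we use the per-generation odds factor `1+s`
rather than `e^s`; the two agree to O(s^2 g) and the former is the exact
solution of the recursion, which the unit tests exploit as an oracle).  For
very small pulses (m ≲ 0.01) a conditioned stochastic trajectory is
available: the mean of binomial Wright–Fisher replicates that retain the
allele at time *t* (default 1,000 replicates).  Trajectories are clipped to
`[1e-9, 1 - 1e-9]` before entering any rate computation, so near-fixation
inputs yield finite rates; curves built from a trajectory ending above
`1 - 1e-6` carry a `fixation_regime` flag because *s* is known to be poorly
estimated once the allele has fixed.

**Neutral transition rates.** Under neutrality the ancestry process along a
chromosome is a two-state Markov chain with switch hazards per Morgan

    L10 = 2 Ne (1 - m) (1 - e^{-t/2Ne}),      L01 = L10 m / (1 - m),

so the stationary donor frequency is *m*.  The saturation with `2Ne` captures
coalescence: junctions formed long ago may be erased when their flanking
lineages coalesce.

**Selection-distorted rates.** Around a selected site, hazards become
distance dependent: `f10(r)` (donor→recipient) is suppressed near the site
and grows monotonically to `L10`; `f01(r)` is elevated near the site and
decays to `L01`.  We compute them from a three-locus forward recursion: the
selected site plus a closely spaced marker pair at distance *r*, tracked as a
2×2×2 haplotype-frequency tensor.  Each generation, selection reweights the
selected-site axis so its marginal follows the trajectory, and recombination
in either gap splices in a random population chromosome; a splice in
generation *g* carries the coalescence weight `e^{-(t-1-g)/2Ne}`, which makes
the neutral limit exact.  The hazards are the pair's conditional switch
probabilities per Morgan, *marginalised over the selected-site state*.  This
choice is deliberate: it makes the HMM's transition kernel match the true
pairwise ancestry statistics, and — run outward from the focal site — it
reproduces the hitchhiking-elevated marginal donor frequency at every
distance (both properties are verified against the forward simulator).

**Four-point approximation.**  Evaluating the recursion for every interval is
slow, so the default backend fits the parametric form

    f10(r) = L - k e^{-alpha r^p}

(and the mirrored form approaching `L01` from above for `f01`), anchored at
numerically computed hazards at r ≈ 0, r1 = r2/10 and r2 = 2/L10 (the
expected neutral tract length), with the fourth point being the neutral limit
at infinity: `k = L - f(0)`, `y_i = log((L - f(r_i))/k)`,
`p = log(y1/y2)/log(r1/r2)`, `alpha = -y1/r1^p`.  Degenerate anchors (k ≤ 0,
as at s = 0) fall back to the constant-`L` curve; unresolvable exponents fall
back to a simple exponential through the r2 anchor.  Across the regimes we
validate, the parametric curve tracks the forward-iteration curve within
~5–7% of `L10` over `[0, 5 r2]`; the `forward` backend (tabulated hazards on
a log-spaced grid, 64 points per decade) is available when that matters.
Beyond the tabulated/anchored range both backends extrapolate to the neutral
limits.

**HMM.**  The hidden state at a site is the donor-ancestry dosage of a sample
(0..ploidy; pools are one sample of ploidy = number of pooled chromosomes).
Per-interval dosage transition matrices are the binomial lift (independent
chromosomes) of the exact two-state interval solution with trapezoidal mean
hazards, so rows are stochastic by construction and a zero-length interval is
the identity.  Emissions are unaffected by selection: panel allele
frequencies are estimated with a +1/+2 pseudocount (a flag disables it); in
pileup mode reads are binomial draws with per-read error ε around the
genotype implied by the ancestry-conditional panel frequencies, in genotype
mode the allele dosage is observed directly.  Sites where either reference
panel has zero sampled alleles are dropped (with a count) because the
emission mixture is undefined there; this treatment of uncovered sites is a
package choice, as is the pseudocount plug-in (validated by parameter
recovery rather than by equation match to upstream tools).

Under the *neutral* model the chain is stationary and evaluated left to right
from the binomial(ploidy, m) prior.  Under *selection at site p* the chain is
anchored at the focal site — state prior binomial(ploidy, x_t), the
selected-allele frequency at sampling — and evaluated outward in both
directions with the distance-dependent matrices; the two branches are
conditionally independent given the focal state.  The distance-only hazard
curves apply identically on both sides (mirror symmetry).  Samples are
independent, so log-likelihoods add.

**Scan.**  For each focal site (every `stride`-th site), the log-likelihood
ratio between the selection model and the neutral model is computed on a
window extending 10% of the chromosome length on each side (a fixed-Morgan
window is available because chromosome-fraction windows are map dependent).
`s` is optimised by golden-section search on log s over [0.001, 0.15]
(relative tolerance 1e-2, deterministic), or evaluated on a user grid.
Boundary maxima, truncated windows and fixation-regime curves are flagged.
Peaks are called greedily by descending LR with a minimum genetic separation
(default 2 cM, leftmost tie-break).  Significance is calibrated exclusively
by scanning neutral simulations with matching (Ne, m, t) and choosing the
smallest threshold whose mean false-discovery count per simulated genome does
not exceed a target (default 1); linkage between tests makes analytic
cutoffs unreliable, and the calibrated threshold scales with genome size, so
no universal constant is asserted.

## The simulator

The validation simulator is a discrete-generation Wright–Fisher forward
simulation of `Ne` diploids with exact ancestry-tract tracking (junction
lists), fitness-proportional parent sampling, Poisson crossovers without
interference on a sex-averaged map, and per-chromosome selected-site alleles
(so alleles segregating in the donor population are representable).
Scenarios cover: single or multiple additive selected sites, dominance
h ∈ {0, ½, 1} (fitness `1 + 2sh` het, `1 + 2s` hom), continuous gene flow
after the pulse (migrants carry the selected allele at its donor starting
frequency), conditioning on allele retention by restarting lost runs, an
optional early stop once the selected allele reaches a frequency bound
(default off: sampling times are fixed, and beyond 0.99 selection is
negligible anyway), and two-locus Dobzhansky–Muller incompatibilities
(dominant sign epistasis: any cross-population combination at the two loci is
penalised; or one-directional).

Variant sites are placed uniformly on the map.  Reference panels do not
re-implement any particular species demography: per site an ancestral
frequency is drawn from a 1/x density on [0.05, 0.95] and the two population
frequencies are Balding–Nichols dispersed around it with a single divergence
parameter F.  The default F = 0.3 was calibrated once so that the mean
per-site ancestry information (symmetrised KL divergence between pseudocount
panel allele distributions, 50-haplotype panels) matches coalescent panels
simulated under a two-population *Drosophila*-like demography
(African/cosmopolitan split with a strong out-of-Africa bottleneck,
Hudson Fst ≈ 0.19) at ancestry-informative sites (MAF ≥ 5%): symKL 0.575 vs
0.577.  Reads are Poisson(depth 2) per individual per site with a uniform
per-allele error of 0.01; pooled mode merges all chromosomes into one
observation column.  What the generator does **not** emulate: linkage
disequilibrium within the reference panels, site-frequency ascertainment,
variable recombination maps, sequencing-depth heterogeneity, and structural
variation — passing tests therefore demonstrate correctness of the method
under its own assumptions plus WF drift, not robustness to every property of
real data.

## Validation experiments and problem sizes

All validation runs use desk-scale sizes chosen once: populations of 10,000
diploids (full-scale analyses of this kind use ~100,000), one 1-Morgan / 10-Mb chromosome
with 2,000 variant sites (10,000 at ~1 kb spacing for the DMI localisation
experiment, matching *Drosophila*-like kb-scale marker spacing), 25
diploids at Poisson depth 2, ten seeded replicates per
experiment, scans at stride 25 (every 100th site for pools, whose emission
state space makes per-site evaluation costlier).  The experiments: (1) parameter recovery at
m = 0.1, s = 0.05, t = 200; (2) the same data re-scanned with m and t
perturbed ±20%; (3) the same data as a single 50-chromosome pool; (4/5) a
dominant-sign-epistasis DMI (50% pulse, |s| = 0.1, loci 40 cM apart,
t = 500, chosen so the winning co-adapted pair is fixed and its haplotype
signature narrow) scanned after the
ancestry label flip; (6) null-threshold calibration from 20 neutral
replicates at Drosophila-like m = 0.17, t = 430 (Ne = 5,000 for speed).

## Known limitations

* **Near-fixation upward bias at large pulses.**  At m = 0.1, s = 0.05 the
  selected allele passes 0.99 frequency by generation ~136; sampling at
  t = 200 sits well past fixation.  There the maximum-likelihood s is biased
  upward (mean relative error ~30–45% in our experiments) even though the
  model's marginal frequency profile and pairwise switch hazards match the
  simulation at the true s: the residual misfit is the drift-driven
  clustering of the rare recipient-ancestry remnants into few long blocks,
  a correlation structure no Markov chain over these states can express, and
  the likelihood trades it against a wider transition-rate dip.  In regimes
  sampled before or shortly after fixation (t ≤ 150 here), and in the
  small-pulse showcase regime (m = 0.01, s = 0.05, t = 500), mean relative
  error is ~12%.  Estimates with the `fixation_regime` flag should be read
  as order-of-magnitude.
* The estimator assumes the one-pulse model; continuous gene flow, donor
  segregation and dominance are handled only through the generic scan (with
  reduced accuracy), and there is no multi-pulse or background-selection
  model.
* Power depends strongly on per-site ancestry information × site density;
  with sparse, low-divergence data the posterior shrinks toward the binomial
  prior and LR power drops smoothly (no warning is emitted).
* No X-chromosome inheritance, no crossover interference, no panel LD.
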