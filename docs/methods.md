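# Methods

## Data model and conventions

Samples sit at the integer crossings of a 1-m grid over a square plot
(default 20 m), at most one ramet per crossing. Vegetation-cover quadrats
are unit squares named by their lower-left corner and must cover the plot
plus a one-quadrat ring (484 quadrats at 20 m), so every grid point has
four incident quadrats. The five ordinal cover categories (no shade, ≤30%,
≤60%, ≤90%, ≤100%) are mapped to their midpoint fractions
{0, 0.15, 0.45, 0.75, 0.95}; a sample's covariate x_j is the mean midpoint
of its four incident quadrats, centred and scaled to unit SD over the
sample set. The midpoint rule is the least-informative way to carry
quadrat-level ordinal cover onto points, and standardization keeps the
cover slope on a stable scale for the sampler; the choice is recorded in
run metadata so users can substitute their own covariate.

All files are UTF-8 TSV with a header and `NA` for missing. Band calls
propagate missingness through scoring; samples with any missing SSR locus
are excluded from genet assignment (logged), since exact multilocus
matching is undefined on partial genotypes.

## MSAP scoring

HpaII does not cut when the internal CG is methylated on both strands;
MspI does not cut when the external cytosine is hemimethylated. The paired
(HpaII, MspI) presence pattern therefore maps to conditions
I (1,1) = unmethylated, II (0,1) = CG-methylated,
III (1,0) = CHG-hemimethylated, IV (0,0) = fully methylated or site lost.
Mixed scoring expands each locus into three binary subepiloci (n, m, h),
one-hot over conditions I–III; condition IV scores 0 at all three rather
than missing, making it a genuine fourth state whose rate completes the
partition of non-missing calls. A fragment is retained as polymorphic when
at least two distinct non-missing conditions occur; no minor-frequency
floor is applied.

Scoring error is the percentage of mismatched calls among jointly
non-missing replicate pairs, reported per enzyme, per primer pair and
pooled. Stability statistics compare per-locus calls for equality on a
channel basis: the CG column compares the HpaII-channel call (whose loss
marks CG methylation), the CHG column the MspI-channel call. Positional
stability averages per-ramet fractions (top leaf included) across ramets
rather than pooling leaves, so ramets with different leaf counts weigh
equally; seasonal stability is the fraction of matched ramet pairs, with
the pair count taken from the data.

## Genet assignment and P_gen

Ramets sharing an identical multilocus genotype across all SSR loci form
one genet; genets are numbered 1..G by decreasing ramet count with ties
broken by first-encountered sample order (deterministic for a fixed file).
No somatic-mutation tolerance is applied. P_gen is the Hardy–Weinberg
probability of a multilocus genotype — p² per homozygous locus, 2pq per
heterozygous locus, multiplied over loci — with allele frequencies counted
at the ramet level by default (genet-level counting is available via a
flag). It screens the exact-match rule: when every observed genotype has
P_gen ≪ 10⁻³, independent sexual origin of a shared genotype is
implausible.

## Spatial autocorrelation

Markers are embedded numerically — SSR genotypes as per-allele counts
{0,1,2} per locus, epigenotypes as the concatenated binary subepilocus
scores — and pairwise squared Euclidean distances are Gower-centred,
c_xy = −½(d_xy − d̄_x· − d̄_·y + d̄··). Within a distance class,
r = Σ c_xy / Σ ½(c_xx + c_yy) over the class's pairs. Classes are
half-open 1-m bins by default; an equal-pair-count binning is available
behind a flag. Significance per class comes from jointly permuting sample
locations against marker rows (holding C fixed), with the two-sided
add-one estimator p = (1 + #{|r*| ≥ |r|})/(n_perm + 1); uncertainty in r
itself comes from resampling pairs within the class with replacement. Both
envelopes are reported and plotted, since either convention appears in
field studies. All samples identical (C ≡ 0) makes r undefined and is
flagged as NaN rather than reported as 0. The aggregation *extent* is the
upper edge of the initial run of classes with r above the permutation
envelope, skipping classes with no pairs (the [0,1) class of a 1-m lattice
is always empty).

## Hierarchical Bayesian model

For one subepilocus class, y_ijk ~ Bernoulli(q_ijk) with
logit(q_ijk) = g0 + g_i + g_ik + (e0 + e_i)x_j + s_j. Priors: N(0, 10³)
on g0 and e0; N(0, σ²) hierarchies on g_i, g_ik, e_i; Uniform(0, 100) on
all σ. The spatial prior is the intrinsic CAR in pairwise-difference form
over the 1-m rook adjacency — each s_j conditionally Gaussian around its
neighbour mean with variance σ_s²/deg(j) — and isolated samples receive a
proper N(0, σ_s²) term, the natural completion of a conditional mean over
an empty neighbour set. The three classes are fitted independently over
the same samples and genets. Zero-variance loci are retained (the
hierarchy regularizes them) but noted.

The ICAR prior is invariant to level shifts, which would confound s with
g0. Each sweep subtracts the *global* mean of {s_j} and adds it to g0 — an
exact reparameterisation that leaves every linear predictor unchanged.
Per-component centring with a single intercept was considered and
rejected: subtracting different constants per component while adjusting
one shared intercept changes the likelihood, so the chain would no longer
target the stated posterior. Residual shifts between components are
identified by the likelihood itself.

The sampler is blocked random-walk Metropolis-within-Gibbs. Scalars (g0,
e0, σs on the log scale with Jacobian) update singly; g_i, e_i and g_ik
update as vector blocks with element-wise accept/reject, valid because the
likelihood support of each element is disjoint given the rest; s updates
by graph-colour classes so no two simultaneously-updated nodes are
adjacent. Two extra "ridge swap" moves shift mass along
likelihood-invariant directions (g0 against all g_i; each g_i against its
g_ik row), whose acceptance involves priors only — these decorrelate the
hierarchy levels that the predictor identifies only as sums, and are what
makes the intercept chain mix at the default run lengths. Step sizes adapt
multiplicatively toward 0.44 acceptance during burn-in and are frozen
afterwards, preserving detailed balance for the retained draws. Defaults
follow common practice for this model class: 3 chains, burn-in 1000,
thinning 50, 1000 retained draws per chain. Convergence is the classic
Gelman–Rubin PSRF per monitored scalar (g0, e0, all σ, every g_i, and a
seeded subsample of 50 g_ik), with 1.1 as the failure threshold.

Global probability per locus is the posterior of inv-logit(g0 + g_i),
i.e. evaluated at the covariate mean (x̄ = 0 after standardization) and
zero spatial effect; genet-specific probability adds g_ik. The raw
empirical locus rate is reported alongside, since a field table's
"methylation rate" may refer to either. Intervals are equal-tailed 95%
percentile intervals from pooled chains (not HPD). A genet is flagged +1
when its interval's lower bound exceeds the global median, −1 when its
upper bound is below it. Singleton genets are estimated (they inform the
hierarchy) but suppressed from genet-level reports.

## Synthetic data

The generator emulates the study conditions of a stoloniferous clonal
herb on a 20 m plot sampled at every grid crossing:

- **Clonal landscape** — founders by a homogeneous Poisson process
  (0.42/m² including a 2-m margin), each spawning a random walk of clonal
  steps; step lengths are exponential with mean 0.5 m (stolons exceed
  30 cm), and step counts are lognormal-Poisson (median 3, log-SD 1.8),
  giving right-skewed genet sizes with singletons modal. One ramet per
  grid point is kept (nearest within 0.5 m). Across seeds this yields
  ~350 ramets (range ≈ 295–390) in ~127 genets with ~5 genets of ≥10
  ramets — the regime of the motivating field survey (335 ramets, 137
  genets, 6 large genets).
- **Cover** — a planar latent trend (default direction south-by-southeast,
  matching the reported densening) plus Gaussian noise, cut at equal
  quantiles into the five ordinal categories.
- **SSR** — 8 loci with 6–10 alleles and Dirichlet(2) frequency spectra;
  one HWE genotype per genet, redrawn on collision.
- **Methylation** — the three subepilocus classes get class-specific
  linear predictors (intercepts −0.27 / 1.40 / −3.19 chosen so the
  marginal n/m/h rates land near the survey's 13% / 69% / 0.7%;
  σ_g = 2.0, σ_gk = 1.5, σ_e = 0.3, σ_s = 0.5), renormalised
  softmax-style into a four-way categorical draw with condition IV as the
  residual mass — this is what keeps the three marginal Bernoulli fits
  well-defined while the emitted subepiloci stay mutually exclusive. ICAR
  fields are drawn exactly via the Laplacian eigenbasis and centred per
  component. Band calls are flipped independently at 3.9% (HpaII channel)
  and 7.4% (MspI channel), the survey's replicate error rates.

Two named scenarios fix conditions for benchmarking. `recovery_config`
(founder density 0.11/m², heavier clonal spread) lands at ~300 ramets in
~50 genets so genet-level effects are estimable; parameter-recovery checks
draw outcomes directly from the fitted model's own Bernoulli form on that
landscape. `structure_config` switches off the cover slope and spatial
field so epigenetic aggregation can only come from clonal patches plus
scoring noise, and places the h class in the regime field surveys report
for hemimethylation: rare (intercept −5) and essentially unstructured by
genet (σ_gk = 0.5) — consistent with the observed absence of deviating
genets for h.

What the generator does *not* emulate: somatic SSR mutation, scoring-error
correlation between fragments of one gel, demographic turnover, selection,
and any linkage between epigenetic states and genotype beyond the genet
effect. Passing tests therefore demonstrate correctness of the estimators
under the model's own assumptions, not robustness to these violations.

## Verification strategy and problem sizes

The sampler is checked against a dense-grid integration oracle on a tiny
model (2 loci × 20 samples × 3 genets, no covariate/spatial term): with
the intercept integrated out analytically, the posterior factorises over
loci given (g0, σ_g, σ_gk), leaving nested 1-D quadratures inside a 3-D
outer grid, and the sampler's posterior mean probabilities agree within 3
Monte-Carlo SE. Permutation p-values are checked against exhaustive
enumeration of all 720 placements of a 6-sample fixture; because that
fixture's permutation distribution carries large tie masses and float
round-off decides tie membership, the sampled p is compared against the
exact tie-exclusive/tie-inclusive interval widened by 3 SE.

Parameter recovery fits the m class on `recovery_config` geometry with a
shortened chain (burn-in 800, thinning 5, 3 × 400 draws — the full-length
defaults change the summaries negligibly on this size): 95% intervals
cover the true g_ik at the nominal rate within binomial tolerance
(measured ≈ 0.94–0.96 over ~1100 multi-ramet cells) and fewer than 10% of
cells with |g_ik| < 2 are flagged. Flag *sensitivity* for |g_ik| ≥ 2 is
~0.2–0.3 at this design and rises above 0.8 only for genets with ≥10
ramets: with ~6 ramets per genet the 95%-interval exclusion rule simply
lacks power against a Gaussian effect distribution, and any rule powerful
enough to reach 0.8 sensitivity there also flags a quarter of the genuine
intermediate effects in [1, 2). This power boundary is a property of the
design size and the flag rule, and is reported as measured.

Deterministic seeding throughout: every generator takes a master seed;
sub-seeds are derived by SHA-256 of labelled strings, and MCMC chains use
`SeedSequence.spawn`. Identical seeds give byte-identical outputs.

## Known limitations

- The sampler is single-threaded pure NumPy; a full default-length fit of
  24 loci × ~330 samples × ~130 genets takes a few minutes per class.
- The marginal Bernoulli fits ignore the one-hot coupling between the
  three subepilocus classes (as the analysis framework intends); their
  parameters are marginal effects, not the categorical generator's.
- P_gen uses HWE with ramet-level allele frequencies; no correction for
  inbreeding or population structure.
- The equal-pair-count binning uses quantile edges, which can merge bins
  when many pairwise distances tie on a lattice.
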