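# epiclone

Spatial epigenetic analysis of clonal plant populations.

Clonal herbs such as *Cardamine leucantha* spread by stolons, so a single
genet (one sexual recruit) can occupy many grid points of a mapped plot as
physiologically independent ramets. Methylation-sensitive AFLP (MS-AFLP /
MSAP) screens anonymous 5'-CCGG-3' sites with the isoschizomers HpaII and
MspI, whose different methylation sensitivities turn each site's paired
band pattern into a four-way methylation condition. `epiclone` implements
the full analysis chain for such surveys:

- **MSAP mixed scoring** — paired band matrices → conditions I–IV →
  three binary subepiloci per locus (n: unmethylated, m: CG-methylated,
  h: CHG-hemimethylated), plus replicate scoring-error rates and
  leaf-position / seasonal stability statistics.
- **Genet assignment** — exact multilocus SSR genotype matching, genets
  ranked by ramet count, with the Hardy–Weinberg identity probability
  P_gen = ∏ᵢ (pᵢ² or 2pᵢqᵢ) as the screen against merging distinct recruits.
- **Spatial autocorrelation** — the multivariate correlogram of Smouse &
  Peakall: squared marker distances, Gower centring, per-distance-class
  r with permutation envelopes and pair-bootstrap CIs.
- **Hierarchical Bayesian model** — for each subepilocus class,

  ```
  y_ijk ~ Bernoulli(q_ijk),
  logit(q_ijk) = g0 + g_i + g_ik + (e0 + e_i) x_j + s_j
  ```

  with locus deviations g_i, genet-by-locus deviations g_ik, a
  vegetation-cover slope (e0 + e_i) on the standardized covariate x_j, and
  intrinsic-CAR spatial effects s_j on the 1-m sampling lattice. Fitting is
  by blocked adaptive Metropolis-within-Gibbs; per-locus global and
  per-genet methylation probabilities are summarised as medians with 95%
  equal-tailed credible intervals, and a genet is flagged as deviating
  (+1/−1) when its interval excludes the global median.
- **Synthetic data** — a seeded generator producing complete,
  ground-truth-labelled datasets: Poisson founders with random-walk clonal
  spread on a 20 m × 20 m grid, an ordinal cover cline, HWE genotypes per
  genet, and methylation conditions drawn from class-specific linear
  predictors with CAR noise and enzyme-channel scoring error.

## Worked example

```
epiclone simulate --seed 7 --out run/
epiclone run --run-dir run/ --seed 7 --perm 999 --boot 999 \
    --chains 3 --burnin 500 --thin 5 --keep 300
epiclone report --run-dir run/
```

On this seed the generator places 372 ramets; exact SSR matching groups
them into 115 genets (largest: 34 ramets) with a worst-case
P_gen = 1.3 × 10⁻⁸, far below the usual 10⁻³ screening level — identical
genotypes can safely be treated as clones. The correlograms
(`correlogram_{ssr,subepiloci}.tsv`) show genetic aggregation out to 7 m
(first-class r = 0.20) but epigenetic aggregation only to 4 m
(first-class r = 0.04): epigenotypes track clonal patches, attenuated by
scoring noise and within-genet epigenetic variation.

`deviations.tsv` counts deviating genets per locus and class:

```
locus    n_low  n_high  m_low  m_high  h_low  h_high
Lo1-100      2       2      0       1      0       2
Lo1-111      0       0      1       2      0       0
Lo1-122      0       1      1       0      0       0
Lo1-133      0       4      5       0      0       0
```

and `fit_m/posterior_summary.tsv` gives per-locus global probabilities with
their credible intervals next to the raw empirical rates:

```
locus    median     lo     hi  empirical_rate
Lo1-100   0.088  0.057  0.126           0.124
Lo1-111   0.616  0.529  0.690           0.640
Lo1-122   0.848  0.789  0.891           0.820
```

`fit_*/convergence.tsv` holds the Gelman–Rubin statistic per monitored
parameter (max 1.03 for the m-class fit above). The shortened MCMC
settings shown keep the example fast; at the default settings
(burn-in 1000, thinning 50, 3 × 1000 retained draws) all monitored
parameters converge below the 1.1 threshold.

Every command is also available as a library call (`epiclone.simulate`,
`epiclone.msap`, `epiclone.genets`, `epiclone.spatial`, `epiclone.hb`,
`epiclone.report`).

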