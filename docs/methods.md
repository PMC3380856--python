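# Methods

This note records the statistical models implemented in `genecult`, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical and design decisions a maintainer should
know about. Every number quoted here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not verify.

## Data model and frequencies

The unit of observation is a population with genotype counts
(n_rr, n_ra, n_aa) for one biallelic SNP. Frequencies are obtained by
direct counting, p_alt = (n_ra + 2 n_aa) / 2n, kept at full precision
internally and rounded half-up to two decimals only for display. The
packaged table (50 Native American populations, 1905 individuals, grouped
as Mesoamerican agriculturalists, Andean agriculturalists and South
American hunter-gatherers/foragers) stores counts verbatim together with
the originally printed two-decimal frequencies. Three rows are internally
inconsistent in the original: Zapotec (58/250 = 0.232 prints as 0.24),
Guaymí (10/70 = 0.143 prints as 0.15) and Hulliche (3/26 = 0.115 prints as
0.11). Counts are treated as authoritative everywhere; the printed values
are retained for documentation and test purposes only. Missing VCF
genotypes reduce n rather than being imputed, matching the direct-counting
convention. Coordinates are metadata and never enter a statistic.

## Hierarchical AMOVA

Each diploid individual contributes its two alleles as exchangeable 0/1
observations (a within-individual level is deliberately not modelled: with
a single unphased SNP it adds nothing to the among-population questions the
package answers). Sums of squares are partitioned among groups / among
populations within groups / within populations, variance components are
recovered with the classical unequal-sample-size expected-mean-square
coefficients, and the fixation indices are

F_CT = σ²_a / σ²_tot, F_SC = σ²_b / (σ²_b + σ²_c), F_ST = (σ²_a + σ²_b) / σ²_tot.

Negative components are stored as estimated and clamped to zero only in
percentage-of-variance displays. Permutation schemes: whole populations
among groups (F_CT), individuals (genotype pairs kept intact) among
populations within groups (F_SC) or among all populations (F_ST);
p = (1 + #{perm ≥ obs}) / (B + 1) with B = 10,000 by default, so "p = 0.000"
is reported as p < 1/(B+1). The implementation is verified to machine
tolerance against a brute-force oracle that enumerates every allele
explicitly.

On the packaged table this yields F_CT = 0.039, within-Mesoamerica
F_ST = 0.017, within-hunter-gatherer F_ST = 0.072 and within-Andes
F_ST = 0.031 (non-significant). The originally printed set (3.6%, 1.8% or
0.013, 5.3%, 0%) is not jointly reproducible from the printed genotype
counts under this or any of roughly a dozen alternative conventions we
evaluated (genotypic four-level AMOVA, Weir–Cockerham θ, individuals
treated as haploid observations, printed-frequency inputs, Nei-style group
heterozygosity ratios, sample-size and monomorphic-population exclusions).
The allele-level convention implemented here is the standard one and is the
only one that reproduces the printed within-Mesoamerica footnote value
(1.8%); the residual differences presumably reflect the original software
input convention or an analysis dataset that differed slightly from the
printed table. `scripts/acceptance.py` reports the as-computed values.

Pairwise and within-group F_ST use the same one-level allele-count ANOVA
(the two-population case is the classical θ-style estimator); multi-locus
values are ratios of summed components, and negative estimates are reported
raw.

## Allele ages

**Frequency method.** E(t₁) = [−2p/(1−p)] ln p, time in units of 2N
generations. The conversion to years exposes N (default 720, a diploid
effective size for the peopling-of-the-Americas window) and generation time
(25 y) as ordinary parameters. At the Mesoamerican mean frequency 0.154
this gives 0.681 × 2N generations ≈ 24.5 kyr. The ages printed in the
original study (12,097 and 19,409 YBP) cannot be recovered from this
formula with its stated inputs under any standard unit convention, so the
package documents its convention explicitly and the tests pin only the
closed forms (E = 2 ln 2 at p = ½; limit 2 as p → 1; strict monotonicity).
Under directional selection the frequency method overestimates age — the
expected and observed direction when compared with the LD estimates.

**LD decay, moment estimator.** For one flanking marker with recombination
fraction c, the proportion y of carrier chromosomes retaining the ancestral
marker allele, corrected for recurrent background recovery q
(y′ = (y−q)/(1−q)), follows y′ = e^(−ct) in expectation, inverted as
t̂ = −ln y′ / c. y′ ≥ 1 clamps to 0; y′ ≤ 0 is reported as undefined. The
estimator is invariant to marker relabeling and chromosome duplication.

**LD decay, MCMC.** The intra-allelic genealogy is approximated by two
layers: a *stem* (the interval from the founding mutation to the carriers'
most recent common ancestor — a real and often substantial distinction,
since the sample MRCA postdates the mutation) occupying a fraction φ of the
age t, and a star-like genealogy of depth (1−φ)t below the MRCA. Marker by
marker, recombination on the stem (probability 1 − e^(−cφt)) sends the whole
carrier class to background; otherwise each carrier retains the ancestral
allele with probability e^(−c(1−φ)t) + (1 − e^(−c(1−φ)t)) q. This mixture is
a composite likelihood (carriers are treated as independent given the
layer structure; residual within-clade correlation is ignored). The prior
on t is lognormal with median ln(K)/r — the time a single copy needs to
reach K = carriers/sampled-fraction copies under deterministic growth at
the population rate r — and log-sd 1.5, kept weakly informative because a
selected allele grows faster than its host population; the prior on φ is
flat. A Metropolis–Hastings random walk on (log t, logit φ) adapts its
scales during burn-in toward 20–50% acceptance; default 100,000 iterations
with 20% burn-in (2,000,000 remains a config option), chains reproducible
by seed. Point estimate: posterior mean, with the central 95% interval and
the mode. With no informative marker the likelihood is flat and the
posterior reproduces the prior (verified by KS distance < 0.1). Calibration
under the panel generator: the 95% interval covers a true age of 300
generations in ≥ 90/100 panels, and the median absolute relative error of
the posterior mean is ≈ 19% for true ages between 100 and 1,000
generations. Simpler likelihoods that ignore the stem (plain binomial, or
beta-binomial overdispersion, even with a composite-likelihood sandwich
adjustment) under-cover badly (47–85%); the stem term is what makes the
intervals honest.

## Coalescent simulators

Both simulators are continuous-time structured coalescents with exact
exponential waiting times, written for this package (sizes in diploids,
times in generations).

**Island model.** ``n_demes`` demes (default 100) of constant size; each
lineage migrates backwards at total rate m_within to demes of its own group
and m_between to other groups (uniform within class); coalescence at rate
k(k−1)/2 per deme per 2N generations. A ``target_fst`` parameterization
inverts F_ST = 1/(1 + 4Nm D²/(D−1)²) for the non-hierarchical rate, since
the original study left its migration rates unstated. One mutation is
placed uniformly on total branch length (infinite sites), which makes every
locus polymorphic in the pooled sample by construction. Verified: mean
pairwise coalescence time 2N in a single deme; multi-locus F_ST within
±0.05 of 1/(1+4Nm) at 4Nm = 1 over 5,000 loci; mutation placement
chi-square-consistent with branch-length proportions on a hand-built tree.

**Settlement demography.** Three demes of 830 diploids (sampled at the
study's panel sizes 68/35/23 by default) merge into a single ancestral
population at a split time drawn uniformly from 6,350–18,000 years BP, the
ancestral size drawn uniformly from 70–830; each deme shrinks
exponentially backwards from 830 to the ancestral size at the split
(deterministic trajectory), constant size before it. Post-split migration
defaults to 0 and is configurable. A region carries 20 fully linked SNPs
(one genealogy, 20 uniform mutations); an unlinked mode draws independent
genealogies. Verified: F_ST ≈ 0 in the panmixia limit and non-decreasing
in split time over 1,000–40,000 years.

**Summaries.** Per-locus unbiased heterozygosity 2p(1−p)·2n/(2n−1)
averaged within demes, then across demes and loci; global and pairwise
F_ST as across-loci ratios of summed ANOVA components (monomorphic loci
contribute zero to both numerator and denominator). The summary vector
layout is fixed: (mean_he, global_fst, pairwise F_ST for deme pairs i<j in
deme order).

## F_ST-outlier test

The null is a cloud of (He, F_ST) points from the island simulator (50,000
draws by default; calibration tests use 1,500+). A locus's p-value
conditions on heterozygosity: null points are weighted by a Gaussian kernel
on |He_i − He_obs| (Silverman bandwidth unless given) and p is the weighted
proportion of null F_ST ≥ observed, with add-one smoothing
(p = (Σw·I + 1)/(Σw + 1)) so the floor is 1/(effective n + 1). A joint
two-tailed option exists; flags default to α = 0.05 with no
multiple-testing correction (a Benjamini–Hochberg helper is deliberately
not wired in by default, mirroring the original single-locus usage).
Because single-SNP F_ST is discrete, exactly tied null points count half
(mid-p) in reports, and a classical randomized tie-break is provided for
calibration assessment — with it, 500 null-locus p-values pass a KS
uniformity test at α = 0.01, and the mid-p flag rate at α = 0.05 is ≈ 5%.
Power: a locus driven by s = 0.05 for 200 generations in one deme (drift
generator below) is flagged in ≥ 80% of 50 replicates against a
target-F_ST-matched null. Conditional quantile envelopes (2.5/50/97.5%) of
null F_ST over a He grid provide the plot analogue; the 95% band contains
the median line by construction of weighted quantiles.

## Neutrality goodness-of-fit

Observed and simulated locus sets are summarised to vectors S\* and S and
compared by ∂ = ‖S − S\*‖. Because the coordinates mix scales (He vs
F_ST), the default standardises each coordinate by its standard deviation
in the neutral ensemble (raw mode retained; whether the original distances
were standardised is unknown). The report carries the mean/median/min
distance of the observed vector to the ensemble and the ensemble's internal
baseline (each simulation vs the ensemble mean), so "fits worse than a
reference dataset" is a paired comparison of mean distances. Verified: a
settlement-simulated set is indistinguishable from the baseline, and a
sweep-distorted set (below) is farther than its neutral original in
≥ 80% of 50 pairs. The original study's absolute distances (70.64 / 35.12 /
45.80) depend on unavailable genotype data and are not reproduction
targets; the qualitative two-dataset contrast is.

## Gene–culture correlation

Mid-rank (tie-corrected) Spearman correlation with the two-tailed t
approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df. Mid-ranks are mandatory: on
the packaged seven-row pollen table (frequencies 0.24…0.10 vs calendar ages
9212…3096 BP, with one tie at 0.15) they reproduce ρ = 0.936975 and
p = 0.0019 exactly as printed, whereas the no-tie shortcut
1 − 6Σd²/(n(n²−1)) gives 0.9375. Radiocarbon→calendar calibration is not
implemented; the table's calendar column is used as published. Subdivision
contrasts use Student's t on per-population frequencies (unweighted), Welch
by default with a pooled option; the originally printed t-test p-values are
not recovered from the printed frequencies under either variant (the
original procedure is unstated), so only the direction and significance of
the Mesoamerica–Andes contrast is asserted.

## Synthetic-data generators

**Drift tables.** Forward Wright–Fisher per population: deterministic
mixing toward the metapopulation mean frequency at rate m, additive
viability selection (fitnesses 1, 1+s/2, 1+s) in one designated group,
binomial drift at 2N, final genotype counts multinomial under
Hardy–Weinberg. Defaults mirror the study layout (16/7/27 populations,
demes of 830, 400 generations ≈ 10 kyr, m = 0.01, samples of 40). Under
neutrality the default scenario centres AMOVA F_CT on zero (median < 0.01
over seeds); with s = 0.05 the selected group's mean frequency exceeds the
others' in ≥ 95% of seeds and F_CT is stochastically larger
(Mann–Whitney p < 0.01).

**Sweep overlay.** For the neutrality-fit contrast, selection is applied
*on top of* a neutral settlement region: each locus's frequency in one deme
is evolved forward 160 generations (≈ 4 kyr) at s = 0.05 with drift, then
the deme's sample counts are redrawn. This keeps neutral and selected sets
paired and keeps the neutral sets exchangeable with the ensemble —
a drift-table "observed" set would differ from the coalescent ensemble in
its site-frequency spectrum regardless of selection, which is the wrong
contrast.

**Age panels.** The carriers' genealogy is a coalescent inside an
exponentially growing allele class whose present size is
carriers/sampled-fraction (default 0.0002, so the class collapses to one
copy at the true age; lineages not yet coalesced at the origin join the
founder there). Recombination is laid on every branch *including the stem
above the sample MRCA* (omitting the stem inflates retention and biases
every downstream estimator young by ~20%); a recombined lineage's
descendants draw marker alleles from the background frequencies,
approximating continued background mixing. Non-carriers are independent
background draws. Defaults: 19 markers with recombination fractions
log-spaced 2×10⁻⁴–10⁻², background frequencies 0.2–0.8, 40 carrier and 160
non-carrier chromosomes, growth 0.005/generation. What the generator does
not emulate: marker–marker LD within the background, recurrent mutation,
genotyping error, and unphased data — so passing tests demonstrate
estimator correctness under the model, not robustness to real-data phasing
or ascertainment artefacts.

## Numerical and interface choices

- All stochastic code takes an integer seed (or an RNG object); identical
  seeds give identical results. The pipeline derives per-stage seeds from
  one global seed and logs them.
- Problem sizes in the test suite (e.g. 1,500–2,000-point null clouds, 300
  settlement ensembles, 100 MCMC panels at 20,000 iterations, 5,000
  island loci) were chosen so the whole suite runs in a couple of minutes
  on one core while leaving the Monte-Carlo checks well-powered; module
  defaults remain at the study-scale values (50,000 null simulations,
  100,000 settlement genealogies are config options).
- Degenerate inputs are first-class: monomorphic loci are flagged (AMOVA)
  or excluded with a reason (outlier scan); identical constant groups give
  t = 0, p = 1; an observed He outside the null support triggers a warning
  and a nearest-neighbourhood fallback.
- The CLI (`genecult`) is a thin wrapper; every number it prints is
  produced by exactly one library operation, and the pipeline report maps
  each section to that operation.

## Known limitations

- The AMOVA printed-value discrepancies described above: F_CT and the
  within-hunter-gatherer F_ST computed from the printed counts differ from
  the originally printed 0.036 / 0.053 by 0.003 / 0.019 under the standard
  convention.
- The composite-likelihood MCMC ignores within-clade correlation below the
  MRCA; its intervals are calibrated under the package's own generator but
  could under-cover for strongly non-star genealogies (weak growth).
- The island-model null is built at fixed sample sizes; per-locus
  re-conditioning on observed sample sizes is not performed.
- Single-SNP statistics are discrete; deterministic p-values therefore
  carry atoms, and exact uniformity holds only for the randomized
  tie-break variant.
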