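# genecult

Population-genetic toolkit for testing gene–culture coevolution hypotheses
with single-SNP genotype-count data, built around the case of the *ABCA1*
Arg230Cys variant (rs9282541) in Native American populations: a derived
allele private to the Americas whose frequency rise in Mesoamerica has been
attributed to selection driven by the maize-farming niche.

It is aimed at population geneticists and human-evolution researchers who
have per-population genotype counts for a candidate SNP (plus, optionally,
flanking-marker haplotypes and multi-locus frequency matrices) and want to
run the full inference chain:

1. **Hierarchical F-statistics** (`genecult.fstats`) — allele-level AMOVA
   partitioning variance among groups of populations (F_CT), among
   populations within groups (F_SC) and within populations (F_ST), with
   permutation p-values; within-group and pairwise F_ST.
2. **Allele ages** (`genecult.allele_age`) — the frequency estimator
   E(t₁) = [−2p/(1−p)] ln p (in units of 2N generations), a moment
   estimator inverting the intra-allelic LD decay y′ = e^(−ct), and a
   composite-likelihood MCMC sampler over (age, stem fraction) with a
   growth-induced prior.
3. **F_ST-outlier test** (`genecult.coalescent`, `genecult.outlier`) — a
   bespoke structured-coalescent simulator for a (hierarchical) island
   model builds a null cloud of (He, F_ST) pairs; loci get
   heterozygosity-conditional kernel-weighted p-values.
4. **Neutrality goodness-of-fit** (`genecult.neutral_fit`) — Euclidean
   distances ∂ = ‖S − S\*‖ between observed summary vectors and an ensemble
   simulated under a three-deme settlement demography for the peopling of
   the Americas.
5. **Gene–culture correlation** (`genecult.geneculture`) — tie-corrected
   Spearman rank correlation of allele frequencies against calibrated
   archaeological *Zea* (maize) pollen dates, plus subdivision-level
   t-tests.
6. **Synthetic data** (`genecult.synthetic_data`) — forward Wright–Fisher
   drift/selection tables, intra-allelic haplotype panels of known age, and
   the packaged study tables (50 populations, n = 1905; 7 pollen-dated
   sites).

## Worked example

```python
from genecult import amova, frequency_vs_age_report, kimura_ohta_age
from genecult.popdata import subdivision_mean_frequency
from genecult.synthetic_data import fixtures

fx = fixtures()

res = amova(fx.table1, n_permutations=10_000, seed=1)
print(f"F_CT = {res.fct:.3f} (p = {res.p_fct:.4f})")

p_meso = subdivision_mean_frequency(fx.table1, "mesoamerican_agriculturalist")
age = kimura_ohta_age(p_meso)
print(f"meso mean freq = {100 * p_meso:.1f}%  ->  {age.age_years:,.0f} years")

corr = frequency_vs_age_report(fx.table1, fx.table2).correlation
print(f"Spearman rho = {corr.rho:.6f} (p = {corr.p_value:.4f}, n = {corr.n})")
```

prints

```
F_CT = 0.039 (p = 0.0003)
meso mean freq = 15.4%  ->  24,476 years
Spearman rho = 0.936975 (p = 0.0019, n = 7)
```

Reading: about 3.9% of allelic variance separates the three subsistence
subdivisions (highly significant by permutation of populations among
groups); the Mesoamerican mean 230Cys frequency of 15.4% implies, under the
neutral frequency–age relation with N = 720 and 25-year generations, an age
around 24.5 kyr (frequency ages overestimate selected alleles — see
`docs/methods.md`); and the derived-allele frequency of seven
Meso/Central-American populations tracks the age of the nearest
archaeological maize-pollen deposit almost perfectly (rho 0.94).

The same chain runs from the shell:

```bash
genecult amova --permutations 10000 --seed 1
genecult correlate
genecult run --config config.yaml
```

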