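# otuwas

**OTU-wide association of gut-microbiome profiles with a continuous phenotype.**

`otuwas` is a reusable pipeline for studies that ask how much a host trait —
the motivating case is weaning weight in meat rabbits, measured in grams —
is shaped by the gut microbial community profiled with 16S rRNA sequencing.
It takes an OTU count table, a sample sheet (sex, cage, weight), and
optionally predicted functional profiles, and runs:

1. **Preprocessing** — rarefaction to a fixed library size (default 40 000
   tags/sample), conversion to relative abundances, removal of OTUs with
   mean relative abundance < 0.05% or prevalence < 5%, and residualization
   of the phenotype on sex and cage (OLS fixed effects).
2. **Two-part association.** Microbiome abundances are zero-inflated and
   non-normal, so each OTU is tested twice against the adjusted phenotype
   *y*: a **binary** model (OLS of *y* on the presence indicator, equivalent
   to a pooled-variance t-test) giving β₁, and a **quantitative** model (OLS
   of *y* on the standardized log relative abundance among the samples where
   the OTU is detected) giving β₂. The signed z-scores are combined by the
   unweighted-Z method, z_meta = (z₁ + z₂)/√2, and the per-OTU p-value is
   the minimum of the defined component p-values. Because min-P is
   anticonservative, q-values come from a permutation FDR: the adjusted
   phenotype is permuted across samples (default 1000×), the whole scan is
   re-run, and FDR(t) = E[#null p ≤ t] / #{observed p ≤ t} with step-up
   monotonization.
3. **Co-abundance structure.** SparCC correlations among the significant
   OTUs (log-ratio variances → basis variances → correlations, median over
   Dirichlet-resampled repetitions), bootstrap pseudo-p-values, a network of
   edges with p < 0.05 and |r| > 0.4, Ward clustering of d = (1 − r)/2 into
   co-abundance groups (CAGs) validated by PERMANOVA (999 permutations), and
   Spearman association of CAG abundances with the phenotype.
4. **Functional features.** Spearman + Benjamini–Hochberg screening of any
   samples × features table (e.g. predicted KO or pathway profiles) with the
   significance rule q < 0.05 and |ρ| > 0.3.
5. **Variance explained.** Repeated 80/20 cross-validation: the two-part
   scan runs on the discovery set, OTUs passing a p-value threshold enter an
   additive predictor r_m = Σⱼ (β₁ⱼ·bⱼ + β₂ⱼ·qⱼ) evaluated on held-out
   samples, and the explained variance at each threshold is the mean squared
   Pearson correlation between r_m and the adjusted phenotype.

A synthetic-data generator (`otuwas.simulate`) produces rarefied,
compositional, zero-inflated cohorts with planted effects and full ground
truth, so every stage is testable without sequencing data.

## Worked example

```python
import numpy as np
from otuwas import (SimulationConfig, block_correlation, simulate, to_relative,
                    adjust_phenotype, two_part_scan, permutation_fdr,
                    results_to_frame, explained_variance)

rng = np.random.default_rng(0)
m = 50
zi = rng.uniform(0.3, 1.0, m); zi[:10] = 1.0
lm = rng.normal(0, 1.5, m); lm[:10] = 0.5
cfg = SimulationConfig(
    n_samples=200, n_otus=m, library_depth=40_000, n_cages=10,
    cage_sd=0.0, sex_effect=0.0, noise_sd=np.sqrt(70.0), seed=1,
    zero_inflation=zi, log_mean=lm,
    basis_correlation=block_correlation(m, [(0, 10, 0.6)]),
    effects=[(j, 0.0, 0.70) for j in range(10)],  # ~30% of variance
)
table, pheno, truth = simulate(cfg)
rel, adj = to_relative(table), adjust_phenotype(pheno)
scan = two_part_scan(rel, adj)
permutation_fdr(scan, rel, adj, n_perm=200, seed=2)
df = results_to_frame(scan)
print("q < 0.05 discoveries:", (df.q_value < 0.05).sum(),
      "of which planted:", (df.q_value[:10] < 0.05).sum())
curve = explained_variance(rel, adj, n_repeats=20, seed=3)
print(curve.to_frame().to_string(index=False))
```

prints

```
q < 0.05 discoveries: 10 of which planted: 10
 threshold  mean_r2    sd_r2  mean_n_otus
   0.00001 0.334210 0.102751         9.95
   0.00010 0.334746 0.103383        10.00
   0.00100 0.334360 0.102922        10.05
   0.01000 0.328384 0.105957        10.75
   0.05000 0.314974 0.103604        14.90
   0.10000 0.309720 0.100182        20.10
```

All ten OTUs planted with quantitative effects are recovered at q < 0.05
with no false positives, and the cross-validated microbiome-explained
variance (~31-33%) matches the planted ~30% contribution. The full pipeline — including the SparCC/CAG network and
feature screens — runs from a YAML config via

```bash
otuwas run-all --config run.yaml
```

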