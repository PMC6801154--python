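# Methods

## The statistical problem

A cohort of weaned animals (the motivating design: 135 rabbits, 70 male and
65 female, housed one or two per cage across 90 cages) is profiled by 16S
rRNA sequencing, yielding per-sample OTU tag counts, and weighed at weaning.
The goals are (i) to find OTUs whose presence or abundance associates with
the weight, (ii) to describe the co-abundance structure of the associated
OTUs, (iii) to screen predicted functional profiles, and (iv) to estimate
how much of the phenotypic variance the microbiome explains out of sample.

## Preprocessing

Counts are rarefied to a common depth (default 40 000 tags) by multivariate
hypergeometric subsampling — drawing without replacement from each sample's
tags, so a sample already at the target depth is returned unchanged and the
subsampled row sums are exact. Samples below the depth are dropped with a
warning. After conversion to proportions, OTUs are removed when their **mean**
relative abundance across analyzed samples is below 0.05% or their prevalence
(fraction of samples with any reads) is below 5%. Both thresholds are
inclusive on the keep side; the abundance statistic is configurable to `max`.
Surviving abundances are deliberately **not** renormalized, so "relative
abundance of OTU j" keeps its original meaning. An OTU failing both rules is
counted once, under the abundance rule, in the filter report.

The phenotype is residualized on sex (one indicator) and cage (categorical
fixed effects, one reference level) by OLS before any association test.
Fixed rather than random cage effects keep the residuals exactly orthogonal
to the design; the residuals are invariant to the reference level chosen,
and rank-deficient designs are absorbed by the pseudoinverse fit. Note that
with many small cages (90 cages for 135 animals) this residualization is
aggressive: a cage sampled once contributes a zero residual, so any
microbiome signal confounded with cage is removed along with the cage
effect. That is a property of the design being emulated, not of the
implementation.

## The two-part association model

Relative abundances are zero-inflated and non-normal, so each OTU is tested
with two complementary components against the adjusted phenotype y:

* **Binary**: OLS of y on the presence indicator (abundance > 0). The slope
  β₁ is the mean difference between carriers and non-carriers, identical to
  a pooled-variance two-sample t-test (asserted against a hand-rolled oracle
  at 1e-10). Skipped when either group has fewer than `min_group = 5`
  samples.
* **Quantitative**: OLS of y on the natural-log relative abundance,
  standardized to mean 0 / sd 1 **among the detected samples only**; β₂ is
  in phenotype units per SD of log abundance. Skipped when fewer than
  `min_present = 10` samples are detected or the abundance is constant. A
  rank-based inverse-normal transform is available as an alternative.

Component p-values are converted to signed z-scores, z = sign(β)·Φ⁻¹(1−p/2),
combined by the unweighted-Z meta-analysis z_meta = (z₁+z₂)/√2, and the
final p-value is the minimum over the defined components {p_binary, p_quant,
p_meta}. `min_group`/`min_present` are practical guards, not part of the
published procedure, and are configurable. P-values are floored at 1e-300. A
zero standard error with a nonzero effect (perfect separation) is reported
at the floor rather than dropped; only a genuinely undefined 0/0 statistic
marks a component undefined.

**Permutation FDR.** Min-P is anticonservative (its null rejection rate at
0.05 exceeds 0.05, verified by simulation), so significance uses q-values
from phenotype permutations: the adjusted phenotype vector is permuted
across samples (preserving the inter-OTU correlation structure), the entire
scan is recomputed per permutation (default 1000), and for each observed
threshold t, FDR(t) = mean null #{p_final ≤ t} / max(1, observed #{p_final ≤
t}), monotonized step-up (q(t) = min over t' ≥ t) and capped at 1. The scan
internals are vectorized so all permutations reduce to a few matrix
products; 1000 permutations on a 135 × 800 table take about a second.

## SparCC, co-abundance groups, PERMANOVA

Correlations among the q-significant OTUs are estimated on the count scale
with SparCC: per repetition, counts plus a pseudocount of 1 are perturbed to
fractions by a per-sample Dirichlet draw; the log-ratio variance matrix
t_ij = Var(log x_i/x_j) is reduced to basis variances ω by solving the
sparse-system approximation t_i· ≈ deg_i·ω_i + Σ_j ω_j; correlations are
r_ij = (ω_i + ω_j − t_ij) / 2√(ω_iω_j), clipped to [−1, 1]. The single most
correlated pair above the exclusion threshold (default 0.1) is removed from
the basis sums and the system re-solved, up to `n_exclude_iter` times
(default 20; recovery fixtures use more because each planted block
contributes 28 correlated pairs). The final estimate is the elementwise
median over `n_inner = 20` repetitions. Non-positive basis variances are
clipped with a warning. Two-sided pseudo-p-values come from a bootstrap that
shuffles each OTU's counts independently across samples (destroying
correlation, preserving marginals): p = (1 + #{|r_boot| ≥ |r_obs|}) /
(1 + n_boot), so the smallest attainable value with 100 bootstraps is 1/101.

Edges are retained at p < 0.05 and |r| > 0.4 (strict). OTUs are clustered on
d = (1 − r)/2 with Ward linkage and cut into k = 2 co-abundance groups by
default (k is a parameter); CAG labels are renumbered so CAG 1 contains the
lexicographically smallest OTU id. The partition is validated by PERMANOVA
on the same distances: pseudo-F = (SS_between/(k−1)) / (SS_within/(n−k))
with squared-distance sums, p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) over
label permutations (default 999). Because a two-group label swap reproduces
the same partition, ties with F_obs can lift p slightly above the 1/(n+1)
minimum. Per-sample CAG abundance is the sum of member relative abundances
(the mean is a monotone rescaling, so Spearman results are identical), and
CAG–phenotype association uses Spearman with Benjamini–Hochberg correction.

## Functional-feature screens

Predicted KO/pathway tables are consumed as-is (the prediction step depends
on external reference artifacts and is out of scope). Each feature is
rank-correlated (average ranks for ties) with the adjusted phenotype;
p-values use the t approximation, multiplicity is handled by
Benjamini–Hochberg (the published analysis says only "FDR correction" for
these screens, so the analytic BH rather than permutation estimator is an
interpretation), and the significant set is q < 0.05 with |ρ| > 0.3.

## Variance explained by the microbiome

Per repeat (default 100), samples are split 80/20 into discovery and
validation (`round(0.8 n)` discovery). The two-part scan runs on discovery
only; OTUs with nominal p_final ≤ threshold (grid 1e-5 … 0.1, matching the
published range, selection deliberately pre-FDR) enter the additive
predictor

    r_m = Σ_j (β₁ⱼ·bⱼ + β₂ⱼ·qⱼ)

where bⱼ is the presence indicator in the validation sample and qⱼ the log
abundance standardized with the **discovery** moments (0 when absent);
undefined components contribute 0. The published rendering of this formula,
Σ(β₁+bⱼ+β₂qⱼ), adds a per-OTU constant that cannot contribute to a
correlation and is read as a typographic corruption of the product form; the
literal variant remains available behind `formula="literal"` for audit (its
predictions differ by Σβ₁ + Σ(1−β₁)bⱼ, which is not an affine function of
the product form, so its R² is generally different). The explained variance
at a threshold is the squared Pearson correlation between r_m and the
adjusted phenotype over validation samples (0 when r_m is constant),
averaged over repeats. Selection, effect sizes and transform moments use
discovery data only; a leakage test asserts that shuffling validation
phenotypes never changes r_m.

## Synthetic cohorts and what they do (not) show

`simulate` draws per-sample log basis abundances from a multivariate normal
with a configurable correlation (block helper provided), applies per-OTU
Bernoulli presence masks (structural zeros, so binary effects have
well-defined ground truth), renormalizes to fractions, and draws counts
multinomially at the library depth — every simulated library is already
rarefied, with exact row sums. The phenotype is grand mean + sex effect +
cage random intercept + planted effects + Gaussian noise; planted
quantitative effects act on the standardized log **fraction** (the realized
composition, the scale every downstream analysis observes — defining them on
the latent basis scale would make the planted β₂ unrecoverable in principle,
because the estimator can never see the basis). Defaults mimic the
motivating design: 135 samples, 90 cages of 1–2 animals, 800 OTUs, depth
40 000, grand mean 500 g, sex effect 20 g, cage sd 30 g, residual sd 50 g
(typical values for rabbit weaning weight at ~28 days), per-OTU log-mean
spread 1.5, log sd 1.0, presence probabilities Uniform(0.2, 1).

Two compositional facts discovered while validating the generator are worth
recording. First, every OTU's log fraction shares the −log(total) term, so
a panel of **same-signed** planted effects makes all "null" OTUs weakly but
genuinely associated with the phenotype through that common mode; recovery
fixtures therefore plant mixed-sign effects (as real associated panels
have). Second, at exactly zero residual noise every OTU's compositional
spillover correlation becomes infinitely significant and the whole panel
enters the additive predictor; "noise-free" recovery fixtures therefore keep
a ~2% residual. Simulated cohorts share none of the taxonomic structure,
sequencing error, or cage–microbiome confounding of real data, so passing
recovery tests demonstrates correctness of the estimators under the model's
own assumptions, not field performance.

Feature tables with target Spearman correlations are generated through a
Gaussian copula on phenotype ranks, with the latent Pearson correlation
2·sin(πρ/6) chosen to hit the requested Spearman ρ.

## Fixture sizing for the recovery checks

The power panel (tests and acceptance script) plants 5 binary effects
(|shift| 1.5× residual SD, detected in a quarter of animals) and 5
quantitative effects (|slope| 0.4× residual SD per SD of log abundance,
ubiquitous) among 490 nulls. Ten simultaneous effects of these sizes inflate
phenotypic variance to ~4× the residual noise, so the cohort is sized at
n = 700 for t ≈ 5 on the weakest (quantitative) effects; with that design
power is ≥ 9/10 and the realized false-discovery proportion at q < 0.05 is
~0.06 across seeds. The variance-explained fixture plants ten co-abundant
ubiquitous OTUs (basis block correlation 0.6, β₂ = 0.70 per OTU with
residual sd √70 g) contributing ~30% of variance at n = 200 — co-abundance
both mirrors the CAG structure of real associated panels and is what makes
10 small effects individually detectable. The SparCC fixture uses two 8-OTU
blocks (basis r = 0.8) among 24 independent OTUs at n = 200, keeping the
correlated-pair fraction near 7% as the algorithm's sparsity assumption
requires, with 60 exclusion iterations (> 2×28 within-block pairs).

## Pipeline reproducibility

`run_all` wires the stages behind a `RunConfig` (YAML-serializable; every
threshold recorded next to the outputs). All randomness flows from one
master seed through per-stage substreams derived as
(seed + CRC32(stage name)) mod 2³¹−1, so reruns are byte-identical and
adding a stage never perturbs earlier streams. The network stage is skipped
(and noted in the manifest) when fewer than 4 OTUs are significant, since
the SparCC basis system is underdetermined below that.

## Known limitations

* The binary component models the phenotype as the response ("binomial
  analysis" in the source methodology); a logistic alternative is not built.
* Permutation FDR assumes exchangeability of the adjusted phenotype across
  samples; strong residual cage structure would violate it.
* SparCC estimates degrade when a large fraction of pairs is truly
  correlated (sparsity assumption) or when OTU panels are small (< ~20).
* The variance-explained estimator uses marginal per-OTU effect sizes; with
  strongly correlated OTUs r_m overweights the common signal, which is
  harmless for the correlation-based R² but makes r_m itself uninterpretable
  as a calibrated prediction in grams.
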