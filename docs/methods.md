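# Methods

## The design being modelled

Two heterotic groups (Dent, Flint) each contribute four founder inbred
lines. Within a group, all six pairwise crosses of the founders yield six
biparental populations of inbred progeny: doubled haploids (DH) on the Dent
side, lines obtained by repeated selfing (SSD, default 5 generations) on the
Flint side. Lines of the two groups are crossed in an incomplete factorial —
most lines parent a single hybrid, a minority two, a rare few three or four —
such that every one of the 36 Dent-population × Flint-population
combinations is represented. Hybrids are phenotyped in several environments;
QTL detection runs on their least-squares means.

## The generating model of the simulator

A hybrid's genetic value is

```
g = μ + α(dent pop) + β(flint pop) + (αβ)(pop pair)
  + Σ_q [ γ_q(Dent founder transmitted) + θ_q(Flint founder transmitted) + sca_q(pair) ]
  + u_D(dent parent) + u_F(flint parent)
```

with u_D ~ N(0, σ²_D), u_F ~ N(0, σ²_F). A hybrid-level residual
e ~ N(0, σ²_e) and, per plot, a fixed environment effect plus plot noise
(both drawn at scale σ²_env_plot — one knob for field noise, so setting it
to zero yields exactly the population means) complete the phenotype.

Meiosis uses the Haldane map function (no interference): crossover
indicators between adjacent markers are independent Bernoulli draws at the
recombination fraction of the cM distance, with free recombination across
chromosome boundaries. DH lines double a single F1 gamete; SSD lines are
selfed generation by explicit generation, so residual heterozygosity arises
at its natural rate (~2⁻ᵍ per initially heterozygous locus) rather than
being injected from a parameter. The infinite-selfing approximation
r\* = 2r/(1+2r) is used only as a test oracle and inside the HMM transition
model, never in the generator.

Founder genotypes are drawn independently per marker: a marker segregates
within a group with probability `p_polymorphic` (conditioned on actually
segregating among the four founders); where a group is monomorphic, the two
groups share the allele with probability `p_shared_minor`. This is enough
structure to exercise all three models' assumptions (group-specific alleles,
shared biallelic QTL) without modelling linkage disequilibrium between
founder panels.

QTL positions are snapped to the nearest mapped marker. All randomness flows
from a single master seed expanded into named substreams (map, founders,
meiosis per population, mating, phenotype, genotyping noise), so stages are
reproducible in isolation.

What the generator does **not** emulate: field spatial structure (plot
values are exchangeable within an environment), selection during line
development, ascertainment bias of array markers, and genotyping error
beyond a symmetric per-call error rate. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated genetic model, not
robustness to those real-data artifacts.

## Ls-means

Hybrid means are adjusted by OLS for `value ~ environment + hybrid` (both
fixed); the ls-mean of hybrid *h* is the intercept plus its effect plus the
unweighted mean of the environment effects. Connectivity of the
hybrid-environment incidence graph is checked first and a disconnected
design is an error naming the components. Environments enter with equal
weights (not plot counts); per-trait environment exclusion is an explicit
configuration choice, not an automatic rule, because no numeric criterion
defines "uncorrelated environment".

## Genotype QC

Markers pass when missingness is below 20% within each group,
heterozygosity is at most 5% among Dent lines and among all lines pooled and
at most 10% among Flint lines (SSD lines legitimately retain residual
heterozygosity), and pooled MAF is at least 5%. Lines are dropped above 10%
(Dent) / 25% (Flint) heterozygous calls. The off-type screen drops lines
inconsistent with their population's founders in more than 20% of
comparable calls; since at a marker informative for a biallelic founder pair
every homozygous call matches one founder, off-type evidence accrues where
the two founders agree (a call for an allele neither carries) or where a
heterozygous call meets identical founders. Segregation distortion is a
per-population chi-square test of 1:1 founder-allele counts,
Bonferroni-corrected at 5% across tested markers by default. The scan set
for the SNP-based models is the markers with MAF strictly above 5% within
both groups; the founder model scans all mapped markers.

## Founder-origin probabilities

For a line from the cross of founders (f1, f2), descent along a chromosome
is a two-state Markov chain. Transitions between adjacent markers use the
Haldane recombination fraction of the map distance — the single-meiosis r
for DH lines and r\* = 2r/(1+2r) for SSD lines, which is the effective
recombination accumulated over repeated selfing (5–6 generations are close
to the limit). Emissions compare the observed call with the founder alleles
under a symmetric per-call error rate (default 1e-3, strictly positive so no
real data set can produce an impossible path): the matching homozygote has
probability 1−ε, each other call ε/2. Heterozygous calls at informative
markers emit ε/2 under either state — origin-ambiguous, which is the
desired treatment of Flint residual heterozygosity — and missing
observations emit 1. A single exact forward–backward pass yields the
posterior; it is deterministic, needs no iterations, and equals exhaustive
path enumeration to 1e-10 (tested up to 2¹² paths).

A near-inbred parent transmits its resident allele, so the hybrid's
probability of carrying founder f's allele is the parent line's own
posterior, placed in the 4-founder slot of its population (the other two
founders get 0); at residual-heterozygous loci the posterior already
averages the two phases with weight 0.5. Missing parental calls are imputed
as posterior-expected founder dosages; note that a posterior-mean dosage
minimizes squared error, so hard-called imputations are the right comparison
for absolute-error benchmarks.

## Mixed model, Wald tests, thresholds

REML estimates (σ²_D, σ²_F, σ²_e) by profiling the residual variance and
maximizing over the two variance ratios with L-BFGS-B (three starts by
default; variance-component surfaces of two-component models are
boundary-prone). Boundary solutions are flagged, not errors; a design in
which every parent appears exactly once leaves its component inseparable
from the residual and is flagged as confounded. Fixed effects follow by GLS.

Each marker's QTL block is tested added-last: the whitened response and
block are residualized against everything else in the model and the
chi-square Wald statistic uses the coefficient covariance of this partition,
with the residual variance re-profiled under the full model at that marker.
With both variance components at zero this reduces exactly to df × the OLS
F statistic. Singular blocks (degenerate markers) use the pseudo-inverse
with rank-reported degrees of freedom.

Identifiability of the founder model deserves a note. The four transmission
probabilities of a group sum to 1, and the 16 SCA products sum to 1, so the
QTL block has rank 15 given the intercept (3 GCA per group + 9 SCA). Two
reductions span the same space: dropping a reference founder per group, or
sum-to-zero (Helmert) contrasts. The global Wald test is identical under
both, but the *component* tests are not: with reference-cell coding, the
added-last GCA test conditions on SCA product columns that nearly span the
GCA columns (the classic Type III coding problem), so a pure GCA QTL can
show a significant global test with a "non-significant" GCA component. The
package therefore parametrizes the reduced block with Helmert contrasts,
making the GCA_D, GCA_F and SCA tests the standard factorial main-effect and
interaction tests. Per-marker variance re-estimation is the default for the
scan, with a "profile" switch (estimate once under the base model) for large
simulation studies; off-QTL the two agree closely and the profiled scan is
conservative at strong QTL.

The genome-wide 5% threshold is −log10(0.05 / M_eff), with M_eff the
effective number of markers: per chromosome, the smallest k such that the
top-k eigenvalues of the marker correlation matrix reach 99.5% of its trace,
summed over chromosomes (the cutoff is configurable). The per-marker scalar
coding used for that correlation matrix is the hybrid additive dosage for
the SNP-based models and the expected founder index of the transmitted Dent
and Flint alleles for the founder model, whose smoother along-chromosome
correlation correctly yields a lower threshold. Base-10 logarithms are used
throughout, the genome-scan convention.

Multilocus selection: forward steps add the most significant remaining
marker above the genome-wide threshold, conditioning on the current
selection (ties broken by smaller p, then lower chromosome/position);
backward steps drop any selected marker whose conditional test falls below
the threshold, weakest first; iteration proceeds to a fixed point with a cap
of 50 and a revisited-state guard. The final model re-estimates variance
components in full and reports, per retained QTL, the global and component
tests conditioned on all other QTL.

## Variance explained and cross-validation

R² values use fixed-effect predictions only (population terms, QTL terms)
under the REML variance structure: R²_pop from the population-only model,
R²_pop+QTL from the final model, R²_QTL by difference, and
R²\*_QTL = R²_QTL / (1 − R²_pop) as the within-population share. The
individual R² of a QTL is the drop in R²_pop+QTL when its columns are
removed and the fixed effects refitted. Note the population block absorbs
the between-population part of any QTL effect whose founder-allele
frequencies differ across populations; the decomposition is a projection
identity, not an orthogonal variance partition.

Cross-validation samples 80% of the hybrids within each of the 36
population combinations (rounded up; strata under 5 hybrids are merged into
the largest stratum with a warning), re-tests the whole-data QTL on the
training set at the individual 5% level, re-estimates population + QTL fixed
effects on training (reusing the whole-data variance ratios rather than
re-running REML per sampling), and records the squared correlation between
predicted and observed test values. Variants: population-only baseline,
GCA/additive terms only, and additionally the SCA/dominance terms of QTL for
which they were individually significant on the whole data. Parental BLUPs
are excluded from prediction because test-set parents are largely absent
from training.

QTL lists from different models are matched greedily by ascending distance
within a 10 cM window per chromosome (lower bound inclusive, upper
exclusive), pairwise only — no chain-linking.

## Problem sizes used by the test suite

The simulation studies in the acceptance tests use 200 null genomes of 2
chromosomes × 100 markers with ~400 hybrids for threshold calibration, 100
replicates of ~1000 hybrids with an 8%-variance Dent-specific QTL for
detection/component recovery (single-start REML there; the multi-start
default matters for boundary cases, not for these well-conditioned fits),
and one ~5000-hybrid design for the R² budget. These sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances.

## Known limitations

* Populations have exactly two founders each; multi-allelic founder HMMs
  (>2 founders per population) are out of scope.
* No kinship-matrix control of relatedness beyond the population terms and
  parental effects; no epistatic design columns.
* The effective-marker rule (99.5% trace) is one of several in use; the
  cutoff is exposed in configuration and thresholds should be read as
  data-dependent outputs.
* CV predictions use fixed effects only; hybrids whose parents appear in
  both training and test sets could in principle borrow parental BLUPs.
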