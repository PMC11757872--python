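# Methods

This note documents the statistical models implemented in `clovergs`, the
design choices made where several conventions exist, what the synthetic-data
generator does and does not emulate, and the numerical details that matter
for reproducing its output.

## The breeding design being modelled

The unit of analysis is an outcrossing half-sib (HS) family programme: a set
of maternal parents is genotyped, each parent's open-pollinated progeny
forms one HS family, and families are evaluated as plots in a replicated
multi-location, multi-year trial. Under this design the among-family
variance carries ¼ of the additive variance (σ²_f = ¼σ²_A) and ¾ remains
within families. The two-stage analysis first condenses plot records into
family BLUPs (stage 1), then regresses those BLUPs on the maternal parents'
marker genotypes (stage 2) so that unphenotyped candidates can be ranked
from markers alone.

## Synthetic data generator

`synthetic_data.SimConfig` defaults encode the reference study conditions:
200 HS families, 100 seedlings per family, 2 locations × 3 years × 3
replicates, 24 check plots per replicate (12 per check cultivar, giving
3×(200+24) = 672 plots per location and 1,344 in total), and low-coverage
GBS with mean depth 8× and negative-binomial overdispersion (size 2), which
yields a median depth around 7 — comfortably in the "median < 12.8" regime
the depth-adjusted kinship estimator is designed for.

Population model. Founder allele frequencies are uniform on [0.05, 0.5].
The parents are *not* mutually unrelated by default: they are simulated as
crosses among a limited base of founder lines (40 by default,
`n_founder_lines=None` gives unrelated Hardy–Weinberg parents). This is the
one structural choice that matters for realism. With unrelated parents and
markers in linkage equilibrium, GBLUP's accuracy is bounded near
√(n/(n+m)) ≈ 0.1 at n = 200 and m = 5,500 — far below what related breeding
material achieves, because in such panels most of the accuracy comes from
family relationships captured by the markers. A founder-line base of 40
gives each parent ≈ 10 half-sibs among the other parents and puts
predictive abilities in the empirically observed 0.2–0.45 range without any
further tuning.

Families are produced as one maternal gamete (free recombination; markers
unlinked) plus one gamete from a random non-self parent — an open-pollinated
polycross with selfing excluded. Traits are controlled by pleiotropic QTL
(default min(100, m) loci) with effects drawn multivariate normal across
traits; the effect draws are recoloured so the realized progeny
breeding-value correlation equals the target genetic-correlation matrix
exactly, and rescaled per trait so the variance of family means equals
σ²_f exactly. Trait defaults (σ²_f, σ²_fl, σ²_fy, σ²_e) = (1.0, 0.6, 0.6,
2.0) give a family-mean h² ≈ 0.62; supplying `h2_family_mean` re-derives
σ²_f from the other components.

Read model. Depth per entry is gamma–Poisson (negative binomial); given
depth k, alternate reads are Binomial(k, dosage/2); depth 0 is a missing
call. The naive call is heterozygous only if both alleles are seen, so a
true heterozygote at depth k is miscalled homozygous with probability
2·(1/2)^k. An optional per-read error rate exists and defaults to 0 — the
depth-adjusted kinship model below assumes error-free binomial sampling.

What the generator does not emulate: linkage disequilibrium along
chromosomes (markers segregate independently), spatial autocorrelation in
the row–column layout, grazing/defoliation dynamics, polysomic inheritance
(the allotetraploid is treated as disomic, which is the observed inheritance
mode in white clover), multi-allelic variants, and genotyping artefacts
other than collapsed homoeologues (which are emulated only as
heterozygote-excess markers for filter tests). Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to spatial trends or LD structure in real trials.

## Marker quality control

The screen retains biallelic SNPs with MAF ≥ 0.01, missing fraction ≤ 0.5
and HWdis > −0.05, where HWdis = f(AA) − p² is computed from naive calls
with A the major allele; all-heterozygote markers score −0.25 and are
removed as collapsed-homoeologue candidates. Removal counts are attributed
to the first failing rule in the order MAF → missingness → HWdis. Note that
at low depth, observed heterozygosity is biased downward (miscalled
heterozygotes), so call-based HWdis is a coarse screen, not an estimator;
this matches its role here. Filtering is idempotent.

## Relationship matrices

VanRaden: markers coded −1/0/1, missing entries replaced by the marker mean,
columns centred by P = 2(p − 0.5), G = XX′ / (2Σp(1−p)). Allele frequencies
are estimated from naive calls over all individuals unless supplied.

Depth-adjusted (KGD-style): computed from fractional dosages d = 2·alt/k
rather than hard calls. Off-diagonals use only markers observed in both
individuals, with the denominator restricted to the same marker set; because
read sampling is independent between individuals, no further correction is
needed. The naive diagonal is inflated by heterozygote read-sampling
variance: E[(d−2p)²] = (g−2p)² + g(2−g)/k at depth k. Since
E[d(2−d)] = g(2−g)(1−1/k), the statistic d(2−d)·k/(k−1) is unbiased for
g(2−g) when k ≥ 2, so the implementation subtracts d(2−d)/(k−1) per marker;
at k = 1 nothing in the data identifies g(2−g) and the Hardy–Weinberg
expectation 2pq is subtracted instead. The resulting diagonal is validated
against a Monte-Carlo oracle (200 replicate read-samplings of a known
individual at mean depth 2) before the matrix is used in prediction. The
estimator is method-of-moments and can be slightly indefinite; the GBLUP
solver bends it (clips negative eigenvalues) when the most negative
eigenvalue is within 5 % of the largest, and refuses it otherwise. Dense
solvers add a logged 1e−6 ridge where needed.

MDS uses the inner-product distances d²_ij = G_ii + G_jj − 2G_ij, i.e.
classical scaling of the double-centred GRM.

## Stage-1 REML

The model is y = μ + location + year + rep(location) + f + fl + fy + ε with
independent normal random effects; check plots carry fixed cultivar effects
and no family effect; interactions confounded by a single-level factor are
dropped with a warning. This is a declared simplification of a full
row–column spatial analysis: it carries exactly the components the gain
model consumes. The restricted likelihood is profiled over the residual
variance and maximised directly over log variance ratios (Nelder–Mead on
the mixed-model-equation form; one sparse cross-product pass, then one dense
Cholesky of the ~q×q coefficient matrix per evaluation). Variance ratios are
bounded in [e⁻¹⁵, e¹⁵]; boundary estimates are clamped to zero. Family
BLUPs come from the mixed-model equations at the optimum; the reported
grand mean is the average fixed-effect level of a family plot. The solver is
cross-checked against lme4 (REML) in the test suite: components agree to
2 % and BLUPs correlate > 0.999 on a shared dataset.

σ_PF, the among-family phenotypic SD used by the gain engine, is the
family-mean SD for the evaluation design,
√(σ²_f + σ²_fl/l + σ²_fy/y + σ²_e/(lyr)), with the number of years
overridable (2- vs 3-year scenarios) and a user-supplied σ_PF accepted,
since deterministic-gain software conventions differ on this point.

## Stage-2 prediction

The response is the stage-1 family BLUP attached to the genotyped maternal
parent (family ids and parent ids coincide in this package's data model).
BLUPs are not weighted by reliability.

GBLUP/KGD-GBLUP share one code path; only the relationship matrix differs.
Variance components are estimated by profiled REML on a single
eigendecomposition of the training block (1-D bounded search over the log
variance ratio); GEBVs for all individuals follow from the genomic
covariance with the training set. An independent dense-solve path exists
and agrees to 1e−8; on complete data GBLUP equals the ridge marker
regression with matched penalty to 1e−6 (both are test invariants).

BayesCπ: spike-and-slab marker effects with a common slab variance,
inclusion probability sampled with a uniform prior, scaled-inverse-χ²
priors (df 5) on slab and residual variances with scales set from the
phenotypic variance by an R² = 0.5 heuristic — the convention of standard
Bayesian whole-genome-regression software, exposed in
`PredictionModelSpec`. Default chain: 3,000 iterations, 1,500 burn-in,
thinning 1 (posterior summaries use all post-burn-in draws). The sampler is
a numba kernel; fixing the seed fixes the output exactly.

RKHS: Gaussian kernel K_ij = exp(−h·d²_ij/median(d²)) on mean-imputed
centred dosages, fitted by the same machinery as GBLUP. The default is a
single kernel with h = 1 on median-scaled distances; h is configurable
(e.g. for multi-kernel averaging by the caller). As h → 0 the kernel
degenerates to all-ones and predictions collapse to the intercept.

Multi-trait model: y_it = μ_t + b_it + e_it with b ~ N(0, K ⊗ G)
(K unstructured, inverse-Wishart prior with df T+2 and scale ½·diag(vy))
and diagonal residual covariance (scaled-inverse-χ², df 5). Gibbs updates:
the full conditional of b has precision K⁻¹ ⊗ G⁻¹ + diag(obs/r) and is
sampled by one Cholesky per iteration; masked phenotype cells simply drop
out of the likelihood, which is what implements the MTCV schemes. A fully
masked secondary trait is legal (its μ/R updates fall back to the prior); a
fully masked primary trait is an error. K updates that lose positive
definiteness are jittered with a warning.

## Cross-validation and sweeps

Monte-Carlo CV draws a random 20 % test set per iteration (default 100
iterations), fits on the training set only and scores predictive ability
r(GEBV, BLUP) and bias (slope of observed on predicted) on the test set.
Relationship matrices are built once on all individuals — standard GBLUP
semantics. Iterations with constant predictions have undefined r and are
recorded as missing, excluded from means and counted, never coerced to 0.
MTCV1 masks all traits of test individuals; MTCV2 masks only their primary
trait. In the training-size sweep the test set is drawn before the training
pool is subsampled, keeping test difficulty constant across sizes; in the
marker sweep the GRM is rebuilt per subset per iteration. Box-plot
significance uses the notch convention median ± 1.58·IQR/√n. Accuracy is
r/√h², clipped to [−1, 1] with a warning.

## Deterministic gain

Selection intensity is the infinite-population truncated-normal value
k = φ(z)/p (k(20 %) = 1.400, k(1 %) = 2.665); an optional finite-population
correction k − (N−n)/(2n(N+1)k) sits behind a flag because the convention
used by deterministic-gain tools is not standardised. Scheme counts use
round-half-up with a floor of 1 and error on an empty selection; with 200
families, 100 seedlings per family, 5 % among-family and 1 % within-family
pressure this yields 10 families, 1,000 plants genotyped and a 10-genotype
polycross. The two gain equations are implemented exactly as stated in the
package docstrings; the within-family term k_W c_W h_X r (√3/2) σ_PF uses
the among-family SD symbol deliberately — (√3/2)·σ_PF encodes the
within-HS-family phenotypic SD under the ¾-within-family additive-variance
partition. Percent gains are relative to the trial grand mean, which must
be supplied; the percent increase of the combined strategy over phenotypic
selection is independent of it.

## Problem sizes and runtime choices

The test suite and `scripts/acceptance.py` keep the study's population and
panel sizes — 200 families and 5,500-marker panels (11,000 for the plateau
check) — and scale the Monte-Carlo repetition counts instead: 15–30 CV
iterations per setting (8 per phenotype realization × 3 realizations for
the multi-trait comparison, where a single noise draw at h² = 0.2 would
otherwise dominate), BayesCπ chains of 1,500/500 and multi-trait chains of
800/300 inside CV loops, with full-length 3,000/1,500 chains retained as
model defaults and for single-fit parameter-recovery tests. Simulated
trials for REML recovery use 80–100 families over 6–8 seeds. Behavioural
checks are band or direction checks (model spread ≤ 0.06, plateau gap
≤ 0.03, dispersion ratio > 1), so the reduced repetition counts leave
ample margin; parameter-recovery checks use two empirical standard errors
across seeds.

## Known limitations

Stage 1 ignores spatial row–column effects and seasonal repeated measures;
the KGD diagonal uses an HWE fallback at depth 1 (slightly biased for
inbred individuals); BayesCπ assumes a single slab variance; the
multi-trait sampler is O((nT)³/ iteration) and is practical to a few
hundred individuals and a handful of traits; the gain engine is single-cycle
and deterministic — no inbreeding trajectories, drift, or multi-cycle
two-part strategies.
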