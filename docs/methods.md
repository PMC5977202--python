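# Methods

`hostcline` analyses genomic differentiation between two host races of a
phytophagous insect sampled at latitudinally ordered sympatric sites, from
low-coverage genotyping-by-sequencing (GBS) data.  This note documents the
statistical procedures, the synthetic-data generator that stands in for raw
study data, the numerical choices, and the known limitations.

## Genotype likelihoods and allele frequencies

All inputs are per-individual genotype likelihoods for biallelic SNPs
(VCF `GL` or `PL`).  At 3–6× mean coverage hard genotype calls are
unreliable, so allele frequencies are estimated by an EM algorithm with a
Hardy–Weinberg prior: with likelihoods L_i(g) for g ∈ {0, 1, 2} copies of
the alternate allele,

    w_i(g) ∝ L_i(g) · HWE(g | p),
    p ← Σ_i Σ_g g · w_i(g) / (2 n_informative),

iterated to |Δp| < 1e−6 (max 100 iterations; p clipped to [1e−9, 1−1e−9]
inside the prior so boundary estimates stay well-defined).  Individuals
that are missing (zero depth) or genotype-flat are excluded; they do not
move the fixed point.  With certain likelihoods the estimator reduces
exactly to the allele-count estimator.  The observed-data log-likelihood
is non-decreasing across iterations (tested).

Expected dosages E[g | data, p] under the same prior are the working
currency for LD, resampling and clustering; at the EM fixed point the mean
posterior dosage over informative individuals equals 2p̂ (tested at 1e−6).

Sign conventions are fixed globally: eclosion response = early − late
emergence groups; prewinter response = 7-day − 32-day treatment survivors;
geography = first − last site in latitudinal order; host = hawthorn −
apple.  Reference polarization (counting the reference population's major
allele) breaks p = 0.5 ties as "no flip".  The eclosion response used
downstream is the arithmetic mean of the per-race response vectors.

## Composite LD and LD classes

Composite (Burrows) disequilibrium is estimable from unphased genotypes:

    Δ̂ = (1/2n) Σ X_i Y_i − 2 p̂_A p̂_B,
    r̂ = Δ̂ / sqrt((p̂_A q̂_A + D̂_A)(p̂_B q̂_B + D̂_B)),

with D̂_A the within-locus Hardy–Weinberg disequilibrium.  With population
(1/n) moments these equal half the dosage covariance and the dosage
Pearson correlation, which is how the vectorised code computes them; the
genotype-count form is kept as an independent oracle in the tests.
Pairs are computed pairwise-complete over missing entries; monomorphic
loci and pairs with n < 2 are NA with a reason.

Within-chromosome r̂² drives a threshold-graph classification into LD
classes, proxies for association with inversion polymorphism: a SNP is
**high** iff r̂² > 0.6 with at least one other SNP on its chromosome,
**low** iff every within-chromosome r̂² < 0.15, **intermediate**
otherwise.  Thresholds are strict as stated; values exactly in
[0.15, 0.6] are intermediate; a SNP alone on its chromosome is low
(vacuously); an all-NA row is unassigned.  High-class SNPs are grouped
into connected components of the > 0.6 graph.  The per-SNP
"mean linked LD" covariate is the mean r̂² to all other same-chromosome
SNPs (|r̂| available via `stat="abs_r"`).

Dosages entering LD are posterior means (soft calls) by default, because
coverage is low.  Soft dosages shrink toward the prior mean, which
attenuates r̂² relative to true genotypes — at ~4× coverage enough to pull
a minority of genuine high-LD pairs under the 0.6 threshold.  The LD-class
recovery analyses therefore run at 6.2× mean depth, the coverage of the
eclosion-study data from which the original class assignments derive.

## Monte Carlo resampling tests

Two-group frequency contrasts are tested non-parametrically: null
replicates draw, with replacement from the pooled individuals of both
groups, random samples of the original group sizes — whole individuals,
so LD among loci and missingness patterns are preserved — and recompute
per-SNP |Δp|.  A SNP is significant iff its observed |Δp| strictly
exceeds the 95th percentile (linear interpolation) of its own null draws
(two-sided at overall α = 0.05).  The table-wise excess test scores each
replicate's percentage of SNPs beyond their own critical values and asks
whether the observed percentage exceeds the 95th percentile of that
distribution.

Within replicates, per-individual genotype posteriors are computed once
from the pooled sample, and group frequencies re-estimated as mean
posterior dosage / 2 over resampled individuals (no EM refit per
replicate — the resampling operates on genotype probabilities, not reads).
The observed statistic uses the same estimator so observed and null are
exactly comparable.  All Monte Carlo p-values use the add-one convention
(1 + #{null ≥ obs}) / (n_reps + 1); the minimal attainable p is
1/(n_reps+1).  Critical values are taken from the full replicate set (no
hold-out); per-SNP quantiles require at least 100 valid draws, else the
SNP is untestable.

**Calibration.**  The per-SNP test is well calibrated: on null data (one
population split into two groups of 30, 2,000 SNPs, 2,000 replicates) the
rejection fraction is ≈ 0.05.  The *table-wise* p-value under the
with-replacement bootstrap is **not** uniform under the null: the critical
values are built from the same pooled individuals as the observed data, so
the observed percentage's shared-individual noise is conditioned away
while replicate percentages retain it, and the table-wise p concentrates
mid-range (measured ≈ [0.19, 0.57] on null datasets).  The test is
therefore conservative for declaring table-wise excess.  A
without-replacement variant (`resample="permutation"`), in which the
observed split is exchangeable with the replicates, is exactly calibrated
(table-wise p uniform; measured KS p ≈ 0.45).  The bootstrap remains the
default because it is the procedure the analysis is defined by; users who
need a calibrated table-wise p should use the permutation variant.

Cross-experiment regressions get Monte Carlo significance the same way:
the observed r² regresses the contrast's Δp vector on a fixed predictor
vector across SNPs; null replicates rebuild Δp from resampled pooled
individuals.  The predictor is held fixed (it comes from an independent
experiment); a both-sides mode exists behind `resample_predictor=True`.

## Regressions

Simple regressions are OLS over pairwise-complete SNPs, reporting the
signed correlation r (sign of the slope) alongside r².  Stepwise multiple
regression searches both directions from the full model, scored by
Gaussian AIC = n·ln(RSS/n) + 2k with k the number of fitted coefficients
(computed from the design-matrix rank, so duplicated or collinear
predictors are penalised correctly and exactly one copy of a duplicated
column survives).  AIC ties break toward the smaller model, then earlier
column order.  The four-predictor design (eclosion, apple prewinter,
hawthorn prewinter, mean linked LD) is fit complete-case on mapped SNPs,
since mean linked LD is undefined off the map.  Per-SNP observations are
treated as independent; LD-induced dependence between SNPs inflates the
classical t/F statistics, which are reported as descriptive.

## Clustering

**Nei distance.**  For biallelic loci, J_X = mean(p² + q²), J_XY =
mean(p_x p_y + q_x q_y), D = −ln(J_XY / sqrt(J_X J_Y)), NA loci dropped
pairwise; a non-positive identity yields an infinite, flagged distance.

**Neighbor joining.**  Saitou–Nei agglomeration with the standard
branch-length update; a negative branch length is clamped to zero and the
deficit shifted to its sister so the joined pair's path length is
preserved; Q-matrix ties resolve to the first row-major minimum
(deterministic).  On additive metrics topology and branch lengths are
exact (tested at 1e−10 against closed forms and against an independent
implementation).  Bootstrap support resamples loci with replacement
(replicates with non-finite distances are skipped and counted) and reports
each observed bipartition's recovery percentage.

**DAPC.**  Missing dosages are imputed with the per-SNP mean; columns are
centred (no unit-variance scaling by default; flag available); PCA by SVD;
linear discriminant analysis on the retained m PC scores with equal group
priors and pooled within-group covariance (ridge 1e−9·tr(W)/m for
numerical safety).  Membership probabilities are the Gaussian posteriors;
"mean correct assignment" is the mean posterior probability of an
individual's own group.  The number of PCs is chosen by a-score: observed
correct-reassignment proportion minus its mean over label-randomized
refits (n_rand = 10 by default), maximised over the m grid with the
smallest m on ties.  Self-reassignment (no cross-validation) matches the
definition of the score.  Cluster significance permutes labels with group
sizes preserved and compares the observed mean correct-assignment
probability to the permuted distribution.

**Mantel.**  Geographic distance is the difference in latitudinal site
order; ecological distance is a same/different-host indicator; r is the
Pearson correlation of upper-triangle entries; permutations jointly
shuffle rows and columns of the genetic matrix; one-tailed p (positive
association), since the isolation-by-distance/ecology hypotheses are
directional.

## Coupling LD among unlinked loci

SNPs "strongly associated with diapause" are those significant in at least
one of the three experiments AND showing |Δp| ≥ 0.2 in at least one.
Composite LD is then computed for all pairs on *different* chromosomes:
within each population, within host pairs pooled per site, and within the
geographic extremes pooled — the per-pair Δ̂ averaged across the pools of
each mode, giving one distribution per mode.  Pooling populations with
allele-frequency offsets δ_A, δ_B adds δ_A δ_B / 2 to the expected pair
Δ̂ (mixture covariance), so concerted divergence right-shifts the pooled
distribution relative to the within-population baseline; this closed form
is verified in the tests.  Δ̂ is the default reported axis; r̂ is emitted
alongside.

## Synthetic data generator

The generator emulates the study design: 2 host races × 4 latitudinally
ordered sympatric sites, ~2,000–3,000 biallelic SNPs on 5 chromosomes plus
an unmapped bin (mapped fraction ≈ 41%, mirroring the study panel), paired
experiment samples, and GBS-style sequencing.

Population allele frequencies follow a logit-scale model per SNP:

    logit p = α + β·s + γ·[apple] + α_site(s) + γ_site(s)·[apple]

with s the 0-based site order.  β is the shared latitudinal slope, γ the
shared host effect; `alpha_site` are drift-like per-site offsets shared by
the sympatric pair, and `gamma_site` are site-local host effects.  The two
site-local terms matter: a perfectly straight logit cline makes Nei
distances grow quadratically in site separation (non-tree-additive, so NJ
chains interior sympatric pairs instead of pairing them), and a purely
shared host effect displaces every apple population in the same direction
(likewise breaking local pairing).  Real data show neither pathology —
host divergence direction varies among sites ("crossing" patterns) and
geographic differentiation accumulates partly in independent directions —
and both terms implement exactly that.

Inversion polymorphism is modelled as biallelic latent orientations: each
block (one high-LD, m = 0.02, and one intermediate-LD, m = 0.12, block per
chromosome by default) has its own orientation cline; an individual draws
two latent gametes and each member SNP's allele matches its gamete's
orientation with probability 1−m.  This produces the three within-
chromosome LD strata the classification targets.

Default magnitudes (logit scale): β ~ ±U(0.06, 0.24) on 35% of SNPs;
γ aligned with β's sign for 70% of clinal SNPs (the coupling fraction),
magnitude U(0.04, 0.16); site effects N(0, 0.25); site-local host effects
N(0, 0.08); block orientation clines β ~ ±U(0.09, 0.21).  These were
calibrated so the measured Nei distances sit in the study's regime —
geographic distance ≈ 0.02–0.03, sympatric host distance ≈ 0.010–0.013,
ratio ≈ 2–3 — i.e., within-race geographic differentiation two- to
three-fold greater than host differentiation in sympatry.  Defaults for
sampling: 50 individuals per population, Poisson depth 4 (the surveys ran
at ~3.3–6.2×), base-calling error 0.01.  Experiment samples (eclosion
early/late 50+50 per race; prewinter 7-day/32-day 48+41 per race) are
drawn from frequency-shifted copies of a base population (±δ/2, clipped
into (0,1), δ attenuated to the base frequency's headroom), since the
downstream analysis consumes only frequency contrasts; planned responses
concentrate on chromosomes 1–3 (eclosion) and 2–3 / 3–5 (prewinter), with
70% of δ signs aligned to the local cline direction.

Read simulation: depth ~ Poisson(depth_mean); alternate reads ~
Binomial(d, e_g) with e_g ∈ {ε, ½, 1−ε}; genotype likelihoods are the
binomial read likelihoods; d = 0 is a missing entry.  `PL` is written as
rounded phred-scaled normalized likelihoods, `GL` as log10 likelihoods at
4 decimals.  One master seed drives all sub-streams.

What the generator does **not** emulate: read-level error structure
(FASTQ), allele-sharing via migration between sites (populations are
independent draws from the cline model), recombination gradients within
inversions, selection acting through time, and reference-bias or
paralog artefacts in the genotype likelihoods.  Passing tests therefore
demonstrate correctness of the estimators and the qualitative
geographic-vs-host regime, not robustness to those real-data artefacts.

## Problem sizes in the test and acceptance runs

The bundled analyses run at desk scale: 2,000–3,000 SNPs (vs 10,241 in a
full panel), 50 individuals per population, 2,000 Monte Carlo or bootstrap
replicates where the field convention is 10,000 (the pipeline default
remains 10,000).  These sizes are the package's own choice of
reproducible example scale; all procedures scale linearly or quadratically
in the obvious dimensions.

## Known limitations

- The table-wise excess p-value of the bootstrap resampling test is
  conservative, not uniform, under the null (see Calibration above).
- Classical p-values in regressions ignore between-SNP LD.
- The NJ clamp-and-transfer rule for negative branch lengths preserves
  path lengths for the joined pair only; deeply non-additive inputs can
  still produce zero-length internal edges.
- EM frequencies assume Hardy–Weinberg within each sample; within
  inversion blocks this is an approximation when orientations are
  strongly clinal.
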