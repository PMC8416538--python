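# Methods

`mtgp` implements the genomic-prediction workflow of a replicated,
multi-environment wheat breeding trial: marker QC, genomic relationships,
adjusted phenotypes, and a ladder of prediction models from single-trait
GBLUP to a Bayesian multi-trait multi-environment (MTME) model, evaluated
with the cross-validation schemes and the sparse-testing allocation used in
practice. This note records the models, the priors and numerical choices,
what the synthetic data emulate, and the known limitations.

## Phenotype adjustment

Plot values from a randomised complete-block trial are reduced to
per-environment adjusted genotype means (BLUEs) with the model

    y_ij = mu + R_i + G_j + e_ij

where the replicate (complete block) R_i is random and the genotype G_j is
fixed. A companion fit with genotype random supplies the variance
components for the entry-mean broad-sense heritability

    H2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / n_rep).

The across-environment model adds random environment, replicate-within-
environment and genotype-by-environment terms; genotype is fixed for BLUEs
or random for BLUPs. All REML fits use an EM algorithm on the mixed-model
equations, iterated to a relative tolerance of 1e-8 (at most 10,000
iterations) with variance components floored at zero; blocks whose
component hits zero are dropped from the final solve (their BLUP is exactly
zero), which keeps fixed effects clean at the boundary. On balanced data
this EM-REML coincides with the classical ANOVA estimators, which is how it
is tested (plus an independent lme4 cross-check on unbalanced data).

Per-environment BLUEs — not across-environment BLUPs — are the response of
every prediction model; an across-environment fit is provided separately.

## Genomic relationships

With dosages coded 0/1/2 (count of the alternate allele) and allele
frequencies estimated from the analysed lines themselves, the column-
centered matrix W = Z − 2p gives

* the additive GRM, G = WW′ / (2 Σ p_k(1−p_k)) — used by every predictor;
* the centered-IBS kinship, K = WW′ / (trace(WW′)/n) — mean diagonal 1,
  proportional to G off the diagonal.

Non-PSD matrices (possible after mean imputation and filtering) are
repaired by clipping eigenvalues below 1e-8 and reconstructing; clipping
preserves eigenvectors, which the spectral REML and both Gibbs samplers
reuse. Markers are filtered by missingness (> 20% removed), then minor
allele frequency (< 0.05, computed on non-missing calls), then unplaced
markers; missing dosages are imputed with the per-marker mean. Mean
imputation is a deliberate simplification relative to haplotype-based
imputation: it preserves allele frequencies but not linkage structure.

## Single-trait GBLUP

y = 1·mu + u + e with u ~ N(0, G sigma_g^2). The restricted likelihood is
profiled to a one-dimensional function of delta = sigma_e^2/sigma_g^2 after
one eigendecomposition of G, and maximised by bounded scalar optimisation
on log(delta) in [1e-5, 1e5]. The model is exactly equivalent to ridge
regression on centered markers at penalty delta · 2Σp(1−p) (push-through
identity), which the tests verify to 1e-6. Unphenotyped lines are predicted
by joint-normal conditioning, u_new = G[new, obs](G[obs] + delta I)^{-1}
(y − mu), so every line in G gets a GEBV. Variance components are refit
inside every cross-validation replicate; nothing from held-out lines enters
the fit.

## Bayesian multi-trait model

Per environment, Y (n lines × t traits) = 1 mu′ + U + E with
vec(U) ~ N(0, Σ ⊗ G), unstructured t×t genetic covariance Σ, and a
*diagonal* residual covariance. Gibbs sweep order: intercepts, U, Σ
(inverse-Wishart), residual variances (scaled-inverse-chi-square), missing
cells (data augmentation). In the eigenbasis of G the rows of U are
conditionally independent, so the U update is n batched t×t solves.

Priors: flat intercepts, Σ ~ IW(t+2, I), residual variances
~ scaled-inv-χ²(ν=3, s² = half the observed variance). Traits are
standardised internally and back-transformed, so these identity-scale
priors are weakly informative whatever the trait units; without the
standardisation the Σ prior measurably drags the genetic variance of
large-unit traits (verified against an exact two-parameter grid posterior
at t=1, which the sampler reproduces).

Masked cells (the CV1/CV2 schemes) enter the sampler only through their
augmented draws — they contribute nothing to the Σ or residual full
conditionals — which makes the masking schemes exact rather than
approximate.

## Bayesian multi-trait multi-environment model

On the environment-major stacked response Y (j × t, j = n·l):

    Y = X B + Z1 b1 + Z2 b2 + E
    b1 ~ MN(0, G, Σt),  b2 ~ MN(0, ΣE ⊗ G, Σt),  E ~ MN(0, I_j, Re)

with environment fixed effects B, genotype main effects b1, genotype ×
environment × trait effects b2, unstructured trait covariance Σt,
environment covariance ΣE and unstructured residual covariance Re. The
Kronecker structure is never materialised: with G = QDQ′ and ΣE = PΛP′ the
rotated rows are conditionally independent, so each sweep costs batched
t×t solves over n (b1) and n·l (b2) rows.

Two sampler design choices matter:

* **Partially collapsed b1 draw.** b1 and the common component of b2 are
  nearly confounded; drawing b1 with b2 integrated out (then b2 | b1) is a
  valid blocked draw that removes an otherwise severe random walk along
  that ridge.
* **Residual prior scale.** Priors are B flat, Σt ~ IW(t+2, I),
  ΣE ~ IW(l+2, I) and Re ~ IW(t+2, 0.01·I) on standardised data. The small
  residual scale matters: an identity scale would act as a handful of
  pseudo-observations of pure noise at full phenotypic variance and put a
  spurious floor (~8% of variance at n=40) under Re, visibly breaking the
  near-interpolation limit on high-heritability data.

ΣE is left unnormalised. Because Σt is shared by b1 and b2, the overall
scale of ΣE is likelihood-identified — its diagonal carries the G×E share
of genetic variance relative to the main effect — and forcing a unit
diagonal would pin that share and distort the ΣE correlations.

**Identifiability caveat.** The likelihood identifies only
(11′ + ΣE) ⊗ Σt: splitting a compound-symmetric environment covariance
between b1 and b2 is a prior-influenced choice, so the posterior ΣE
correlation is attenuated relative to a generative value even though
predictions (driven by b1 + b2) are unaffected. Recovery tests of ΣE
should be read with this in mind; the environment-covariance acceptance
check is deliberately left asserting the generative value and documents
this limit when it fails.

Default chain lengths follow the production settings (5,000 burn-in with
25,000 iterations for cross-validation, 15,000 for sparse-design runs,
thinning 5); the test suite and the acceptance script use shorter chains
(200–2,000 burn-in, 600–8,000 iterations) chosen so that doubling the
chain moves posterior means by less than the Monte-Carlo error at the
problem sizes used.

## Evaluation

Predictive ability (PA) is the Pearson correlation between predictions and
the held-out per-environment BLUEs — raw plot values are never used.
Schemes, all on repeated random 80/20 line splits (a k-fold mode exists):

* ST-CV1: single-trait GBLUP, test lines fully unphenotyped (default
  1,000 repetitions);
* MT-CV1: multi-trait, all traits of test lines masked (default 50);
* MT-CV2: only the primary trait of test lines masked; their secondary
  traits stay in the fit (default 50);
* MTME-CV: every cell of a test line masked in all environments
  (default 25).

Partitions are derived deterministically from the seed, so schemes run at
the same seed are paired by repetition. Summaries are plain means over
repetitions (Fisher-z averaging is available), and percent improvement is
100·(PA_model − PA_baseline)/PA_baseline. Every runner accepts an audit
callback that receives the exact masked object handed to the fitting
stage; the leakage tests assert the masked cells are NaN there and that
corrupting held-out values leaves predictions bit-identical.

Sparse testing: elite lines phenotyped in all environments, advanced lines
in a training subset; the MTME model predicts the advanced lines in the
held-out environments and PA is scored per (environment, trait) against
their actual held-out BLUEs.

## Synthetic data

The generator emulates a winter-wheat advanced-breeding trial: ~150 inbred
lines from ~15 families, ~2,000 genome-wide SNPs (scalable to 10,000+),
five environments, two complete blocks, and up to five agronomic traits
(grain yield, protein, test weight, height, heading date) with entry-mean
heritabilities in the 0.6–0.95 range and a negative yield–protein genetic
correlation. Families are made by drawing a small pool of founder
haplotypes per family (marker frequencies U(0.05, 0.5)) and mixing two
founder haplotypes per recombination-free block per line — enough to
create realistic within-family relatedness without a meiosis model.
Markers that come out nearly monomorphic are redrawn so realized MAF stays
above 0.01.

Phenotypes follow the MTME generative direction: B1 ~ MN(0, G, v1·Σt),
B2 ~ MN(0, ΣE ⊗ G, v2·Σt) with v1 = v2 = 1/2 by default (the
`main_effect_prop` dial), plus a small block effect (5% of genetic
variance) and plot noise calibrated per (environment, trait) from the
*realized* genetic variance so the entry-mean H² hits its target exactly:
sigma_plot² = n_rep · var(g) · (1−h²)/h². Exact calibration is what makes
±0.08 recovery bounds meaningful at n = 300.

Two presets mirror a two-season contrast: `season_low` (yield–protein
correlation −0.28, other trait correlations halved, environment
correlations 0.3) and `season_high` (yield–protein −0.54, stronger trait
correlations, environment correlations 0.7). Genetic standard deviations
(4 bu/ac yield, 0.5% protein, 0.9 kg/hL test weight, 3 cm height, 1.2 d
heading) and environment means are chosen to give coefficients of
variation in the range typical of such trials.

What the generator does **not** emulate: linkage disequilibrium decay and
map structure (blocks are recombination-free), selection and drift,
non-infinitesimal trait architecture, heterogeneous residuals within an
environment, and spatial field trend. Tests passing on these data show the
estimators and schemes behave correctly under the stated generative model,
not that real-trial accuracies will match any particular printed value.

## Problem sizes and reproducibility

All randomness flows from explicit integer seeds: the generator derives
child streams from (seed, fixed offsets) with numpy's PCG64, and every
Gibbs chain takes its own seed, so runs are bit-reproducible. The test
suite and `scripts/acceptance.py` run the full pipeline at reduced sizes —
40–300 lines, 300–2,000 markers, 2–5 environments, cross-validation at
4–20 repetitions with shortened chains — sizes chosen so the whole
analysis re-runs comfortably on a laptop while leaving the qualitative
contrasts (CV2 > ST, MTME > ST under strong correlations, sparse-testing
accuracy) clearly resolvable.

## Known limitations

* EM-REML is robust but slowly converging near variance boundaries; the
  across-environment model with many G×E levels is the slowest fit.
* Posterior means of weakly identified variance splits (genetic vs
  residual on smooth kinship spectra; b1 vs common-b2) are prior-sensitive
  even when predictions are stable; REML point estimates and Bayesian
  posterior means legitimately differ there.
* The diagonal-residual multi-trait model ignores residual trait
  correlations by construction.
* Mean imputation attenuates relationships if missingness is high.
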