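# Methods

`haplogp` implements haplotype-block genomic prediction for phased diploid
SNP panels: haploblock construction, haplotype-allele dosage coding,
VanRaden-form relationship matrices, GBLUP-family mixed models, BayesB-family
Bayesian regressions, and cross-validated evaluation of prediction accuracy
and dispersion bias. This note records the models, the numerical choices,
and what the synthetic-data generator does and does not emulate.

## Haploblocks and haplotype alleles

Two partition rules operate on the ordered marker map.

**LD rule.** For two biallelic loci, LD is measured over the 2n phased
haplotypes as r² = D² / (p_A1 p_A2 p_B1 p_B2) with
D = p_A1B1 p_A2B2 − p_A1B2 p_A2B1. A haploblock is a maximal run of
consecutive SNPs in which every adjacent pair has r² at or above the chosen
threshold. The scan is greedy left-to-right within each chromosome: a
candidate block opens at the current marker and extends while the r² between
the block's last marker and the next one clears the threshold. Candidates of
one marker become "nonblocked" SNPs; blocks never span chromosomes; blocks
are disjoint by construction. Monomorphic markers (possible in synthetic
edge cases; LD is undefined for them) go straight to the nonblocked set.
Ties and ordering are fully deterministic.

**Fixed-SNP rule.** The map is chunked into consecutive runs of exactly k
markers (k = 5, 10, 20 typical). The default chunking is genome-wide — the
block count is then exactly ⌈m/k⌉, e.g. 672,060 markers give 134,412 blocks
of five — with a per-chromosome mode offered as the biologically cleaner
alternative (chunking restarts at chromosome boundaries, so remainders occur
per chromosome). Every marker lands in a block; the nonblocked set is empty.

**Haplotype alleles.** Within a block, each phased haplotype spells a string
over the block's SNP alleles; the distinct strings are the block's haplotype
alleles. An individual carries 0, 1 or 2 copies of each allele, giving the
pseudo-marker dosage matrix M_H; before filtering, each individual's dosages
within one block sum to exactly 2 (asserted in tests on every build).
Column order is descending allele frequency with lexicographic tie-break, so
identical inputs give identical designs.

**MHAF filtering.** Haplotype-allele columns with frequency strictly below
the minor-haplotype-allele-frequency threshold (0.01–0.1 typical) are
discarded. A block left with at most one surviving allele is dropped
entirely — its markers are *not* returned to the nonblocked set — and
nonblocked SNPs are themselves MAF-filtered at the same threshold. Recorded
frequencies are always the pre-filter observed values. No reference-allele
column is dropped: all surviving alleles get columns, and the resulting
within-block collinearity is tolerated (both the GRM quadratic form and
Bayesian shrinkage are well defined under collinearity, and total allele
counts then match the natural accounting of observed alleles).

## Relationship matrices

G = (M − P)(M − P)ᵀ / Σᵢ 2pᵢ(1−pᵢ), where M holds 0/1/2 dosages, P's columns
are 2pᵢ, and pᵢ is the *observed* frequency of the counted column (the only
computable choice without a defined base population). The same construction
serves the SNP matrix G, the haplotype-allele matrix G_H, and the
nonblocked-SNP matrix of the combined model. For multiallelic blocks the
denominator Σ 2pᵢ(1−pᵢ) over allele columns is not a heterozygosity; it is
implemented as written because it is the published form of the haplotype
GRM this package follows. A useful identity, used as a cross-module test:
with one-SNP blocks each SNP contributes two complementary allele columns
whose combined centered cross-product is twice the SNP term while the
denominator doubles, so G_H collapses to G exactly.

Symmetry and positive semidefiniteness (eigenvalue ≥ −1e−8, checked up to
n = 2000) are validated on every constructed matrix. No blending toward the
identity is applied by default.

## Mixed models

Records are first adjusted for fixed effects by OLS: candidate factors and
covariates are screened with type-II F-tests, terms with p < 0.05 are
retained and refitted, and the adjusted phenotype is the residual plus the
grand mean. The REML model then contains only the mean and the genomic
effects, matching the pre-adjustment workflow this package mirrors; each
individual has one record, so incidence matrices are identities.

    y = 1μ + a (+ a_u) + e,   a ~ N(0, σa² K₁),  a_u ~ N(0, σau² K₂),
    e ~ N(0, σe² I)

Variance components are estimated by average-information REML. Each
iteration solves the AI system; a proposal that drives a component below the
floor (1e−10 · var(y)) is replaced by the EM-form update
θ_k ← θ_k + θ_k² (y′P V_k P y − tr(P V_k))/n, and any proposal that would
decrease the restricted log-likelihood is step-halved toward the current
point, so accepted iterations never decrease the likelihood (asserted by an
independent eigen-rotated profile-likelihood grid oracle in the tests).
Convergence is |Δ log L_R| < 1e−8 or 200 iterations; non-convergence flags
the result rather than raising. Approximate standard errors come from the
inverse AI matrix by the delta method. For the one-component model
h² = σa²/(σa²+σe²); for the two-component model the per-component
proportions and their sum are all reported, explicitly labelled, since a
single h² is defined only for the one-component model.

GEBVs for unphenotyped individuals are conditional expectations through the
train–validation blocks: â = σ² K[:, train] V_train⁻¹ (y − μ̂), summed over
components. GBLUP predictions are algebraically identical to
ridge-regression SNP-BLUP with λ = σe² / (σa²/Σ2p(1−p)); the test suite
verifies this to 1e−6.

## BayesB

    y = u + Σⱼ Zⱼ αⱼ δⱼ + e,  δⱼ = 1 w.p. 1−π,
    αⱼ | δⱼ=1, σⱼ² ~ N(0, σⱼ²),  σⱼ² ~ scaled-inv-χ²(ν, S²)

Columns Zⱼ are dosages centered by 2pⱼ: SNPs (BayesB), haplotype alleles
(BayesBH), or their union as one exchangeable set with a single π
(BayesBH+BayesB). Per sweep, each column's δⱼ is sampled from its
conditional odds with αⱼ integrated out analytically (point mass at zero vs
normal slab), αⱼ | δⱼ=1 from its conditional normal, σⱼ² from its
conditional scaled-inv-χ², then the intercept and σe² from their
conditionals; the residual vector is maintained incrementally. The sweep is
numba-compiled; a chain of 5,000 over 2,000 columns × 1,000 records runs in
roughly ten seconds on one core.

Priors: ν = 4.2 (default, configurable) and scale
S² = σ̂g² (ν−2)/ν / ((1−π) Σⱼ 2pⱼ(1−pⱼ)), so the prior-expected total genetic
variance equals the initial guess σ̂g² (default half the phenotypic
variance). π defaults per trait analogue: 0.96 for a liveweight-like trait,
0.995 for component traits; chain length 30,000 with 10,000 burn-in
(production defaults; tests and the acceptance script run reduced chains of
5,000/2,000 where the check is about ranking, not about posterior
precision). Posterior means average every post-burn-in iteration; thinning
(default 10) only limits stored diagnostics. Test hooks can freeze the
per-column effect variance and σe², which makes the single-column posterior
a known normal — the suite checks the chain mean against that closed form
within Monte-Carlo error, and checks that π = 0 with a shared fixed variance
reproduces ridge/SNP-BLUP predictions.

Zero-variance columns are skipped with a warning. A column's inclusion
frequency is the posterior mean of δⱼ; effective sample size of σe² is
reported from the stored thinned samples (initial-positive-sequence
estimator).

## Cross-validated evaluation

Five folds × five repeats by default: balanced random partitions (sizes
differ by at most one), deterministic given the seed, and shared across all
models in a run so per-fold comparisons are paired. Per validation fold:

    accuracy r = cor(y_adj, gebv)      bias b = cov(gebv, y_adj)/var(gebv)

b = 1 is unbiased; b > 1 indicates deflated, b < 1 inflated predictions.
Accuracy is the plain correlation — it is not divided by √h². Model
comparisons use the one-sided paired t-test over (repeat, fold) pairs
(df = n−1); the haplotype-over-SNP improvement is the per-fold percent
change 100·(r_hap − r_snp)/r_snp, reported mean ± SE over all (repeat, fold)
pairs (the SE is labelled as such since fold and repeat variation are
pooled). Folds with non-positive baseline accuracy are excluded from
percent change with a warning; constant-GEBV folds get undefined-metric
flags and are excluded from means.

Block construction and allele frequencies are computed once on the full
panel — mirroring the single genome-wide construction step of the workflow
this package follows — and only model fitting is fold-specific, so no
validation phenotype can influence its own GEBV (a permutation leakage test
asserts this).

## Synthetic data

The generator emulates an HD-chip-like livestock panel at desk scale:

- **Founder LD.** Founder haplotypes threshold a latent stationary AR(1)
  Gaussian field whose correlation decays as exp(−d/ld_decay_bp) with
  physical distance d. The per-marker MAF series (marginally uniform on
  [maf_low, 0.5], floor 0.01 by default to match the QC floor) and the
  strand carrying the minor allele are themselves transformed AR(1) paths at
  the same scale: thresholding a shared field can only produce high r²
  between neighbours whose allele frequencies match, so smooth frequencies
  are required for realistic haploblocks, and they also give the correct
  strong-LD limit (decay scale ≫ chromosome ⇒ adjacent r² → 1).
- **Recombination.** n_generations of random mating with Poisson crossovers
  under the Haldane map, one Morgan per chromosome, which breaks long-range
  LD and leaves discontinuous block-like local LD.
- **Defaults.** 10 Mb chromosomes, 500 markers each (20 kb spacing),
  ld_decay_bp = 100 kb, 80 founders, 4 generations. These were calibrated
  empirically — once, before the downstream analyses were frozen — so that
  LD-threshold partitions at r² ∈ [0.2, 0.8] give mean block sizes of about
  3–5 SNPs with maxima of 10–20 and a substantial nonblocked remainder,
  the regime the partitioner is designed for. No external population is
  emulated quantitatively.
- **Phenotypes.** QTL positions uniform without replacement, effects i.i.d.
  normal, tbv = centered QTL dosages × effects, and σe² set so
  var(tbv)/(var(tbv)+σe²) equals the target heritability exactly on the
  realized tbv (targets 0.16–0.40 are the intended regime). Optional
  categorical fixed effects add group shifts. h² = 1 requires nonzero
  genetic variance; h² = 0 requires zero QTL; both are validated.
- **Determinism.** All randomness flows from one seed through named streams
  (SHA-256 of seed:stage), so any stage regenerates independently and
  identical seeds give bit-identical panels and phenotypes.

What the generator does **not** emulate: pedigree structure, selection,
migration, genotyping error, imputation artefacts, sequence-level mutation,
or any dominance/epistatic architecture. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under a clean additive
regime with realistic block-like LD — not performance on any particular real
population.

## Numerical and design choices

- **HWE test.** QC uses the mid-p exact test, enumerated over all feasible
  heterozygote counts given the minor-allele count; SNP removal is
  attributed to the first failing criterion (call rate → MAF → HWE) after
  individual call-rate filtering, and the filter is idempotent.
- **Strict inequalities.** MAF and MHAF filters discard columns strictly
  below threshold; a frequency exactly at threshold survives.
- **Problem sizes.** The heavy checks are sized for a single core: h²
  recovery uses n = 1000 × m = 1000 over 20 seeds per target; BayesB QTL
  recovery uses n = 1000 × m = 2000 with reduced chains of 5,000; CV bias
  calibration uses n = 1000 with 2 repeats × 5 folds. These sizes are the
  package's verification conditions, chosen so the whole suite runs in a
  few minutes.
- **QTL-recovery success rule.** With i.i.d. normal effects, the smallest
  few of ten |effects| are routinely ≈0 and statistically invisible at any
  sample size; the recovery check therefore requires a strict majority
  (≥6/10) of causal columns in the top 5% of inclusion frequency per seed,
  in at least 8 of 10 seeds. Requiring all ten would test the luck of the
  effect draw, not the sampler.
- **Degenerate inputs.** Monomorphic markers are excluded from LD blocks and
  from all VanRaden constructions (p ∈ (0,1) is a precondition); empty
  nonblocked sets make the combined two-matrix models degrade to the
  haplotype-only model with an explicit error; non-PSD matrices beyond
  tolerance are rejected with advice to use the (default-off, logged)
  `grm_ridge`-style rescue only in tiny test scenarios.

## Known limitations

- The AI-REML implementation is dense (O(n³) per iteration); it is meant for
  panels up to a few thousand individuals, not national evaluations.
- One trait at a time; no multi-trait REML, dominance, or G×E components.
- Phasing and imputation are out of scope: inputs must be phased and
  missing-free downstream of QC.
- The two-component model shares one residual; no heterogeneous-variance
  extensions.
- Percent-change SEs pool fold and repeat variation; folds within a repeat
  are not independent, so these SEs are descriptive rather than exact.
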