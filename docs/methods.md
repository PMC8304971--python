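# Methods

## Statistical model

The scan operates on a working phenotype `y_adj = y − 2·PTA`, where `y` is
a yield deviation (fixed non-genetic effects already removed by the
upstream evaluation system) and PTA is the predicted transmitting ability —
half the estimated breeding value — from routine genetic evaluation.
Writing the two-locus model as

    y − 2·PTA = μ + X_g g + a + e,

twice the PTA is a plug-in estimate of the additive polygenic value `a`, so
the adjustment delivers most of the stratification control of the mixed
model var(y) = σ²_a Z A Z′ + σ²_e I without forming or inverting that
covariance matrix. This approximation (AGLS) is what makes an all-pairs
scan computationally possible; its cost is that the residual after
adjustment retains a fraction (1 − reliability) of the polygenic variance,
which simply inflates `v²` and is absorbed by the t-test.

Each pair is fitted in the **cell-means parameterization**: one mean per
occupied two-locus genotype cell. The mean-plus-effects form μ + g is rank
deficient; cell means is the canonical full-rank resolution, gives the same
fitted values and contrasts, and makes X′X diagonal (the cell counts), so a
pair's fit reduces to per-cell counts, sums and sums of squares — three
`bincount` passes. The residual variance is `v² = RSS/(n−k)` with `k` the
number of occupied cells and `n` the pairwise complete-case count
(individuals missing either genotype are dropped for that pair only).

## Interaction contrasts

The four interaction components use per-locus basis contrasts
`w_a = (−1, 0, 1)` (additive: homozygote difference) and
`w_d = (−½, 1, −½)` (dominance: heterozygote deviation), Cockerham-style.
The nine-cell contrast vector for component `j` is the outer product of the
two per-locus vectors; each sums to zero and the four are mutually
orthogonal under equal cell counts. The t statistic `|L|/√var(L)` is
invariant to rescaling of the contrast vector, so any standard
normalization of `w_a`, `w_d` yields identical tests. A contrast is
estimable only if every cell it weights is occupied; non-estimable
contrasts are reported as absent (not as p = 1), and a pair ranks by the
maximum log₁₀(1/p) over its estimable contrasts with the arg-max type
attributed (ties broken in AA, AD, DA, DD order, then by map position).

Degrees of freedom are `n − k`; at the sample sizes the scan is meant for
(thousands and up) the Student-t is effectively normal.

## Extreme significance scores

Two-sided p-values underflow IEEE doubles near t ≈ 37.6 (large df), where
log₁₀(1/p) ≈ 308. Below the underflow bound the score is continued by the
empirical power law

    log10(1/p) = max(308, 0.2416 · t^1.9713).

At the boundary the power law gives 307.8 versus the exact normal-tail
value 308.7 (0.3% apart). The floor at 308 — the representability bound —
keeps the score monotone nondecreasing across the switch; without it the
power-law branch starts ~0.5 units below the exact branch's endpoint. The
constants (0.2416, 1.9713) are taken as given; the power law is a large-df
calibration and is applied only on the underflow branch, where the exact
value is uncomputable in double precision anyway.

## Thresholds and accounting

Genome-wide significance uses Bonferroni: per-test threshold α / n_tests
with n_tests = C(n_SNPs, 2) × 4 effect types × n_traits. For the reference
design of 76,109 SNPs and 8 traits this is 92,680,060,352 tests and a
log₁₀(1/p) threshold of 12.27 at α = 0.05. The trait count is a
configuration value (default 8) because a multi-trait analysis corrects
across all traits scanned, not just those reported. Intra-chromosome
pairs are counted per chromosome as C(m_c, 2); the intra-4 Mb flag uses a
strict `|pos1 − pos2| < 4,000,000` same-chromosome distance.

## Synthetic data generator

The generator emulates what the adjustment and the tests rely on, not a
full livestock pedigree:

* **Genotypes.** Per chromosome, counted-allele frequencies follow a
  reflecting random walk (step SD 0.015) inside `maf_range`
  (default [0.05, 0.5]); haplotype alleles follow a first-order Markov
  chain whose conditional probabilities reproduce both the marginal
  frequency of every SNP and a target adjacent-SNP correlation `ld_rho`
  exactly (up to clipping, which the slowly varying frequencies make
  rare — two binary variables can only be strongly correlated when their
  frequencies are similar). Two independent haplotypes per individual sum
  to 0/1/2 (Hardy–Weinberg, no inbreeding). Default 30 chromosomes
  (labelled 1–29 and X, X treated as autosomal) of 100 Mb, the bovine
  autosome scale.
* **Polygenic layer.** Half-sib families: sire breeding values contribute
  σ²_a/4, a Mendelian/dam term the remaining 3σ²_a/4. Defaults
  σ²_a = 0.5, σ²_e = 1.0 give heritability ≈ 0.33, typical of a yield
  trait. The PTA proxy is `r²·a/2` plus noise scaled so
  corr(PTA, a/2)² equals the configured reliability (default 0.6, a
  first-lactation-cow figure); reliability 1 makes y − 2·PTA remove `a`
  exactly.
* **Planted pairs.** A planted pair's 3×3 genotypic-value surface is
  `effect_size · σ_e · outer(w_u, w_v)` for its type, so effect sizes are
  in residual-SD units and the surface has zero marginal additive and
  dominance main effects at both loci — the planted signal is purely
  epistatic by construction.

What the generator does **not** emulate: real pedigree depth and
herd-year-season structure (only the PTA-correctable polygenic part of it),
coalescent-grade LD decay, X-specific dosage in males, and genotyping or
imputation error. Passing tests therefore demonstrate the statistical
machinery — calibration, estimability handling, ranking, power at planted
effects — not robustness to those real-data features.

## Validation studies

`episcan.studies` packages two procedures used by the test suite and the
acceptance script:

* **Null calibration** — 10,000 independent Hardy–Weinberg SNP pairs
  (n = 1,000, MAF uniform on [0.05, 0.5]) with fresh N(0, 1) phenotypes.
  Under normal errors every estimable contrast statistic is exactly
  Student-t, so pooled p-values are checked for uniformity
  (Kolmogorov–Smirnov) and the rejection rate at α′ = 10⁻⁴ against its
  binomial band. Many AA/DD contrasts at rare-by-rare pairs are
  non-estimable at this n (empty double-homozygote cells) and are excluded
  rather than imputed.
* **Planted-pair recovery** — one pair of a given type at 0.5 residual-SD,
  n = 5,000, 200 SNPs on 10 chromosomes, full scan, top-1 check. The pair
  is planted at the SNP on each of two different chromosomes whose realized
  MAF is nearest 0.3: the interaction contrasts weight double-homozygote
  cells, whose expected counts scale as the product of squared allele
  frequencies, so a rare-by-rare pair is non-estimable or powerless at any
  realistic n and a power study conventionally plants at common variants.

Problem sizes in the studies (10,000 null pairs; 20 seeds per power study)
were chosen as the smallest giving stable Monte-Carlo answers for the
quantities checked.

## Numerical and design choices

* Pair ranking is **pair-level**, not contrast-level: each top-K slot is a
  pair carrying its best effect type, which matches the one-type-per-pair
  accounting of the summary tables.
* Tie-breaking everywhere is deterministic: descending log₁₀(1/p), then
  (chrom1, pos1, chrom2, pos2) with chromosomes ordered 1–29 then X.
* `v²` is floored at 0 against negative round-off; `var(L) = 0` (e.g. a
  saturated fit) marks the contrast non-estimable rather than producing an
  infinite t.
* Missing genotypes are kept in the panel and handled per pair
  (complete-case), which is what a cell-means fit does naturally; the MAF
  filter (default floor 0.05) is applied at load time.
* The scan kernel evaluates blocks of pairs from shared `bincount`
  sufficient statistics (no per-pair design matrices); the streaming top-K
  pool is pruned whenever it exceeds 4K candidates and provably equals the
  full-sort top-K because pruning only ever discards pairs ranked below K.

## Known limitations

* The AGLS adjustment under-corrects when PTA reliability is low; the
  residual polygenic variance inflates `v²` uniformly, costing power but
  not type-I calibration in the simulated (unstructured-residual) setting.
  With real genetic structure, low-reliability PTA can leave confounding.
* No FDR or permutation thresholds; Bonferroni only.
* Single-node scanning; the block kernel is vectorized but not distributed,
  so full 76k-SNP panels (≈3 × 10⁹ pairs) are out of its intended range.
* Chord and Manhattan plots are idiomatic re-implementations, not
  replications of any specific external plotting tool's layout.
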