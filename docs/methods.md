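# Methods

This note documents the models, conventions and design choices behind
`rangexpand`, in the spirit of a methods appendix: what each stage
computes, why the defaults are what they are, and what the synthetic
generators do and do not emulate.

## Genotype container and VCF handling

Genotypes are alt-allele dosages in {0, 1, 2} with −1 for missing, in a
samples × SNPs `int8` matrix. Only biallelic SNPs are represented:
indels and multiallelic records are skipped on load (counted in the
log), and half-calls such as `./1` become missing — a deliberate
conservative choice, since a half-call carries allele information but
not a diploid dosage. Positions are 1-based and must be strictly
increasing within a chromosome. Reading goes through cyvcf2; writing
emits a minimal VCFv4.2 with a GT-only FORMAT, which round-trips
losslessly through the reader.

## SNP filtering

The filter stages mirror the vcftools/PLINK conventions they stand in
for, and all of them are order-preserving, idempotent subset operations:

* **MAF bounds** (default 0.02–0.98) apply to the *unfolded* alt-allele
  frequency, matching the `--maf/--max-maf` flag semantics; with the
  symmetric 0.02/0.98 pair this is equivalent to a folded-MAF cut.
* **Missingness** has two modes — an absolute missing-call count
  (default 0, i.e. no missing data tolerated) and a missing-rate
  threshold (0.9 for the more permissive joint-panel stage) — selected
  by whichever threshold is supplied.
* **Distance thinning** (50 bp) is the greedy left-to-right scan of
  `vcftools --thin`: a SNP is kept iff it lies strictly more than the
  threshold from the last *kept* SNP on the same chromosome, so the
  first SNP of each crowded run survives.
* **Hardy–Weinberg** uses the exact conditional test on genotype counts
  (no mid-p): given the allele counts, every heterozygote count with the
  right parity gets probability ∝ n!/(n_AA! n_Aa! n_aa!) · 2^{n_Aa},
  and the p-value sums the configurations no more likely than the
  observed one. SNPs with p < 1e-10 are removed (PLINK `--hwe`
  semantics). Monomorphic SNPs have a single configuration and p = 1.
* **LD pruning** slides a window of 50 SNPs by steps of 5; within a
  window, any retained pair whose squared Pearson correlation of
  dosages exceeds r² (0.9, or 0.5 for the PCA panel) loses its
  later-positioned member. Correlations use composite (genotype) r²,
  not haplotype r² — phase is unavailable in the diploid calls — and
  missing entries are mean-imputed *only* inside the correlation;
  the matrix itself is untouched. Zero-variance SNPs correlate with
  nothing and are never removed by this stage.

## PCA and projection

Standardization follows the EIGENSTRAT/SNPRelate convention: entry
(g − 2p)/√(2p(1−p)) with p the training alt-allele frequency, missing
entries set to 0 after centering, and monomorphic SNPs dropped (their
standardization is undefined). The genetic relationship matrix
X Xᵀ/m is eigendecomposed (implemented via SVD of X); eigenvalues are
reported on the GRM scale, scores are X·V (eigenvector × √(m·λ)), and
SNP loadings are the orthonormal right singular vectors. Whether the
study's own PCA used covariance or correlation of standardized
genotypes is not stated in its methods; the GRM convention is adopted
and documented here. Component signs are fixed deterministically
(largest-|loading| entry positive) so results are stable across runs
and BLAS builds.

Projection standardizes new samples with the *training* frequencies and
multiplies by the stored loadings; projecting the training panel
reproduces its scores exactly, and two identical samples always receive
identical scores. SNP sets are matched by (chrom, pos, ref, alt), and a
mismatch fails with the offending SNPs listed rather than silently
subsetting.

## Structure post-processing

* **Assignment**: a sample joins population k iff q_k strictly exceeds
  the 0.8 threshold; a row at exactly 0.8 is admixed. With any
  threshold ≥ 0.5 at most one population can qualify.
* **Ancestry-location R²** is the ANOVA-style 1 − SSW/SST over ancestry
  rows, with a label-permutation p-value using the add-one rule (the
  observed statistic counts itself, so p is never 0). The degenerate
  all-rows-identical case (SST = 0) is defined as R² = 0. This is an
  equivalent of the published ObStruct statistic rather than a verbatim
  reproduction; only R² and P are consumed downstream.
* **Evanno ΔK** = mean over replicates of |L(K+1) − 2L(K) + L(K−1)|
  divided by the replicate standard deviation of L(K); endpoints are
  undefined and omitted, and a zero replicate sd yields ∞ with a
  warning rather than an error. ΔK is invariant to adding a constant
  to all log-likelihoods.
* **Trees**: identity-by-state dissimilarity d(a,b) = mean over
  jointly-called SNPs of |g_a − g_b|/2, clustered by UPGMA (scipy
  average linkage) and serialized to newick with ultrametric branch
  lengths (merge height/2 minus child height). Children are ordered by
  smallest leaf id, so the output is invariant to input sample order up
  to this canonical rotation.

## Weir–Cockerham F_ST and the outlier scan

The diploid estimator computes, per SNP, the variance components
a (among populations), b (among individuals within populations) and
c (within individuals) from population sample sizes, allele frequencies
and observed heterozygosities. Per-SNP θ = a/(a+b+c); the overall θ is
the ratio of summed components, *not* the mean of per-SNP ratios (the
two differ, and the test suite pins this on a two-SNP example). A SNP
is undefined — excluded from the sums and reported as NaN — when any
population has fewer than two called diploids or the total variance is
zero. θ is invariant to swapping ref and alt alleles, and the estimator
is slightly negatively biased around 0, so small negative values on
undifferentiated data are expected, not errors.

The outlier scan replaces a Bayesian model-based scan (whose
reversible-jump MCMC is out of scope here) with a desk-scale
permutation test on the same statistic: population labels are permuted
n_perm times (default 999), the permuted per-SNP θ values from *all*
SNPs are pooled into a single null distribution — stabilizing the tail
at modest n_perm — and each SNP's empirical p-value uses the add-one
rule against that pool. Benjamini–Hochberg at FDR 1% selects the
candidate set. Two consequences worth knowing: p-value resolution is
1/(n_perm · m + 1), so even 199 permutations on a 2000-SNP panel
resolve far below any reasonable FDR cut; and the null is *panmixia*,
so on a panel with genuine background differentiation every SNP is
shifted relative to the permuted null and many SNPs will be flagged —
the scan answers "which SNPs differ from no structure", and is
calibrated for outlier detection on a rare-filtered panel whose
background differentiation is near zero.

## Copy-number profiling

CN[s, o] = depth[s, o] / normalizer[s], where the normalizer is the
median of that sample's per-ORF median depths (the table's column
median). The study's phrase "median read depth for that sample" does
not distinguish per-base from per-ORF medians; the table-median reading
keeps the statistic self-contained, and a pre-computed normalizer
column (e.g. a per-base genome median) or an ORF exclusion list
(plasmid, mitochondrial) can override it. CN is invariant to rescaling
a sample's whole depth row, and the median normalizer ignores
corruption of any minority of ORFs.

Population medians use the plain midpoint convention for even counts.
Presence (median CN ≥ 0.5 in either population) and enrichment
(focal median ≥ 2 × other median) are both inclusive boundaries;
an ORF absent from the other population (median 0) but present in the
focal one is enriched with an infinite factor. The depleted direction
is computable symmetrically.

`enrichment_scan` accepts an optional `resolution` (recommended 0.5
when true copy numbers are integers): population medians are rounded
to that granularity before the presence and ratio tests. The rationale
is that a genuinely 2×-amplified ORF has a *true* factor sitting
exactly on the inclusive ≥ 2 boundary, so with un-rounded medians the
call would be decided by estimator noise symmetric around the
boundary; half-copy rounding makes the decision reflect the underlying
integer copy number (copy numbers are reported at half-copy
granularity in practice — e.g. a plasmid at 11.5). The default leaves
medians un-rounded.

The 2μ plasmid is called per sample as the median CN over its ORFs,
present iff that median reaches the 0.5 presence threshold; simulated
plasmids at true CN 47 and 11.5 are recovered within 10%.

## LTR census

Coordinates are 1-based inclusive internally; BED input/output converts
explicitly (the package's 9-column BED adds the consensus span so a
RepeatMasker `.out` → BED round trip is lossless). For each LTR hit the
5-bp flanks are extracted on both sides — reverse-strand hits are
reverse-complemented with the flanks swapped so the TSD is reported in
element orientation. A TSD is *invalid* only when a flank window leaves
the contig (edge) or contains an N; the two 5-mers are **not** required
to be identical, since post-insertion mutation can break identity — an
`identical` flag is recorded for downstream filtering instead.

Completeness: a hit is full iff its matched consensus span covers at
least 90% of the consensus length (inclusive; configurable — the
source analyses say "partial" without a number). Context: an LTR is
element-associated iff a same-superfamily internal-region hit starts
within 50 bp of its inner boundary, or a second same-superfamily LTR
lies within 7 kb with an internal hit between; the gap and span
defaults reflect Ty element anatomy (LTRs ~250–370 bp, internal region
~4.5 kb) and are configurable. Ty1, Ty2 and Ty1/2 share the copia-like
superfamily for this purpose.

The catalogue admits only valid-TSD, full-length records. The sharing
key is (family, upstream 5-mer, downstream 5-mer, LTR sequence) — a
TSD-only mode drops the sequence — and equal keys collapse to one
representative, preferring reference-panel strains (so ancestral
insertions are attributed to the pre-existing panel), then the
lexicographically smallest strain id. Within-strain duplicates collapse
under the same key as cross-strain ones. A representative is *unique*
to the focal population iff no strain carrying its key is in the
reference panel; otherwise it is an ancestral shared insertion.
Deduplication is order-independent and idempotent.

## Synthetic generators

All generators are pure functions of (config, seed): one
`numpy.random.Generator` per call, no global state, byte-identical
outputs under identical inputs.

* **Genotype panels** use the Balding–Nichols model — ancestral
  frequencies uniform on (0.05, 0.95), population frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F per population (F = 0 is handled
  as exact equality), per-sample ancestry one-hot or symmetric
  Dirichlet, genotypes Binomial(2, Σ q_k p_k). Balding–Nichols is
  chosen because its planted F is what the Weir–Cockerham estimator
  must recover; the admixture Dirichlet is a testing device, not a
  demographic claim. Defaults (2 × 50 diploids, 2000 SNPs, F = 0.05)
  mirror the differentiation scale the pipeline is designed around
  (overall F_ST below 0.05 between the focal populations).
* **Outlier planting** redraws chosen SNPs with population frequencies
  p and p + δ (clipped to [0.02, 0.98]) and records the indices.
* **Depth tables** emulate *median* read depth per ORF: each of
  `orf_length` (default 300) base positions draws
  NegBin(mean = mean_depth · CN, size = dispersion 10) and the entry is
  their median; `orf_length = 1` gives a single NB draw. The median-of-
  bases form is what an ORF-level depth table derived from a pileup
  actually contains, and it is what gives the CN ratio its precision
  (a single NB draw at 50×/size 10 would carry ~0.35 CN-units of noise,
  which no ORF-level analysis of medians exhibits). Entries are exactly
  0 at CN 0 — no mismapping noise, because the downstream statistic
  uses medians that are insensitive to such a tail. Not emulated:
  GC/mappability bias, correlated per-base noise, paralog
  cross-mapping; recovery results on these tables therefore bound the
  statistic's *intrinsic* noise, not mapping artefacts.
* **Contigs** plant LTR insertions as TSD + LTR + TSD in random
  background sequence, one case per contig: normal solo, full element
  (LTR–internal–LTR inside one TSD pair), contig-edge (< 5 bp of
  upstream flank), N-in-flank, truncated (first 100 bp of the
  consensus), and byte-identical shared insertions across ≥ 2 strains.
  TSDs are drawn from non-homopolymer 5-mers to avoid accidental flank
  matches. The generator also emits the RepeatMasker-style hit table
  (the screening tool itself is out of scope, so its output is an
  input here) and a truth table of expected census outcomes.
* **Q-matrices** are Dirichlet draws, optionally with location-specific
  means; **ln P(K) tables** have a piecewise-linear mean with a slope
  break at the true K plus Gaussian replicate noise.

## Pipeline and reproducibility

`rangexpand run` executes stages in dependency order from one YAML
config; each run writes a manifest with the config hash, per-stage
seeds and the SHA-256 of every output, and identical config + seed
reproduces byte-identical files. The global seed expands to per-stage
seeds as (seed · 10007 + stage_index) mod 2³¹, so any stage is
reproducible in isolation. Config validation fails fast naming the
missing field.

## Verification scale

The test-suite and acceptance-script problem sizes are the documented
study conditions of the generators: F_ST recovery on 2 × 50 diploids ×
2000 SNPs over 10 seeds; outlier error control and power on F = 0
panels of the same size with 10 planted δ = 0.8 SNPs (199 permutations
— p-value resolution ~3 × 10⁻⁶ against the pooled null, ample for an
FDR-1% cut); PCA projection on 100 replicates of 2 × 25 diploids × 300
SNPs at F = 0.1; CNV recovery on 10 tables of 40 samples × 500 ORFs at
50×; the LTR census on the six-case genome over 10 seeds; and 200-seed
uniformity checks for permutation p-values.

## Known limitations

* Counts printed in the source study (candidate SNPs, enriched-ORF
  totals, Ty census numbers) depend on its real genomes and repeat
  library and are not reproduced here; the package verifies the
  *procedures* on ground-truth synthetic data instead.
* The permutation outlier scan is a stand-in for a Bayesian
  genome-scan model: it shares the statistic and the FDR criterion but
  not the prior-odds machinery, and its null is panmixia (see above).
* Haplotype-based LD, genotype imputation beyond the LD-internal mean,
  multiallelic sites, and GO-term enrichment of the ORF lists are out
  of scope; the CNV report writes the enriched ORF list that an
  external GO tool would consume.
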