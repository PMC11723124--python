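# Methods

This note documents the statistical models behind `radpop`, the choices
made where the design was genuinely open, and the limits of what the
simulator-based tests demonstrate.

## Genotype model and filtering

Genotypes are stored as alternate-allele dosage plus call ploidy, so a
VCF mixing `0/1`, `0/1/1` and `0/1/1/1` calls loses no information.
Missingness is a distinct sentinel and is never conflated with dosage 0;
unknown DP/GQ/AD use the same sentinel. Coordinates stay 1-based (VCF
convention) internally.

The filter chain mirrors standard RAD-seq SNP cleaning:

* **Per-call filter** — a call passes only with DP > `min_dp` (default
  10) *and* GQ > `min_gq` (default 20); both inequalities are strict.
  Calls with unknown DP or GQ fail, deliberately conservative: a
  depth/quality filter is meaningless for calls that carry neither.
* **Call rate** — loci genotyped in at least a fraction `min_rate`
  (default 0.95) of samples are kept. The default is exposed as
  configuration because reasonable pipelines use anything from 0.90 to
  0.95.
* **Depth normality** — each locus' mean depth is compared with the
  across-locus distribution of such means; loci outside
  mean ± `k_sd`·sd (default k = 2) are removed as poorly covered or
  oversaturated (likely repeat-collapsed) loci. Because mean and sd are
  re-estimated from the surviving loci on each call, a second
  application can trim slightly further — this filter is a statistical
  outlier rule, not a fixed threshold, and is intentionally not
  idempotent. With zero spread all loci are kept and a warning is
  logged.
* **Biallelic SNPs** — downstream statistics assume exactly two
  single-base alleles; everything else is dropped.

Filters never mutate retained calls and always return new matrices.

## Ploidy from allele balance

At a heterozygous site in a sample of ploidy *m* with alt dosage *d*, the
alt-read count is Binomial(DP, μ_d) with

    μ_d = (d/m)(1 − e) + (1 − d/m) e,

where *e* is the per-read miscall rate (default 0.01). Each candidate
ploidy *m* is fit as a mixture over components d = 1..m−1 with *fixed*
means μ_d; only the mixture weights are free, estimated by EM to a
relative log-likelihood tolerance of 1e-8 (≤ 500 iterations; a
non-converged fit is flagged and the best-so-far returned). Candidates
are compared by

    BIC = −2 logL + (m − 2) ln(n_sites),

counting m − 2 free weights. Selection details:

* Sites qualify when heterozygous by GT (0 < dosage < call ploidy), with
  known allele depths and ref+alt ≥ 10 reads. GT-based site selection is
  used even though the caller's GT ploidy may be wrong for the sample;
  the mixture over allele-balance ratios is what corrects the call.
* Fractions outside [0.1, 0.9] are trimmed before fitting; they are
  dominated by sequencing-error leakage from homozygous genotypes, which
  the mixture does not model.
* Diploid/tetraploid guard: both models contain a 1/2 component, so the
  tetraploid model can only win on noise. It is accepted over the
  diploid model only when its 1/4 + 3/4 components carry ≥ 0.1 total
  weight; otherwise the diploid call stands.
* A call is low-confidence when the best-vs-second BIC gap is < 2 or
  fewer than `min_het_sites` (default 200) sites were usable; below the
  site minimum the ploidy is reported as undetermined rather than
  guessed.

The candidate set defaults to {2, 3, 4} and is configurable (some taxa
reach 8×–10×). In simulation, recovery is ≥ 95% for 2n/3n/4n at depth
≥ 30 with ≥ 1000 heterozygous sites, and the BIC gap grows with depth.

## Diversity, Fst, IBD

**Ho/Hs/FIS.** Per locus with *n* genotyped individuals and alt
frequency *p* (computed as Σ dosage / Σ call-ploidy, so polyploid calls
contribute correctly to frequencies): Ho is the observed heterozygote
fraction and

    Hs = n/(n−1) · (1 − p² − q² − Ho/(2n))

is Nei's small-sample gene diversity. Population values are locus means
and FIS = 1 − mean(Ho)/mean(Hs) (ratio of means, the hierfstat-style
convention). Monomorphic-only populations report Hs = 0 and FIS
undefined (NaN). Hs assumes diploid sampling; for tetraploid samples Ho
can legitimately exceed Hs, producing negative FIS — diversity
statistics on polyploids should be interpreted with that caveat or run
on the diploid subset.

**Fst.** The default estimator is Weir & Cockerham's (1984) θ: per-locus
variance components a (among populations), b (among individuals within
populations) and c (within individuals) for two demes, combined as
Σa / Σ(a+b+c) over loci (ratio of sums). Monomorphic loci contribute
nothing and are skipped. Small negative estimates are reported as-is, as
usual for unbiased estimators. The alternative `nei87` estimator uses
(Ht' − Hs)/Ht' with Nei's small-sample Hs and the deme-number correction
Dst' = r/(r−1)(Ht − Hs); without that correction a two-deme Gst
estimates roughly F/2 rather than F. The two estimators agree within
0.03 on balanced simulations with n ≥ 30 per population.

**IBD.** For each diploid pair the observed counts of IBS states 0/1/2
over shared non-missing loci are compared with their expectations given
the per-locus alt frequency p (q = 1 − p):

| state | IBD = 0            | IBD = 1   | IBD = 2 |
|-------|--------------------|-----------|---------|
| IBS 0 | 2p²q²              | 0         | 0       |
| IBS 1 | 4p³q + 4pq³        | 2pq       | 0       |
| IBS 2 | p⁴ + q⁴ + 4p²q²    | p² + q²   | 1       |

Solving top-down yields (k0, k1, k2), truncated to [0, 1] and
renormalized; PI_HAT = k1/2 + k2. Frequencies default to the whole
genotyped panel (the PLINK convention); a per-population mode restricts
both the frequency panel and the estimated pairs to within-population
comparisons. PLINK's finite-sample bias corrections are not applied; at
panel sizes ≥ 40 the residual bias for unrelated pairs is well below the
0.1 screening threshold. Monomorphic loci are uninformative and dropped;
pairs sharing fewer than 50 loci are flagged low-confidence. Samples
with non-diploid calls are excluded with a warning — the IBS inversion
is a diploid argument.

## Structure

**PCA.** Missing dosages are imputed with the locus mean (which leaves
locus means unchanged), columns are centered (optionally unit-scaled)
and the SVD taken. Component signs are fixed by making each component's
largest-magnitude loading positive, so results are platform-stable.
Explained-variance fractions are relative to total dosage variance.

**K selection.** K-means (best of 20 k-means++ starts, fixed seed) for
K = 1..k_max over the PC scores, scored by

    BIC(K) = n ln(WSS_K / n) + K ln(n).

The chosen K is the smallest K with BIC(K+1) > BIC(K); a strictly
decreasing curve returns k_max with a warning. This BIC behaves well
when scores span many axes (the high-dimensional noise floor makes
over-splitting unprofitable); feeding it only 2–3 components makes the
curve decrease indefinitely. Analyses here retain ~min(40, n−1)
components for K selection.

**DAPC.** PCA reduction to `n_pca` axes — auto-selected as the smallest
number covering 80% of variance, capped at n/3 and at
n − n_groups − 1 to guard against overfitting — followed by linear
discriminant analysis on the group labels. Memberships are LDA posterior
probabilities. Per-locus loadings are the squared discriminant
coefficients back-projected through the PC basis, normalized to sum to 1
per axis. Discriminating SNPs are selected by 2-means clustering of the
loading *magnitude* (square root of the squared-coefficient loading —
a variance-stabilizing scale; clustering the raw squared loadings lets a
handful of extreme loci absorb the upper cluster and misses moderate
signal). A quantile rule is available as an alternative.

**UPGMA.** Pairwise Euclidean distances on the imputed dosage matrix;
average-linkage agglomeration with ultrametric node heights (half the
merge distance); ties broken deterministically by the lexicographically
smallest leaf-label pair. Bootstrap support resamples loci (not samples)
with replacement and reports the percentage of replicates containing
each original clade; supports appear as internal-node labels in the
Newick output.

## Variant-effect classification

A deliberately small annotator: every biallelic SNP receives exactly one
category by most-severe-first precedence — stop_gained/stop_lost >
missense > synonymous > 5'/3' UTR > intron > intragenic (inside a gene
but in no transcript feature) > upstream/downstream (within 5 kb,
strand-aware; the common annotator default) > intergenic. Coding effects
substitute the alt base into the strand-corrected codon and translate
with the standard genetic code. Transcripts whose CDS length is not a
multiple of three are dropped with a warning (the model assumes phase
0). A VCF REF base disagreeing with the FASTA is an error, not a silent
re-anchor. Splice-site classes, indel/MNV effects and multi-effect
reporting are out of scope.

## The simulator

`simdata` generates the structures the analyses are meant to detect:

* **Divergence**: per-locus ancestral frequency p ~ Uniform(0.05, 0.95);
  population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) (Balding–Nichols)
  with per-population divergence F.
* **Inbreeding**: with probability FIS an individual's genotype at a
  locus is fully autozygous (dosage 0 or m with probability q, p);
  otherwise Binomial(m, p). This mixture yields the target FIS exactly
  in expectation, unlike approximations via selfing generations.
* **Families**: half-sib offspring of one diploid mother — one gamete
  from the mother's genotype, one from the population frequencies —
  giving expected PI_HAT 0.5 (mother–offspring) and 0.25 (half-sibs).
* **Trait contrast**: a chosen set of loci gets frequency p in one
  phenotype group and min(1, p + δ) in the other. Because of the cap,
  high-frequency trait loci carry a realized gap smaller than δ; recall
  of planted loci is bounded below 100% by construction.
* **Reads**: DP ~ NegativeBinomial(mean 60, dispersion 10); alt reads ~
  Binomial(DP, μ_d); sequencing error is folded into μ_d analytically
  rather than simulated per-read. GQ is the phred gap between the two
  best binomial genotype likelihoods (capped at 99), so DP/GQ filters
  see a realistic joint distribution. GT is emitted at the true ploidy.

Defaults (depth 60 ± NB dispersion 10, error 0.01, 5000 loci and 30–60
samples for estimator-recovery experiments, 2000 loci for ploidy
recovery) reflect a well-powered RAD-seq collection study; recovery
tests use these sizes with fixed seeds. Not modelled: linkage
disequilibrium, RAD locus/allele dropout, reference-sequence emission,
null alleles. Passing recovery tests therefore demonstrates estimator
correctness under the idealized generative model, not robustness to
those real-data artifacts.

## Pipeline

`pipeline.run_pipeline` fixes the stage order (filter → ploidy →
diversity/Fst/IBD → PCA/K/DAPC/tree → optional annotation), derives all
randomness from one seed, and writes a manifest (config, input SHA-256
checksums, per-stage row counts) so repeated runs are bit-identical. A
stage failure aborts with the stage name, preserving partial outputs.

## Known limitations

* Diversity statistics use diploid sampling theory; polyploid samples
  are handled exactly in allele frequencies but approximately in Hs.
* The IBD inversion assumes unlinked loci and panel-estimated
  frequencies; within small or structured panels PI_HAT is inflated for
  all pairs.
* The UPGMA implementation is O(n³) — fine for hundreds of samples, not
  tens of thousands.
* The annotator indexes one transcript model per mRNA feature and
  assumes phase-0 CDS; curated genome annotations with trans-splicing or
  phase offsets are out of scope.
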