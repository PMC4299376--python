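# Methods

## The measurement model

Allelic expression (AE) is measured as an allelic ratio — the A-allele
fraction of signal — at transcribed SNPs, in parallel for genomic DNA and
cDNA from the same individual. gDNA at a heterozygous site carries exactly
one copy of each allele, so it serves as the technical 50:50 reference for
that SNP on that platform. The published array pipelines defer their
normalization details to platform-specific procedures; here we adopt the
simplest transformation that captures the stated intent and is exactly
testable: a **per-SNP affine correction** that moves the mean gDNA
heterozygote ratio to 0.5 and is applied unchanged to the cDNA ratios of
the same SNP. SNPs with no gDNA heterozygote cannot be calibrated and are
excluded with a reason code rather than silently dropped.

The core statistic is the **Δ het ratio**, Δ = cDNA − gDNA after
normalization, defined only at heterozygous sites. Its sign initially
carries the A-allele orientation; phase alignment re-orients it so that
positive means haplotype 1 (the phased reference chromosome) is
over-expressed, making Δ comparable across SNPs of a transcript regardless
of which allele letter each haplotype carries. Transcript-level profiles
are the unweighted mean over a transcript's informative SNPs with a
minimum of three ("average intensity signal" aggregation; no intensity
weighting). Regions covered by more than one gene are maskable; when a
mask removes SNPs the profile is flagged *partial-length*. Only expressed
transcripts enter mapping (median FPKM > 0.01), and only the most
expressed isoform per gene; FPKM ties break to the longest transcript and
then the lexicographically smallest id so the selection is deterministic.

## Association model

Candidate SNPs within ±500 kb of the transcript with MAF ≥ 0.05 are coded
on phased chromosomes (het with B on haplotype 1 → 0, homozygote → 1, het
with A on haplotype 1 → 2). Under an additive cis effect the oriented
Δ equals −e, 0, +e at codes 0, 1, 2, so we test the OLS slope of Δ on the
code with a two-sided t-test, computed through the slope–correlation
identity for speed (the two are algebraically identical). Homozygotes are
retained at code 1 — they carry the null level of the regression line.
Zero-variance Δ vectors are recorded at P = 1 and flagged degenerate;
candidates with fewer than two distinct codes are skipped with a reason.

**Permutation FDR.** For each permutation, sample labels of every locus's
Δ vector are shuffled (genotypes fixed, preserving LD structure within the
locus) and the locus-minimum P recomputed. The discovery threshold is the
largest observed locus-minimum P at which

    FDR(p) = [mean permutation count of locus minima ≤ p] / [observed count ≤ p]

stays at or below the target (default 1%); because loci are mapped at
min P *strictly below* the cutoff, the reported cutoff is the next float
above the largest qualifying observed P. Null permutations are pooled
across loci, which we state explicitly as our empirical-FDR definition.
If no P qualifies the threshold is 0 and a warning is attached. Mapped
loci retain their **top-10 SNPs** by P, with ties broken by absolute
distance to the transcript's nearest edge and then position. Distances
are reported two ways: signed distance from the TSS for summaries, and
nearest-edge distance for the range classification (proximal =
intragenic, distal = up to 200 kb, long-range = strictly beyond 200 kb;
only the long-range boundary and the intragenic-proximal identification
are externally fixed — the proximal/distal split at distance 0 is our
choice).

## Synthetic data: what it emulates and what it does not

The generator provides the study conditions for every test. Haplotypes are
drawn per locus as a single LD block under a **first-order copying
process**: SNP j copies SNP j−1's allele on the same haplotype with
probability ρ, otherwise redraws at its own MAF (uniform in [0.05, 0.5]).
This produces tunable pairwise r² (≈ ρ² between adjacent SNPs at equal
frequencies, decaying with distance) and therefore realistic ranked-SNP
ambiguity — the property the top-10 retention question depends on — without
a coalescent's unbounded variance. SNPs whose realized MAF falls below the
floor are redrawn in place (the chain continues from the accepted column),
with an explicit failure after bounded retries. Defaults are the standard
fixture: 100 samples, 200 loci, 30 SNPs per block, ρ = 0.9, additive
effect 0.15 Δ-het-ratio units, measurement noise SD 0.05 (cDNA) and 0.01
(gDNA), per-SNP technical offsets SD 0.02 shared between assays (removed by
normalization), six transcribed SNPs per transcript. Each generator draws
from its own RNG stream derived from the master seed, so generators can be
added without shifting one another's draws, and fixed seeds give
bit-identical output.

Not emulated: array chemistry and dye bias, genotype/imputation
uncertainty, population demography, splicing and 3′-usage variation,
batch structure, mapping bias in sequencing readouts. Passing tests
therefore demonstrate the statistical machinery is correct under the
declared generative model, not that the pipeline is robust to platform
artifacts absent from that model.

The motif landscape plants PWM consensus instances (width 8 by default,
dominant base probability 0.85) across 31-nt windows with the variant
inside the motif; the weak allele takes the matrix's least-likely base at
that position. For activator-labeled motifs the higher-scoring allele lands
on the over-expressed haplotype with probability `p_act`; repressor-labeled
motifs are mirrored (probability `1 − p_act`); neutral motifs sit at 0.5.
ChIP depths are linear in the count of over-expressed-haplotype alleles
(inverted for repressor sites) with binomially biased allelic counts at
heterozygous sites. Perturbation tables give TF-driven transcripts an
imbalance (0.2) that shrinks by a planted factor (1.6) under inhibition in
heterozygous individuals only, in four conditions mirroring an
activation / inhibition+activation / vehicle / untreated design.

## Motif scanning numerics

Scores are log₂ odds against a background model (uniform by default) with
pseudocount 0.25 per count cell; ambiguous bases contribute the background
(score 0). Score P-values are exact tail probabilities of the background
score distribution, computed by dynamic-programming accumulation of the
per-position score distributions **discretized to 10⁻³ log-odds units**;
this bin width is part of the contract (results are bit-stable) and the DP
matches exhaustive enumeration over all sequences at that discretization to
1e-9 for widths up to 8. A score above the achievable maximum returns
exactly 0. Scanning considers both strands and every placement across the
±15 nt allelic windows; the best hit per allele is kept when either
allele's best placement clears P < 10⁻⁴, pairs with identical best scores
are discarded as carrying no allelic information, and strand ties resolve
to the + strand. Variants are biallelic SNVs only.

Activity classification uses a **two-sided exact binomial test** (a
one-sided mode is available through `alternative`) of the per-motif
over/under split against 0.5, at α = 0.01 by default with a
Bonferroni-corrected mode (0.05/1380) exposed. With discrete counts the
exact test is conservative; its null false-call rate is below α, which is
what the calibration tests assert (a KS test of uniformity is not
meaningful for discrete super-uniform P-values).

## Sharing, π1 and meta-analysis

The strict per-locus sharing rule requires a primary top association to
fall within the secondary population's first percentile of tested SNPs for
that locus (never fewer than one SNP), to have secondary P < 1.1×10⁻⁴, and
to agree in slope sign; the three conditions are reported separately. The
definition is deliberately asymmetric in primary/secondary roles, and the
percentile is computed per locus (the per-locus reading of "first
percentile of mapped SNPs"). π0 follows Storey: π0(λ) = #{p > λ}/(m(1−λ))
on λ ∈ {0, 0.05, …, 0.90}, smoothed by a cubic polynomial evaluated at the
largest λ and clipped to [0, 1]; with m < 100 the smoother is unstable and
the estimator falls back to the single point λ = 0.5 with a warning. The
cubic smoother is our stand-in for the reference implementation's spline —
any smooth fit evaluated at max λ is acceptable and the method is recorded
in the output. Note the estimator's known bias when the alternative
distribution is not sharply concentrated near zero: π0(λ) does not reach
its limit at λ = 0.9, so π1 is biased toward zero by roughly the
alternative's mass above λ; recovery tests therefore use sharp
alternatives. Fisher combination (−2Σln p against χ² with 2k df) is applied
to loci with a positive sharing verdict.

## Overlay and perturbation tests

Depth-by-genotype uses Welch's t between the two homozygote classes
oriented by the mapped association's direction; depth normalization is an
input contract (library-size-normalized upstream), this module never
touches raw reads. Allelic ChIP imbalance uses a χ² goodness-of-fit
against 50:50, switching to the exact binomial below 25 total reads, with
a 10-read minimum. LD r² is computed from phased haplotype frequencies
only (no EM from unphased genotypes, since all inputs here are phased);
monomorphic sites are flagged undefined rather than 0. GWAS intersection
links a locus to a disease when any retained cis-rSNP has r² ≥ 0.9 with a
catalog SNP at P < 5×10⁻⁸, one row per (locus, trait). Trait enrichment
and biotype enrichment are continuity-corrected 2×2 χ² tests with
observed/expected folds; degenerate margins are reported as NaN with a
note instead of raising.

The perturbation caller summarizes a transcript's imbalance per individual
and condition as the mean |Δ| over heterozygous SNPs (a per-SNP median mode
exists via `per_snp`); an individual qualifies only if heterozygous at the
transcript's top cis-rSNP with ≥ 3 het SNPs measured in both the TF-active
and TF-inhibited condition, and passes when the active/inhibited ratio
strictly exceeds 1.2. Two passing individuals make the verdict. Vehicle
and untreated conditions are carried as controls and reported but do not
enter the verdict. Homozygous individuals form the built-in negative
control and are reported separately.

## Problem sizes and determinism

Every stochastic step takes an explicit seed. The shipped checks run the
standard fixture at 200 loci × 100 samples for top-10 retention, 500 null
loci × 200 permutations for FDR calibration, m = 5000 for π1 recovery,
40 sites/motif × 12 motifs for activity-label recovery and 200 transcripts
for the perturbation caller — sizes chosen so the full suite completes in
a couple of minutes on one core while keeping binomial confidence
intervals tight enough for the stated bounds.

## Known limitations

* The normalization is a declared stand-in for the unpublished
  platform-specific procedure; only its intent (gDNA as the 50:50
  technical reference) is preserved.
* The empirical FDR pools permutation nulls across loci; a per-locus null
  would need far more permutations for comparable resolution.
* π1 inherits the Storey estimator's downward bias under diffuse
  alternatives (see above).
* Indels, multi-allelic variants and unphased genotypes are out of scope;
  unphased heterozygotes are treated as missing.
* The copying-process LD model has no recombination-map realism; it is a
  control knob for r², not a demographic model.
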