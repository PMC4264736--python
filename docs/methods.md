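# Methods

## The problem

In female cells one of the two X chromosomes is epigenetically silenced
(X-chromosome inactivation, XCI). The fraction of cells with the maternal
versus the paternal X active — the XCI ratio — ranges from 50:50 (random)
to 100:0 (completely skewed) and modulates the severity of X-linked
conditions in carriers. `xcisight` estimates this ratio directly from
allele-specific RNA expression: at a heterozygous SNP the variant-allele
read fraction reflects the relative expression of the chromosome carrying
that allele, and pooling many SNPs across the chromosome averages out
locus-level regulation.

## Allelic observations and the filter cascade

Allele counts come from a samtools-mpileup text pileup (bases with Phred
quality strictly above 20 by default) or, for simulated reads, from direct
attribution — each simulated read remembers its source haplotype and
coordinates, so counting needs no aligner. The allelic ratio at a locus is
alt reads over *total* quality-passing reads; third-allele (sequencing
error) reads stay in the denominator by default
(`third_allele_in_denominator=False` switches to ref+alt).

Loci are filtered in a fixed cascade before estimation: heterozygous in the
child's DNA (exome) genotype — never inferred from RNA; inside transcripts
(optional, interval-driven); outside the pseudo-autosomal regions PAR1/PAR2
(GRCh37 defaults chrX 60,001–2,699,520 and 154,931,044–155,260,560,
overridable by BED), because PAR loci follow diploid inheritance; variant
recalibration PASS; a dbSNP identifier present; and depth ≥ 20 ("less than
20X" removed). Every stage's survivor count is reported.

## Phased estimator (beta fit)

Given parental phase for each heterozygous SNP, the ratios of each phase
group are fitted to a beta distribution by maximum likelihood (L-BFGS on
(log α, log β) with analytic gradients, method-of-moments start). The beta
absorbs the over-dispersion of RNA-seq counts relative to one binomial. The
XCI estimate is the pair (100·mean_maternal, 100·mean_paternal); the two
numbers are estimated independently and need not sum to 100. The reported
SD is the fitted distribution's standard deviation on the percentage scale;
the empirical SD is available from the group statistics helper.

Boundary handling: a ratio of exactly 0 or 1 has no beta likelihood. Each
boundary observation of depth d is clamped to [1/(2d), 1−1/(2d)], a
half-read continuity correction that vanishes with depth. A phase group
whose ratios are all identical (every SNP mono-allelic at 100:0 with the
noise model off) carries no dispersion information; the fit degenerates on
purpose and reports the common value exactly.

Skew categories are assigned by nearest named panel ratio: ≥97.5 complete,
87.5–97.5 extreme, 77.5–87.5 moderate, below that random (midpoints between
the named grid ratios; the literature also uses an ">80:20" convention for
moderate skew).

## Unphased estimator (semiparametric stochastic EM)

Without parental genotypes the pooled ratios follow a two-component
location-shift mixture g(x) = λ f(x−μ₁) + (1−λ) f(x−μ₂) with a single
unknown component density f. Fitting is by stochastic EM: each sweep draws
a component label per point from the current posterior, re-estimates the
locations as labeled means, and re-estimates f by a binned Gaussian KDE of
the centered residuals (Silverman bandwidth on the current residuals,
evaluated on a fixed grid and interpolated).

Two constraints make the problem identifiable under the conditions this
model is actually used in:

* **f is symmetric and unimodal.** Symmetry alone is not enough: at λ = 1/2
  the model with an arbitrary symmetric f is non-identifiable — f can absorb
  the entire two-mode mixture shape and both locations collapse onto the
  pooled mean. Unimodality is imposed by symmetric decreasing rearrangement
  of the kernel estimate (mass-preserving on the uniform grid) and is the
  natural shape for a single component's allelic-ratio distribution.
* **λ = 1/2 by default.** Each heterozygous SNP's alternative allele lies on
  the maternal or paternal haplotype with probability one half, so the
  mixing weight is pinned by design; freeing it (``estimate_mixing=True``)
  is supported but wanders along a flat ridge when the components nearly
  coincide.

Numerics: 5 random starts (hard split at a random data quantile), 600
sweeps, 150 burn-in. Labels are aligned between sweeps by continuity
(per-sweep sorting would push coincident components apart); each start's
post-burn-in chain is averaged, and the starts are combined by
component-wise median — a robust consensus that ignores the occasional
chain trapped on the collapsed ridge, where pseudo-likelihood ordering is
too noisy to arbitrate. Convergence is declared when the two half-chain
means agree within half a percentage point for most starts. Everything is
deterministic given the seed. Component means are reported sorted
descending and are intentionally blind to parental origin.

At 2σ component separation (a 55:45 ratio at ~30–150X depth) the mixture
density is already unimodal and any unlabeled estimator — this one included
— carries a small residual shrink toward 50:50 (≲0.5 percentage points at
panel scale). At exactly 50:50 the major/minor split of two coincident
components is pure labeling; the component midpoint remains unbiased.

## Trio phasing

Phase-by-transmission on the X: genotypes are first recoded to true ploidy
(a male's X genotype outside the PAR, or any genotype inside a hemizygous
deletion, is one allele, so "A/A" is really "A"; a heterozygous male call on
X_nonPAR is flagged as a data-quality problem). For a child genotype the
implementation enumerates the orderings consistent with one allele from
each parent: exactly one legal transmission ⇒ phased, none ⇒ Mendelian
error (a de novo point change is indistinguishable from a genotype error
and maps to the same status), several ⇒ uninformative. Outside the PAR the
father's hemizygosity always breaks the double-heterozygote tie, which is
why essentially all high-quality het sites on X can be phased while the
same genotypes on an autosome could not.

An apparently homozygous/hemizygous child missing an allele a parent must
have transmitted (father hemizygous "A", child "G", mother carrying "G") is
an out-of-phase genotype — evidence that the region is deleted on that
parental chromosome. A deletion is phased by majority vote over informative
out-of-phase sites inside it; a single informative site suffices, ties are
undetermined.

## Coverage CNV detection

Physical (gapped) coverage counts each proper mate pair once in every 100-bp
window its full fragment span overlaps (the unsequenced gap between mates
included). Per-sample window counts are normalized to sum to one over the
analyzed region (a flag switches to genome-wide totals), log2-ratioed
between case and control with a 0.5/total pseudocount (windows with zero
coverage in both samples are missing, not zero), and smoothed with a
centered 25-window moving average. A heterozygous deletion in the case sits
near −1; one extra copy near +0.58 (amplification calling exists but is off
by default).

Calling: maximal runs of smoothed values ≤ −0.7 (margin below the nominal
−1 for capture noise), merged across gaps that are short (≤5 windows) or
whose smoothed signal stays below half the threshold (hysteresis — noise
excursions inside a deep deletion must not split it; window counts are
correlated over a fragment length, so excursions are long). Runs shorter
than 10 windows are dropped. Each breakpoint is then re-fitted as a sharp
step on the *unsmoothed* log2 series (matched filter over ±span windows):
the moving average blurs an edge by ~12 windows, while the step fit
localizes it to about one window at ≥20 fragments per window. Reported
breakpoints are window-grid coordinates. Because normalization is
per-region, a deletion spanning fraction q of the region raises the outside
baseline by −log2(1−q/2) and the plateau sits slightly above −1; the
plateau estimate uses the unsmoothed run median.

## Escape calling

A phased heterozygous variant escapes XCI when its ratio is more than two
standard deviations from its own phase group's chromosome-wide mean *and*
shows bi-allelic expression (ratio in [0.1, 0.9]). The mean/SD are the
empirical group summaries by default. Candidates below 7X depth are
downgraded to low-confidence rather than removed, mirroring post-hoc
false-positive labeling. Genes roll up by "any candidate variant"; with k
variants per gene the background gene-level rate compounds the ~2.5%
per-variant tail, which is a property of the 2SD rule, not of the
implementation.

## The simulator and what passing tests mean

Read-level route: a transcriptome (synthetic by default: random ≥500-bp
transcripts with alternating strands laid along a synthetic X) is copied
into two haplotypes carrying the alternative alleles of a randomly split
SNP pool (maternal-alt / paternal-alt bins, p = 0.5); wgsim-style pairs are
drawn uniformly over valid fragment starts (fixed 150-bp outer distance,
100-bp reads, Q40, 1e-5 per-base substitution rate, no indels) and the two
pools are mixed exactly at the target ratio — round(ratio·total) maternal
pairs, the rest paternal, without replacement.

Count-level route (the workhorse): per-SNP alt counts are drawn from the
binomial implied by the mixing design. Depth follows a two-class coverage
model — 33% of SNPs sit in well-covered transcripts (gamma-Poisson, mean
150, shape 3), the rest in poorly covered ones (Poisson mean 3) — so that a
4996-SNP pool leaves ≈1600 SNPs at ≥20X, matching a deep transcriptome
experiment in which most pool SNPs fall in weakly expressed transcripts
while passing SNPs are covered at an effective (harmonic-mean) depth near
140. Two nuisances are modeled: reference bias b (an alt read lost to
mapping with probability b; default 0) and a symmetric cross-mapping rate
c = 0.004 (a read attributed to the wrong allele through sequence homology),
the magnitude of residual mapping noise a mismatch-tolerant aligner leaves
on a transcriptome-simulated read set. The 11-ratio panel runs one dataset
per ratio from 100:0 to 50:50 with per-dataset child seeds derived from the
master seed.

What the simulator does *not* model: expression-level variation coupled to
genotype, splice-junction reads, GC/mappability structure, cell-type
mixtures, or genes that genuinely escape XCI (escape loci are planted
explicitly in the escape tests). Passing the panel tests therefore shows
the estimators recover the ratio under binomial sampling with realistic
depth spread and mild mapping noise — not that every real-data nuisance is
handled.

Problem sizes used by the test suite and the acceptance script — 4996-SNP
panels, 20-seed recovery grids, a 10-Mb coverage region at ~100 fragments
per window with the 1.64-Mb deletion at 6,451,600–8,095,100 — are the
package's desk-scale defaults; all scale up linearly via the public
parameters.

## Known limitations

* Chromosome-wide pooling assumes escape genes are rare enough not to drag
  the group means; they are flagged downstream, not excluded upstream.
* The SP route reports components blind to parental origin; only the phased
  route signs the skew.
* The beta fit treats SNPs as independent; multiple SNPs in one transcript
  share expression noise, so the reported SD understates locus correlation.
* CNV detection has no GC or mappability correction and no segmentation
  model; it is designed for single large events against a matched control.
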