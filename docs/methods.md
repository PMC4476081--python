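# Methods

## The statistic

For a biallelic locus with within-population allele frequencies f₁, f₂ and
sample counts n₁, n₂, the pooled frequency treats all animals as one
population with chromosome-count weights:

    f_p = [f₁(2n₁) + f₂(2n₂)] / [2(n₁ + n₂)],   f_q = 1 − f_p.

Total expected heterozygosity is H_t = 2 f_p f_q; within-population expected
heterozygosity H_s is the mean of 2fᵢ(1−fᵢ) under the *same* chromosome-count
weights, and the fixation index is

    Fst = (H_t − H_s) / H_t.

Matching the H_s weights to the f_p weights makes H_t ≥ H_s a theorem
(concavity of 2p(1−p)), so Fst ∈ [0, 1] wherever H_t > 0; `equal_weights=True`
is available but can produce slightly negative values with unequal samples.
No finite-sample (Weir–Cockerham θ-style) bias correction is applied: the
statistic is the plain heterozygosity ratio, computed from the post-imputation
genotype matrix. Loci monomorphic in the pooled sample get NaN and are
excluded from smoothing. The genome-wide mean × 100 is reported as the
percentage of total genetic variation attributable to between-population
differences.

## Data editing

Filters run in a fixed order so the report's removal counts are reproducible
(each SNP is attributed to the first filter that removes it; the retained set
is order-invariant): (1) SNPs monomorphic in *both* populations separately —
a locus fixed in one breed but segregating in the other is kept; (2) pooled
per-SNP missing-call fraction > 2.5%; (3) pooled MAF < 1% (non-missing calls,
both breeds together; per-breed thresholds were considered and rejected
because the pooled-frequency Fst is the downstream consumer). Sample-level
filtering is deliberately absent. Imputation replaces each missing call with
the *homozygote* of the modal allele within that sample's own breed — the
literal two-copies reading of "fill with the most frequent allele" — with
exact 0.5 ties broken toward allele_a, deterministically. Heterozygosity
summaries (H_obs = heterozygote fraction among non-missing calls, H_exp =
mean of 2f(1−f)) are computed after filtering but before imputation, since
imputation adds only homozygotes and would bias H_obs downward.

## LOWESS smoothing and the control chart

Raw per-SNP Fst along a chromosome is noisy; the scan smooths it with the
classic tricube-weighted local polynomial (degree 1, no robustness
iterations by default; both are configurable) evaluated at every SNP. The
neighborhood is the nearest `window_snps` = 20 points by physical distance —
equivalently a chromosome-specific smoothing fraction S = 20/n_chrom — so
each local regression always spans the same marker count regardless of
chromosome length. The regression abscissa is base-pair position (an
SNP-index mode exists for sensitivity analysis); duplicate positions are
jittered by +1 bp; NaN loci are dropped before smoothing and reported.
The implementation is an exact closed-form weighted least squares and agrees
with an independently coded oracle and with a reference LOWESS implementation
to ≈ 1e-8 in tests.

The smoothed series is then treated as a control chart: limits at
mean ± k·SD (k = 3, sample SD, n−1) computed per chromosome by default
(a genome-wide mode exists). Values strictly above the UCL are outliers
(values exactly on a limit are not); contiguous outlier runs collapse to one
peak whose summit is the maximum smoothed value. Lower-limit exceedances are
retained in the data model but excluded from annotation: only elevated
differentiation marks a candidate selection signature. "Borderline" peaks —
local maxima above mean + 0.9·k·SD but not above the UCL — flag possibly
incomplete sweeps; the 0.9 fraction is this package's own convention and is
configurable.

Null behavior worth knowing: because the chart re-estimates its limits from
the smoothed series itself, smoothing does not reduce the flag rate below the
nominal two-sided 3-SD level. With Gaussian noise the null rate is the
nominal ≈ 0.27%; the per-SNP Fst null is chi-square-like, and local averaging
over ~20 SNPs leaves a right-skewed (effective df ≈ 10–20) distribution whose
upper-tail exceedance at mean + 3 SD is ≈ 1%. Interpreting chart outliers as
a 0.27%-level test would therefore be anti-conservative; the procedure is an
outlier screen, not a calibrated hypothesis test.

## Regional LD comparison (varLD-style)

For every sliding window of 20 consecutive SNPs (step 1, never spanning
chromosomes), each population contributes the signed Pearson correlation
matrix of its genotype dosages (composite LD — phase-free). Columns that are
fixed in one population contribute 0 off-diagonal and 1 on the diagonal,
keeping the matrix well defined and the trace equal to k. The window's raw
score is Σ|λ_A(i) − λ_B(i)| over decreasingly sorted eigenvalues — 0 for
identical LD structure, bounded by 2k, symmetric in the populations. Raw
scores are standardized genome-wide; the default is a z-score so a "3 SD"
threshold is literal, with a Blom rank-based inverse-normal transform as the
alternative (the z-score null tail is right-skewed, ≈ 0.5–0.6% above +3 SD,
whereas rank-normal pins it at ≈ 0.13% by construction). Each window's score
is assigned to its central SNP (offset ⌈k/2⌉ from the window start, 1-based)
and the upper tail only is called significant — elevated LD divergence is the
signal of interest.

## Synthetic data

The generator emulates the study conditions this pipeline targets: 29
autosomes of 100 Mb carrying 1800 SNPs each (~52K total, near-regular spacing
with jitter), two breeds of 364 and 410 animals, ancestral allele frequencies
uniform on [0.05, 0.5] (randomly polarised), and adjacent-SNP allelic
correlation ρ = 0.3 via a first-order Markov haplotype walk whose transition
probabilities are clamped to preserve every marginal exactly. Missing calls
are iid at 0.5%.

Background differentiation is pure drift: each population's frequencies
undergo T generations of Wright–Fisher binomial resampling with 2N = 1000
chromosomes. For two demes drifting independently for T generations, the
expected value of this package's (Nei/Gst-style) Fst is

    E[Fst] ≈ F₁ / (2 − F₁),   F₁ = 1 − (1 − 1/2N)^T,

which the test suite verifies; note this is *not* the pairwise-coancestry
quantity 1 − (1 − 1/2N)^(2T) — with only two demes, the total heterozygosity
H_t sits roughly halfway between H_s and the between-population
heterozygosity, halving the statistic. The defaults T = 57, N = 500 target a
background mean Fst of ≈ 0.0285 through the formula above (realized ≈ 0.029).

Sweeps are planted by replacing the drifted frequency of the selected allele
in the target population with the deterministic logistic trajectory
p′ = p(1+s)/(1+sp) run for the whole divergence time, and pulling flanking
SNPs toward a randomly chosen sweep-coupled allele with weight
exp(−distance/decay) · (sweep progress), decay 500 kb — a phenomenological
hitch-hiking proxy that creates Fst peaks of tunable width, not a
recombination-explicit model. LD-divergent regions change the haplotype
coupling inside a span in one population without touching marginals, so they
are visible to the LD detector and invisible to Fst. The default mechanism
sets the coupling to zero (`ld_mode="decouple"`); a literal sign inversion
(`ld_mode="invert"`) is also available but is nearly invisible to an
eigenvalue-based score, because C(−ρ) = D·C(+ρ)·D with D = diag(1,−1,1,…) is
a similarity transform — every window fully inside an inverted region has
*identical* eigenvalues in the two populations, and only boundary windows
differ. This spectral blindness is a genuine limitation of eigenvalue-based
LD comparison worth remembering when interpreting negative results.

What the generator does not model: recombination maps, gene conversion,
demographic events (bottlenecks, migration, expansion), genotyping error
beyond iid missingness, ascertainment bias of array SNPs, and linkage between
drift and LD (frequencies and haplotype structure are generated in separate
stages). Passing recovery tests therefore demonstrates that the detectors see
the planted signal classes under realistic marker density, sample size and
background differentiation — not that they are calibrated for any particular
real demography.

## Problem sizes used in tests and the acceptance script

Unit tests run on small genomes (hundreds of SNPs); calibration and recovery
checks use 50,000-locus null genomes, a 20,000-locus drift genome, and 50
(tests) or 20 (acceptance script) replicates of a 5-chromosome × 2,000-SNP
genome with one sweep and one 2-Mb LD-divergent region per chromosome — sizes
chosen so the full suite completes in a few minutes on one CPU while keeping
≥ 100 planted signals per recovery estimate. The acceptance script's headline
run uses the full study-scale defaults (29 × 1800 SNPs, 364+410 samples).

## Numerical and interface choices

- Coordinates are 1-based closed intervals throughout; BED conversion happens
  only at the file boundary. A significant SNP at p yields the closed
  interval [max(1, p − 250000), p + 250000]; overlapping or book-ended
  intervals merge; a 1-bp gene intersection counts as a hit; strand ignored.
- Allele orientation (which allele dosages count) is fixed at read time and
  never re-polarised; every downstream statistic is invariant to it. Text
  PED stores no allele order, so exact round-trip equality requires
  `polarize_like` against the original (VCF round-trips exactly).
- Concordance between detectors is classified per chromosome: exact (shared
  significant SNP), regional (nearest signals within 500 kb), discordant.
- All randomness flows through one `numpy` Generator seeded from the config;
  identical configs give byte-identical datasets and pipeline outputs.
- Degenerate inputs: zero-SD chromosomes collapse chart limits to the mean
  and flag nothing; chromosomes with fewer SNPs than the window fall back to
  S = 1 (smoothing) or are skipped (varLD) with a warning; fully missing
  loci within a population are an error at imputation time.
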