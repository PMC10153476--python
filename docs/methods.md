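# Methods

This note documents the statistical models implemented in `admixscan`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about behavior on real ancient-DNA data.

## Data model

All genotypes are pseudohaploid: one sequencing read's allele per site per
individual, coded 0 (reference allele sampled), 2 (alternate) or 9
(missing). Each non-missing call therefore contributes exactly one allele to
frequency counts, and a population's observation count at a site is its
number of non-missing calls. True diploid codes (1) are rejected by default;
an opt-in seeded conversion replaces each with a uniformly drawn allele.

Positions are 1-based as in `.snp` files. Interval filters (the mappability
mask, region queries) are consumed as BED, i.e. 0-based half-open; a SNP at
position p is inside [start, end) iff start ≤ p − 1 < end. The mappability
filter is taken as a pre-thresholded interval file of retained regions
rather than a per-base score track, because the analysis applies a single
fixed cut (0.99). Default site filters: at least 20 non-missing Neolithic
genotypes per site, and optionally a pooled minor-allele-frequency floor
(used at 0.05 for shotgun-style confirmation data). Pooled MAF uses all
individuals combined, since that filter is applied before any population
contrast.

## Window scans and the gamma null

Per-SNP statistics (f2, F_adm; definitions in the README) are averaged in
sliding windows of 51 SNPs with step 1, reported at the median SNP's
position; windows never span chromosome boundaries. Missing per-SNP values
are dropped from the window mean (not zero-filled); windows with fewer than
half their SNPs non-missing carry a flag. Which treatment of missing values
the original analyses used is not documented anywhere we know of; dropping
is the conservative reading and the reported `n_snps` lets a user re-filter.

Overlapping windows are strongly autocorrelated, so p-values cannot come
from the raw window distribution. A null sample is built by greedy
left-to-right thinning per chromosome: keep the first window, then the next
window at least `min_gap_bp` (default 5 Mb) beyond the last kept one.
Greedy deterministic spacing was chosen over random spaced draws because it
is reproducible and the spacing constraint, not the draw order, is what
makes the sample approximately independent; a seeded random-offset mode
exists for sensitivity checks. The null size is therefore emergent from the
genome and the gap — it is not forced to any particular count.

A gamma distribution is fitted to the null sample by maximum likelihood
(`scipy.stats.gamma.fit` with location fixed at 0). Exact zeros are excluded
from the fit (gamma support is positive) and zero-valued windows receive
p = 1. Window p-values are the fitted distribution's upper-tail
probabilities, clipped into (0, 1]. For signed tracks, Z scores standardize
against the null sample's mean and standard deviation (ddof = 1); the
standard deviation comes from the same spaced null because a Z score is not
defined by a mean alone.

The F_adm denominator deserves a note: the variance normalization y(1 − y)
is isolated in a single private function so that an alternative
normalization can be swapped in without touching anything else.

## Local ancestry HMM

The admixed cohort is modeled as the product of one admixture pulse between
a minority source (proportion α = 0.3 Mesolithic) and a majority source,
t = 35 generations before sampling, in a population of effective size
Ne = 10,000. Along the genetic map, each haplotype's source-of-origin is a
two-state Markov jump process: recombination events since the pulse arrive
at rate t per morgan and each event redraws the ancestry from Bernoulli(α).
Over an inter-site distance d morgans the haplotype switch probability is
s = 1 − exp(−t·d), giving the transition matrix
[[1 − s(1−α), s(1−α)], [sα, 1 − sα]] (Mesolithic row first) with stationary
distribution (α, 1−α).

Hidden states are the diploid Mesolithic dosage k ∈ {0, 1, 2}: two
independent haplotype chains collapsed to dosage (no inbreeding), with
Hardy–Weinberg prior. Chromosome boundaries are treated as infinite map
distance, so the chain restarts at its stationary prior. At dosage k the
alternate-allele probability is q_k = (k/2)·p̃_M + (1 − k/2)·p̃_N where p̃
are the panel frequencies smoothed with a pseudocount of 0.5 per allele
(Jeffreys-style); a pseudohaploid call is a single Bernoulli(q_k) draw, read
counts are Binomial(reads, q_k), and missing sites contribute likelihood 1,
preserving chain continuity. Ne is recorded in the model spec as the assumed
cohort size but does not enter the emissions; pseudocount smoothing is the
only panel regularization implemented. t and α are fixed model inputs, not
estimated.

Decoding is scaled forward–backward, vectorized across individuals, stable
for 10⁵+ sites; posteriors are renormalized per site and the backward pass
reuses the forward scaling constants. An exhaustive path-enumeration oracle
(for ≤ ~10⁶ paths) and an independent backward-recursion log-likelihood are
kept in the package for verification, and the test suite holds them to
1e−10 / 1e−8 agreement.

**Panel-noise bias.** The emissions use point estimates of the source
frequencies. With panels of a few dozen effective observations per site,
each panel's sampling noise penalizes the likelihood of its *own* ancestry
states across every site of a tract, which biases the absolute genome-wide
posterior fraction by roughly +0.02–0.03 at the default panel sizes (the
smaller, less drifted Neolithic panel loses more). This is inherent to
plug-in emissions, affects the absolute level but much less the *location*
of deviations, and is the reason the LAD track is centered: LAD subtracts
the spaced-null mean fraction, so locus-level inference is made relative to
the cohort's own genome-wide baseline. Validation of absolute ancestry
recovery is therefore run with the simulator's true source frequencies as
panels, which isolates the decoding property from panel estimation.

The LAD track windows the cohort-mean posterior fraction exactly as the
scan statistics, subtracts the spaced-null mean (positive = Mesolithic
excess) and Z-scores against the null standard deviation. Whether to center
on the full genome-wide mean or the null-sample mean is a free choice (they
coincide asymptotically); the null-sample mean is used so that the centering
and the scale come from the same approximately independent sample. Region
averages (e.g. over the MHC span) are the unweighted mean of LAD over
windows whose centers fall in the region; their Z score standardizes
against same-width pseudo-regions centered on every spaced null position —
deterministic, and respecting the window autocorrelation at the region's
own width.

The reference-bias probe decodes a haploid allele sequence (e.g. the
reference genome's alleles at panel sites) with a two-state version of the
same HMM and reports the fraction of sites confidently (posterior > 0.9)
assigned to each ancestry: a reference uniformly closer to one source would
decode one-sided, which would flag mapping bias as an alternative
explanation for local ancestry signals.

## Polygenic test

Associations are thresholded at GWAS p < 1e−8 and thinned by iterative
distance pruning: keep the genome-wide smallest p, drop everything within
250 kb on the same chromosome, repeat. Ties are broken by position then SNP
id, making the output deterministic; pruned output is invariant under
re-pruning. Effect alleles are aligned to the panel's alternate allele
(flipping β when needed; the weight w = β·(p_N − p_M) is invariant under a
consistent flip). Each weighted SNP is matched to the LAD Z at the nearest
window center on the same chromosome within a 100 kb cap — unmatched SNPs
are dropped and counted. The primary statistic is the per-SNP Pearson
correlation between w and Z with its two-sided p-value (≥ 3 matched SNPs
required); the genome-wide sum of w is emitted as an auxiliary per-trait
summary. A leave-out list supports checking whether a signal is driven by
one or two loci.

## Synthetic cohorts

The generator emulates the study system so every stage can be exercised
against known truth:

* **Source frequencies** follow the Balding–Nichols model: ancestral
  frequency p0 ~ Uniform(0.05, 0.95), then per-source
  Beta(p0(1−F)/F, (1−p0)(1−F)/F) with drift F = 0.15 (Mesolithic-like) and
  0.10 (Neolithic-like) — deep enough divergence that the panels are
  ancestry-informative, on the order of the hunter-gatherer/farmer contrast.
* **Genome**: six chromosomes of 100 Mb and 1 morgan (constant 1 cM/Mb),
  2,000 SNPs each on a jittered grid. This SNP density (20/Mb) is far below
  the 1240k capture panel; it keeps simulation and decoding fast while
  leaving ~45 SNPs per expected ancestry tract (1/t morgans ≈ 2.9 Mb), which
  is what the HMM needs. Tests that quote "20,000 SNPs" use five chromosomes
  at double density.
* **Cohort**: 125 Mesolithic and 55 Neolithic panel individuals (the study's
  group sizes), 150 admixed individuals, single pulse α = 0.3 at t = 35
  generations, pseudohaploid calls with 30% missingness (a typical capture
  coverage regime); an alternative Poisson read-count coverage model is
  available.
* **Ancestry truth** is simulated with exactly the Markov jump process the
  HMM assumes, so simulator-vs-inference consistency is exact by
  construction; tract boundaries, per-SNP cohort ancestry fractions and
  source frequencies are recorded in a `TruthSet`.
* **Selection** is injected by conditioning the tract process: at a focal
  SNP each haplotype is Mesolithic with probability α + Δ, and the
  (reversible) chain is simulated outward from the focal point — the exact
  conditional law for one locus per chromosome, giving LAD peaks with
  realistic megabase-scale tract-decay width rather than post-hoc
  relabeling. With several loci on one chromosome, outward simulations are
  joined at midpoints between foci; this is exact only when foci are several
  tract lengths apart, which the polygenic scenarios enforce (≥ 4 Mb
  spacing). An optional frequency shift δ additionally moves admixed allele
  emissions toward the alternate allele within 1.5 Mb of the focal SNP,
  emulating direct selection on the allele itself for the F_adm scan.
* **Trait fixtures**: hit SNPs are placed at spaced panel sites with normal
  effect sizes, optionally correlated with the signed source frequency
  difference; the adaptive scenario couples each hit to an injected ancestry
  shift of fixed magnitude pointing toward the source that carries more of
  the trait-increasing allele.

What the synthetic cohorts do **not** emulate: real human demography (no
coalescent within sources, no linkage disequilibrium beyond the admixture
tracts, no post-admixture drift by default), ancient-DNA damage and
sequencing error, ascertainment of the capture panel, and sample-level
heterogeneity in age or coverage. Passing tests therefore establish the
internal consistency and calibration of the statistics under their own
model assumptions — not robustness to those real-data complications.

## Numerical and reproducibility choices

* Forward–backward underflow is handled by per-site scaling; a zero
  observation likelihood (possible only with unsmoothed degenerate panels)
  raises rather than silently renormalizing.
* A genetic map with zero length on every chromosome is rejected at model
  construction; chromosomes absent from a supplied recombination map fall
  back to a constant 1 cM/Mb with a logged warning.
* Gamma fitting requires ≥ 30 positive null values and raises on constant
  samples; the pipeline degrades gracefully (scan written without p-values,
  with a logged warning) when a run is too small to calibrate.
* A LAD null whose standard deviation is at floating-point noise level
  (≤ 1e−12 relative) is treated as flat: LAD ≡ 0 decodes to Z ≡ 0.
* Every stochastic component takes a `numpy` Generator or seed; the
  pipeline derives per-stage seeds from the global seed by hashing the
  stage name (recorded in the manifest), and identical config + seed
  produces byte-identical run directories. For this reason the run-dir log
  file carries stage tags but no wall-clock timestamps (timestamps appear
  on the stderr handler only), and the manifest omits the output path.
* Output floats are serialized with `%.10g` so text outputs are stable
  across runs and platforms.

## Known limitations

* Two sources, one pulse: no multi-way admixture, no pulse-time or
  proportion estimation, no phasing.
* Plug-in panel emissions carry the absolute-level bias described above;
  integrating panel uncertainty site-by-site does not remove it (the
  single-read emission is linear in the frequency), so cohort-level
  inference should always be read relative to the genome-wide baseline, as
  the LAD track does.
* The gamma null describes the bulk of neutral window statistics well at
  the simulated scales, but extreme tails of correlated window scans can
  exceed nominal significance under panel-frequency noise the statistics do
  not model; genome-wide minima should be interpreted against the LAD and
  F_adm scans jointly, as the worked example does.
* The polygenic test inherits GWAS winner's-curse and portability issues of
  its input effect sizes; it tests for correlation with LAD, not for a
  selection gradient.
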