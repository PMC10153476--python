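# admixscan

Detection of **adaptive admixture** in ancient-DNA cohorts: natural selection
acting on the ancestry introduced when two diverged populations mix — the
motivating case being Neolithic European farmers who acquired 20–30%
Mesolithic hunter-gatherer ancestry and then experienced selection at loci
such as the MHC (excess hunter-gatherer ancestry) and *SLC24A5* (excess
farmer ancestry).

The package is written for population geneticists working with low-coverage,
pseudohaploid genotype data (EIGENSTRAT `.geno/.snp/.ind`, one sampled allele
per site per individual, coded 0/2/9). It provides three complementary
scans, a shared genome-wide null-calibration framework, and a seeded
simulator of admixed cohorts with known ground truth so that every stage is
testable without access to restricted ancient-DNA compendia.

## Methods at a glance

Let p_M, p_N and p_ADM be the allele frequencies of the Mesolithic-like
source, the Neolithic-like source and the admixed cohort, and let
α be the genome-wide admixture proportion of the minority source (default
α = 0.3).

* **f2 scan** — per-SNP squared frequency difference `f2 = (p1 − p2)²`,
  an admixture-unaware differentiation statistic.
* **F_adm scan** — deviation of the admixed frequency from its admixture
  expectation `y = α·p_M + (1−α)·p_N`, variance-normalized:
  `F_adm = (p_ADM − y)² / (y(1−y))`.
* Each statistic is averaged in **51-SNP sliding windows** (step 1, centered
  on the median SNP). A null sample of approximately independent windows
  (≥ 5 Mb apart) is drawn per statistic, a **gamma distribution is fitted by
  maximum likelihood**, and upper-tail probabilities give each window a
  p-value.
* **Local ancestry (LAD) scan** — a two-source hidden Markov model over
  diploid Mesolithic dosage states {0, 1, 2} with Hardy–Weinberg prior
  (α², 2α(1−α), (1−α)²), per-interval transition matrices from a single
  admixture pulse t = 35 generations ago (haplotype switch probability
  `s = 1 − exp(−t·d)` over d morgans), and panel-frequency emissions for
  pseudohaploid calls or read counts. The cohort-mean posterior Mesolithic
  fraction is windowed identically, centered on the spaced-null mean
  (**local ancestry deviation**, positive = Mesolithic excess) and Z-scored
  against the null standard deviation.
* **Polygenic test** — GWAS hits (p < 1e−8) are distance-pruned (250 kb),
  each effect size β is weighted by the signed source frequency difference
  `w = β·(p_N − p_M)`, and w is tested for Pearson correlation with the LAD
  Z score at the nearest window: directional inheritance of trait-raising
  alleles from one source shows up as a nonzero correlation.

## Worked example

Simulate a cohort at the study conditions (six 100 Mb chromosomes, 2,000
SNPs each; 125/55 source panels; 150 admixed individuals; 30% missingness)
with one locus under post-admixture selection — Mesolithic ancestry excess
Δ = +0.2 and an allele-frequency shift δ = 0.15 at chr1:50 Mb — then run both
scans:

```python
import numpy as np
import admixscan as ax

locus = ax.SelectedLocus(chromosome="1", position_bp=50_000_000,
                         ancestry_shift=0.2, frequency_shift=0.15)
config = ax.SimulationConfig(seed=3, selected_loci=(locus,))
result = ax.simulate_cohort(config)

gm = ax.filter_sites(result.genotypes)          # ≥20 Neolithic calls per site
freqs = ax.compute_frequencies(gm)

fadm = ax.fadm_statistic(freqs.freq(ax.ADMIXED), freqs.freq(ax.MESOLITHIC),
                         freqs.freq(ax.NEOLITHIC), alpha=0.3)
windows = ax.sliding_windows(fadm, gm.snps)
null = ax.spaced_subsample(windows)
fit = ax.fit_gamma(null)
windows["pvalue"] = ax.tail_pvalues(fit, windows["value"].to_numpy())
top = windows.nsmallest(1, "pvalue").iloc[0]
print(f"top F_adm window: chr{top.chromosome}:{top.center_bp} "
      f"p = {top.pvalue:.3g}")

hmm = ax.build_hmm(alpha=0.3, t_generations=35, ne=10_000,
                   snps=gm.snps, panel_freqs=freqs)
track = ax.posterior_dosage(hmm, gm.calls[:, gm.population_mask(ax.ADMIXED)])
lad = ax.cohort_lad(track, gm.snps)
peak = lad.windows.iloc[int(np.argmax(np.abs(lad.windows["z"])))]
print(f"top |LAD Z| window: chr{peak.chromosome}:{peak.center_bp} "
      f"LAD = {peak.lad:+.3f} (Z = {peak.z:.2f})")
```

which prints:

```
top F_adm window: chr1:50091264 p = 3.39e-26
top |LAD Z| window: chr1:50472898 LAD = +0.067 (Z = 3.02)
```

Both scans put their genome-wide extreme at the injected locus: the F_adm
window p-value is far beyond anything the gamma null produces elsewhere, and
the LAD peak shows a +6.7 percentage-point Mesolithic excess over the
genome-wide mean. Across replicate simulations the injected locus tops the
LAD scan in ≈ 90–95% of runs; the example seed is one such run.

## Command line

A YAML-configured pipeline wraps the same calls (`data → scan → lad →
polygenic`), writing plain-text intermediates, a manifest and a log into a
run directory; reruns with the same config and seed are byte-identical.

```sh
admixscan run-all --config examples/config.yaml
admixscan report runs/demo
```

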