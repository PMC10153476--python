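# Demonstration pipeline: simulated cohort with one locus under
# post-admixture selection, all three scan stages.
seed: 3
output_dir: runs/demo
stages: [data, scan, lad]

simulation:
  n_chromosomes: 6
  n_snps_per_chrom: 2000
  chrom_length_bp: 100000000
  chrom_length_morgans: 1.0
  n_mesolithic: 125
  n_neolithic: 55
  n_admixed: 150
  miss_rate: 0.3
  alpha: 0.3
  t_generations: 35
  selected_loci:
    - {chromosome: "1", position_bp: 50000000, ancestry_shift: 0.2,
       frequency_shift: 0.15}

# scan / null calibration
window_snps: 51
min_gap_bp: 5000000

# local ancestry HMM
alpha: 0.3
t_generations: 35
ne: 10000
pseudocount: 0.5

# site filters
min_neolithic_obs: 20
maf_min: 0.0
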