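# Demo study: fully synthetic, seeded, runs in ~10 s.
# A binary-liability exposure (per-allele log-OR instruments) with a small
# positive causal effect on fitness outcomes, plus an LD-score panel for
# the genetic-correlation table.
seed: 42
binary_exposure: true
case_exclusion: true
n_boot: 200
phi: 0.5
filter_mode: flat
palindromic_policy: infer_by_eaf

simulation:
  n_individuals: 5000
  n_snps: 80
  true_causal_effect: 0.1
  exposure_h2: 0.05
  pleiotropy_mode: none
  allele_swap_fraction: 0.3
  palindromic_fraction: 0.1

ldsc:
  M: 10000
  h2_1: 0.4
  h2_2: 0.3
  rg: 0.5
  N1: 50000
  N2: 50000
  blocks: 200
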