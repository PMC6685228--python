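# Fully synthetic end-to-end run: three cancer types spanning low to high
# TMB, one 300-gene panel defined in panel300.yaml. Replace the `synthesize`
# block with an `input` block (maf / type_map / gene_lengths paths) to
# analyze a real MAF.
exome_mb: 38.0
synthesize:
  universe: {}
  cancer_types:
  - code: LOTM
    n_samples: 120
    tmb_log_mean: 0.0
    tmb_log_sd: 0.5
  - code: MIDT
    n_samples: 120
    tmb_log_mean: 1.1
    tmb_log_sd: 0.5
  - code: HITM
    n_samples: 120
    tmb_log_mean: 2.3
    tmb_log_sd: 0.5
panels:
- panel300.yaml
cutpoint_fractions:
- 0.2
mode: value_transfer
removal_fractions:
- 0.01
- 0.02
- 0.03
- 0.04
- 0.05
design:
  sizes:
  - 150
  - 320
  - 490
  - 660
  - 830
  - 1000
  n_draws: 100
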