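# Scaled-down full-pipeline demonstration (completes in a few minutes).
# Omitted keys take the documented defaults (see methylaging.workflow.DEFAULTS).
seed: 0
out_dir: run_demo
cohort:
  n_samples: 160
  n_probes: 1200
integrate:
  n_perm: 300
  n_links: 20
clock:
  alpha_grid: [0.1, 0.5, 0.9]
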