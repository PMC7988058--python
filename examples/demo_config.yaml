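# Demo: a 12-patient synthetic cohort with a protective MPP effect
# (HR 0.89 per MPP unit at the reference medium filter scale).
cohort:
  n_patients: 12
  seed: 7
  beta_mpp: -0.117
  reference_ssf_mm: 3.0
ssf_list: [0, 2, 3, 4, 5, 6]
screen_p: 0.05
endpoints: [os, pfs]
out_dir: demo_run
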