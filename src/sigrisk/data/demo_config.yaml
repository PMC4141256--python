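# Demo run: reduced synthetic study that finishes in a few seconds.
seed: 0
simulate:
  n_genes: 400
  n_signature: 12
  paired_patients: [15, 15, 15, 15]
  n_train: 80
  n_validation: [80]
sam_permutations: 100
n_resamples: 50
tumor_concordance: same
min_support: 3
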