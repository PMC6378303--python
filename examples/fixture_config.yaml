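# Small end-to-end fixture: 13-site gradient metacommunity, scaled down for
# a fast full-pipeline run.
seed: 7
outdir: results_fixture
depth: 1000
n_perm: 99
n_null: 49
simulation:
  n_specialist: 60
  n_generalist: 60
  n_neutral: 180
  depth: 1000
  seed: 7
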