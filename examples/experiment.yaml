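# Demo experiment config for `nfloop run --config examples/experiment.yaml`
# 11 participants in three groups, 2 sessions x 4 training runs each.
acquisition:
  tr: 1.5
  n_dummy: 10
  n_scans_total: 150
groups:
  AG:       {n: 5}   # contingent feedback, planted gain 0.28 %
  CG1:      {n: 3}   # contingent feedback, planted gain 0.20 %
  CG2sham:  {n: 3}   # sham feedback, gain 0
sessions: 2
runs_per_session: 4
network:
  labels: [left_FG, right_FG]
  correlation:
    - [1.0, 0.4]
    - [0.4, 1.0]
stages:
  simulate: true
  feedback: true
  metrics: true
  connectivity: true
  glm: false
master_seed: 11
out_dir: scratch/experiment_out
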