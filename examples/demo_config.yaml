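# Demo configuration for `catdecode run` / catdecode.run_pipeline.
# Two small synthetic cohorts with shared category geometry; group b
# responds 150 ms later.  Completes in a few minutes on one CPU.
seed: 7
groups:
  a:
    n_participants: 8
    n_channels: 25
    srate: 500.0
    epoch_window: [-200.0, 1000.0]
    n_trials_per_category: 35
    snr: 1.0
    group_tag: infant
  b:
    n_participants: 6
    n_channels: 63
    srate: 500.0
    epoch_window: [-200.0, 1000.0]
    n_trials_per_category: 35
    snr: 1.5
    group_tag: adult
latency_shift: 150.0
decoding:
  n_reps: 50
  n_bins: 4
stats:
  n_perm: 2000
  cluster_alpha: 0.005
  fwer_alpha: 0.05
  n_boot: 500
binning:
  decode_bin_ms: 20.0
analyses: [timecourse, crossgroup]
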