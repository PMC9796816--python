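"""Time-resolved category decoding on a synthetic infant-like cohort.

Simulates a small cohort with a category-dependent response (onset
250 ms, peak 400 ms), runs the pseudo-trial SVM pipeline per participant,
and applies sign-permutation cluster statistics to the group curve.
"""

import numpy as np

from catdecode import (StatMapSample, SynthEEGConfig, bin_downsample,
                       bootstrap_latency, cluster_correct, decode_timecourse,
                       peak_onset_offset, sign_permutation_pvals,
                       simulate_group)

cfg = SynthEEGConfig(n_participants=10, n_channels=25, srate=500.0,
                     epoch_window=(-200.0, 1000.0), n_trials_per_category=35,
                     signal_onset=250.0, signal_peak=400.0, snr=1.0, seed=1,
                     group_tag="infant")
group = simulate_group(cfg)

series = [decode_timecourse(bin_downsample(e, 20.0), n_reps=50, rng=i)
          for i, e in enumerate(group)]
curves = np.stack([s.grand_average() for s in series])
times = series[0].times

perm = sign_permutation_pvals(StatMapSample(curves - 50.0, tail="right"),
                              n_perm=2000, rng=0)
res = cluster_correct(perm, cluster_alpha=0.005, fwer_alpha=0.05)
lat = peak_onset_offset(perm.mean_map, res.mask, times,
                        window=(0.0, times[-1] + 1.0))
ci = bootstrap_latency(
    curves, lambda c: times[int(np.argmax(np.where(times >= 0,
                                                   c.mean(axis=0), -np.inf)))],
    n_boot=500, rng=1)

print(f"peak decoding accuracy : {perm.mean_map.max() + 50:.1f}% "
      f"(chance 50%)")
print(f"peak latency           : {lat['peak']:.0f} ms "
      f"[95% CI {ci.ci_low:.0f}, {ci.ci_high:.0f}]")
print(f"significant cluster    : {lat['onset']:.0f}-{lat['offset']:.0f} ms "
      f"(cluster-corrected p < .05)")
# The peak latency should recover the injected 400 ms response peak; the
# cluster onset trails the injected 250 ms onset because weak early
# signal needs time to reach statistical significance.
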