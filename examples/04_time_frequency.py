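"""Frequency-resolved decoding of an oscillatory category signal.

The generator amplitude-modulates a 5 Hz carrier with random phase per
trial: category information is invisible to trial averaging but lives in
single-trial oscillatory power, which the Morlet pipeline recovers.
"""

import numpy as np

from catdecode import SynthEEGConfig, decode_timefreq, simulate_group, tf_pipeline
from catdecode.timefreq import default_freq_grid

cfg = SynthEEGConfig(n_participants=1, n_channels=16, srate=250.0,
                     epoch_window=(-500.0, 1000.0), n_trials_per_category=30,
                     carrier_freq=5.0, snr=2.0, seed=1)
epochs = simulate_group(cfg)[0]

freqs = default_freq_grid(2.0, 30.0, 15)
tf = tf_pipeline(epochs, freqs=freqs)           # Morlet -> dB -> 20 ms bins
fr = decode_timefreq(tf, n_reps=20, rng=0)

gmap = fr.grand_average_map()                   # freq x time, percent
post = (tf.times > 100) & (tf.times < 800)
profile = gmap[:, post].mean(axis=1)
print("frequency profile of decoding accuracy (post-stimulus):")
for f, acc in zip(freqs, profile):
    bar = "#" * max(0, int((acc - 50) / 2))
    print(f"  {f:5.1f} Hz  {acc:5.1f}%  {bar}")
print(f"best frequency bin: {freqs[np.argmax(profile)]:.2f} Hz "
      f"(carrier was {cfg.carrier_freq} Hz)")
# Accuracy is confined to the bins nearest the carrier: the spectral
# signature of the injected representation.
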