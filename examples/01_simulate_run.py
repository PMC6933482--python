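"""Simulate one neurofeedback training run and recover the planted effect.

Builds the standard 150-scan training layout (10 dummy scans, then
baseline/regulation blocks of 30 s alternating B R B R B R B at TR 1.5 s),
plants a 0.3% regulation gain in the left feedback ROI, and checks that the
offline percent-signal-change metric recovers it.
"""

import numpy as np

from nfloop import AcquisitionSpec, SubjectParams, make_training_design, rffa, simulate_roi_run

acq = AcquisitionSpec()  # TR 1.5 s, 10 dummies, 150 scans
design = make_training_design(acq)
print(f"run duration: {design.duration_s / 60:.2f} min, "
      f"{acq.n_retained} scans analyzed after dummy discard")

params = SubjectParams(regulation_gain={"roi1_left": 0.3})
noiseless = SubjectParams(noise_sd=0.0, drift_slope=0.0, spike_prob=0.0,
                          regulation_gain={"roi1_left": 0.3})

r_clean = rffa(simulate_roi_run(design, noiseless, "roi1_left", seed=0))
vals = [rffa(simulate_roi_run(design, params, "roi1_left", seed=i)) for i in range(50)]

print(f"planted gain: 0.300% of baseline")
print(f"noiseless recovery: {r_clean:.4f}%  (HRF transients cost a few percent)")
print(f"noisy runs, mean of 50: {np.mean(vals):.4f}%  sd {np.std(vals):.4f}")
# The mean sits within a few hundredths of a percentage point of the planted
# effect; single-run estimates scatter with the AR(1) noise and spikes.
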