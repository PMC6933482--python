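"""Replay the closed-loop feedback computation, contingent vs sham.

The feedback each TR during regulation blocks is
F = (window - baseline)_ROI1 - (window - baseline)_ROI2: the bilateral
feedback ROI's rise over its preceding baseline block, minus the same
quantity in a reference slab (cancelling global activation), shown as a
10-bar thermometer.  Sham feedback is a seeded random walk that ignores
the brain entirely.
"""

import numpy as np

from nfloop import (AcquisitionSpec, SubjectParams, make_training_design,
                    run_feedback_session, simulate_roi_run)

design = make_training_design(AcquisitionSpec())
params = SubjectParams()  # contingent gains: 0.28% in both FFA patches

series = {roi: simulate_roi_run(design, params, roi, seed=i)
          for i, roi in enumerate(("roi1_left", "roi1_right", "roi2"))}

contingent = run_feedback_session(series, design, mode="contingent")
sham = run_feedback_session(series, design, mode="sham", seed=7)

print(f"updates per run: {len(contingent.frame)} (3 regulation blocks x 20 scans)")
print(f"contingent mean F: {contingent.f_values.mean():+.3f} BOLD units "
      f"(positive: the planted up-regulation is fed back)")
print(f"sham mean F:       {sham.f_values.mean():+.3f} (random walk, no contingency)")
print(f"thermometer levels, contingent: min {contingent.levels.min()} "
      f"max {contingent.levels.max()} (center bar = 5)")
reg = design.scans_for("regulate")
r = np.corrcoef(sham.f_values, series["roi1_left"].values[reg])[0, 1]
print(f"sham feedback vs ROI1 BOLD correlation: {r:+.3f} (no information)")
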