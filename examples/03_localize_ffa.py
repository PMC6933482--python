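"""Select feedback ROIs from a synthetic faces/houses localizer run.

Simulates a small 4-D localizer volume with two planted face-responsive
hotspots, fits the per-voxel Faces > Houses GLM, and places a maximal
activation patch in each hemisphere's ventral temporal search box plus the
configured reference slab.
"""

import numpy as np

from nfloop import (AcquisitionSpec, box_mask, build_roi_spec,
                    localizer_contrast_map, make_localizer_design,
                    simulate_localizer_volume)

acq = AcquisitionSpec(n_scans_total=166, grid_shape=(12, 12, 4))
design = make_localizer_design(acq)
print(f"localizer: {design.duration_s / 60:.2f} min, "
      f"{sum(1 for b in design.blocks if b.label == 'faces')} faces blocks, "
      f"{sum(1 for b in design.blocks if b.label == 'houses')} houses blocks")

truth = [(2, 5, 1), (2, 6, 1), (9, 5, 2), (9, 6, 2)]  # left + right hotspots
vol, mask = simulate_localizer_volume(design, acq, truth, seed=4, amplitude_pct=2.0)
tmap = localizer_contrast_map(vol, design)
print(f"t-map peak: {tmap.max():.1f} at {np.unravel_index(np.argmax(tmap), tmap.shape)}")

masks = {"left": box_mask(acq.grid_shape, (0, 0, 0), (6, 12, 4)),
         "right": box_mask(acq.grid_shape, (6, 0, 0), (12, 12, 4))}
spec = build_roi_spec(tmap, masks, reference_corner=(1, 9, 0),
                      patch_shape=(2, 2, 1), reference_shape=(9, 3, 1))
print(f"left patch:  {sorted(spec.roi1_left)}")
print(f"right patch: {sorted(spec.roi1_right)}")
print(f"reference slab: {len(spec.roi2_reference)} voxels")
hit = len(spec.roi1_left & set(truth)) + len(spec.roi1_right & set(truth))
print(f"planted hotspot voxels covered by the selected patches: {hit}/4")
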