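import numpy as np
import pytest

from nfloop import (
    AcquisitionSpec,
    RoiSpec,
    box_mask,
    build_roi_spec,
    localizer_contrast_map,
    select_ffa_patches,
    select_reference_roi,
    simulate_localizer_volume,
)
from nfloop.localizer import _best_patch

GRID = (12, 12, 4)


def _acq(grid=GRID):
    return AcquisitionSpec(n_scans_total=166, grid_shape=grid)


class TestContrastMap:
    def test_faces_voxel_has_largest_t(self, localizer_design):
        vol, _ = simulate_localizer_volume(localizer_design, _acq(), [(3, 4, 1)],
                                           seed=0, noise_sd=0.01)
        tmap = localizer_contrast_map(vol, localizer_design)
        assert np.unravel_index(np.argmax(tmap), GRID) == (3, 4, 1)

    def test_houses_voxel_has_negative_t(self, localizer_design):
        vol, _ = simulate_localizer_volume(localizer_design, _acq(), [(5, 5, 2)],
                                           seed=1, noise_sd=0.01,
                                           condition="houses")
        tmap = localizer_contrast_map(vol, localizer_design)
        assert tmap[5, 5, 2] < -10
        assert np.unravel_index(np.argmin(tmap), GRID) == (5, 5, 2)

    def test_null_volume_false_positive_rate(self, localizer_design):
        """Pure noise: the fraction of voxels with p < 0.001 stays near 0.001."""
        from scipy import stats as sps

        acq = _acq((16, 16, 6))
        hits = total = 0
        for seed in range(3):
            vol, _ = simulate_localizer_volume(localizer_design, acq, [], seed=seed)
            tmap = localizer_contrast_map(vol, localizer_design)
            dof = acq.n_retained - 4
            p = 2 * sps.t.sf(np.abs(tmap), dof)
            hits += (p < 0.001).sum()
            total += tmap.size
        # binomial(total, 0.001): allow generous Monte Carlo slack
        assert hits < 0.004 * total

    def test_scan_count_mismatch_rejected(self, localizer_design):
        vol = np.zeros(GRID + (100,))
        with pytest.raises(ValueError, match="scan count"):
            localizer_contrast_map(vol, localizer_design)


class TestPatchSelection:
    def test_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(3)
        tmap = rng.normal(size=(10, 10, 10))
        mask = np.ones((10, 10, 10), bool)
        shape = (5, 3, 1)
        got = _best_patch(tmap, mask, shape)
        best, best_sum = None, -np.inf
        for i in range(6):
            for j in range(8):
                for k in range(10):
                    s = tmap[i:i + 5, j:j + 3, k:k + 1].sum()
                    if s > best_sum + 1e-12:
                        best_sum, best = s, (i, j, k)
        expect = {(best[0] + a, best[1] + b, best[2])
                  for a in range(5) for b in range(3)}
        assert got == expect

    def test_tie_breaks_to_smallest_index(self):
        tmap = np.zeros((6, 6, 1))
        tmap[0, 0, 0] = tmap[4, 4, 0] = 5.0  # two equal single-voxel maxima
        got = _best_patch(tmap, np.ones((6, 6, 1), bool), (1, 1, 1))
        assert got == {(0, 0, 0)}

    def test_patch_covers_planted_hotspot_per_hemisphere(self, localizer_design):
        acq = _acq()
        active = [(2, 5, 1), (2, 6, 1), (9, 5, 2), (9, 6, 2)]
        vol, _ = simulate_localizer_volume(localizer_design, acq, active, seed=4,
                                           amplitude_pct=3.0)
        tmap = localizer_contrast_map(vol, localizer_design)
        masks = {"left": box_mask(GRID, (0, 0, 0), (6, 12, 4)),
                 "right": box_mask(GRID, (6, 0, 0), (12, 12, 4))}
        patches = select_ffa_patches(tmap, masks, patch_shape=(3, 3, 1))
        assert {(2, 5, 1), (2, 6, 1)} <= patches["left"]
        assert {(9, 5, 2), (9, 6, 2)} <= patches["right"]

    def test_mask_smaller_than_patch_rejected(self):
        tmap = np.zeros((6, 6, 2))
        masks = {"left": box_mask((6, 6, 2), (0, 0, 0), (2, 2, 1)),
                 "right": box_mask((6, 6, 2), (3, 0, 0), (6, 6, 2))}
        with pytest.raises(ValueError, match="patch"):
            select_ffa_patches(tmap, masks, patch_shape=(5, 3, 1))

    def test_recovery_rate_at_moderate_snr(self, localizer_design):
        """Selected patches overlap truth (Jaccard >= 0.5) in >= 90% of replicates."""
        acq = _acq((10, 10, 2))
        truth_l = {(2, 4, 1), (2, 5, 1), (3, 4, 1), (3, 5, 1)}
        truth_r = {(7, 4, 1), (7, 5, 1), (8, 4, 1), (8, 5, 1)}
        masks = {"left": box_mask((10, 10, 2), (0, 0, 0), (5, 10, 2)),
                 "right": box_mask((10, 10, 2), (5, 0, 0), (10, 10, 2))}
        ok = 0
        n_rep = 100
        for seed in range(n_rep):
            vol, _ = simulate_localizer_volume(
                localizer_design, acq, sorted(truth_l | truth_r), seed=seed,
                amplitude_pct=1.0, noise_sd=5.0)  # effect 10 a.u. vs noise 5
            tmap = localizer_contrast_map(vol, localizer_design)
            patches = select_ffa_patches(tmap, masks, patch_shape=(2, 2, 1))
            jacc = [len(patches["left"] & truth_l) / len(patches["left"] | truth_l),
                    len(patches["right"] & truth_r) / len(patches["right"] | truth_r)]
            ok += min(jacc) >= 0.5
        assert ok >= 0.9 * n_rep


class TestReferenceRoi:
    def test_default_slab_has_27_voxels(self):
        voxels = select_reference_roi((20, 20, 5), corner=(5, 8, 2))
        assert len(voxels) == 27  # 9 x 3 x 1

    def test_out_of_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            select_reference_roi((8, 8, 2), corner=(5, 0, 0))

    def test_overlap_with_feedback_patch_rejected(self):
        patch = frozenset({(5, 8, 2)})
        with pytest.raises(ValueError, match="overlap"):
            select_reference_roi((20, 20, 5), corner=(5, 8, 2), avoid=patch)


class TestRoiSpec:
    def _spec(self):
        return RoiSpec(
            roi1_left=frozenset({(1, 1, 0), (1, 2, 0)}),
            roi1_right=frozenset({(8, 1, 0), (8, 2, 0)}),
            roi2_reference=frozenset({(4, 8, 1)}),
        )

    def test_json_round_trip(self, tmp_path):
        spec = self._spec()
        path = tmp_path / "spec.json"
        spec.to_json(path)
        back = RoiSpec.from_json(path)
        assert back.roi1_left == spec.roi1_left
        assert back.roi2_reference == spec.roi2_reference
        assert RoiSpec.from_json(spec.to_json()).roi1_right == spec.roi1_right

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RoiSpec(roi1_left=frozenset({(1, 1, 0)}),
                    roi1_right=frozenset({(1, 1, 0)}),
                    roi2_reference=frozenset({(4, 8, 1)}))

    def test_label_volume_codes(self):
        vol = self._spec().to_label_volume((10, 10, 2))
        assert vol[1, 1, 0] == 1 and vol[8, 1, 0] == 2 and vol[4, 8, 1] == 3
        assert (vol == 0).sum() == 200 - 5

    def test_build_roi_spec_is_deterministic(self, localizer_design):
        acq = _acq((10, 10, 2))
        vol, _ = simulate_localizer_volume(localizer_design, acq, [(2, 2, 0),
                                                                   (7, 2, 0)],
                                           seed=6, amplitude_pct=3.0)
        tmap = localizer_contrast_map(vol, localizer_design)
        masks = {"left": box_mask((10, 10, 2), (0, 0, 0), (5, 10, 2)),
                 "right": box_mask((10, 10, 2), (5, 0, 0), (10, 10, 2))}
        a = build_roi_spec(tmap, masks, (0, 7, 1), patch_shape=(2, 2, 1),
                           reference_shape=(5, 2, 1))
        b = build_roi_spec(tmap, masks, (0, 7, 1), patch_shape=(2, 2, 1),
                           reference_shape=(5, 2, 1))
        assert a.roi1_left == b.roi1_left and a.roi2_reference == b.roi2_reference
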