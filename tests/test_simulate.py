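import numpy as np
import pytest

from nfloop import (
    AcquisitionSpec,
    SubjectParams,
    block_correlation,
    read_dataset,
    rffa,
    simulate_localizer_volume,
    simulate_network_run,
    simulate_roi_run,
    write_dataset,
)


class TestSubjectParams:
    @pytest.mark.parametrize("kwargs", [
        {"baseline_level": 0.0}, {"noise_sd": -1.0}, {"spike_prob": 1.5},
        {"ar_coefficient": 1.0}, {"drift_slope": float("nan")},
        {"group": "XX"},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SubjectParams(**kwargs)

    def test_correlation_matrix_validated(self):
        bad = np.array([[1.0, 0.9], [0.2, 1.0]])  # asymmetric
        with pytest.raises(ValueError, match="symmetric"):
            SubjectParams(network_labels=("a", "b"), network_correlation=bad)
        neg = np.array([[1.0, 1.2], [1.2, 1.0]])  # eigenvalue < 0
        with pytest.raises(ValueError, match="semi-definite"):
            SubjectParams(network_labels=("a", "b"), network_correlation=neg)


class TestRoiRun:
    def test_deterministic_given_seed(self, training_design, default_params):
        a = simulate_roi_run(training_design, default_params, seed=42)
        b = simulate_roi_run(training_design, default_params, seed=42)
        c = simulate_roi_run(training_design, default_params, seed=43)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_noiseless_gain_recovered_within_hrf_tolerance(self, training_design,
                                                           quiet_params):
        series = simulate_roi_run(training_design, quiet_params, "roi1_left", seed=0)
        r = rffa(series)
        assert abs(r - 0.3) / 0.3 < 0.15

    def test_zero_gain_gives_zero_psc(self, training_design):
        p = SubjectParams(noise_sd=0.0, drift_slope=0.0, spike_prob=0.0,
                          regulation_gain={})
        series = simulate_roi_run(training_design, p, seed=0)
        assert rffa(series) == pytest.approx(0.0, abs=1e-12)

    def test_null_psc_unbiased_over_replicates(self, training_design):
        """With gain 0 and default noise the across-run mean r_FFA is ~0."""
        p = SubjectParams(regulation_gain={})
        vals = np.array([
            rffa(simulate_roi_run(training_design, p, seed=5000 + i))
            for i in range(200)
        ])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_series_length_excludes_dummies(self, training_design, default_params):
        s = simulate_roi_run(training_design, default_params, seed=1)
        assert len(s.values) == 140


class TestNetworkRun:
    def _params(self, r=0.6, **kw):
        corr = np.array([[1.0, r], [r, 1.0]])
        defaults = dict(network_labels=("seed", "target"), network_correlation=corr,
                        regulation_gain={}, drift_slope=0.0, spike_prob=0.0)
        defaults.update(kw)
        return SubjectParams(**defaults)

    def test_planted_correlation_recovered(self, training_design):
        """Mean block-restricted r over 10 runs within 0.1 of the target."""
        p = self._params(0.6)
        rs = []
        for i in range(10):
            run = simulate_network_run(training_design, p, seed=200 + i)
            rs.append(block_correlation(run["seed"].values, run["target"].values,
                                        training_design))
        assert abs(np.mean(rs) - 0.6) < 0.1

    def test_identity_target_gives_independent_series(self, training_design):
        p = self._params(0.0)
        rs = [
            block_correlation(
                *(simulate_network_run(training_design, p, seed=300 + i)[k].values
                  for k in ("seed", "target")),
                training_design,
            )
            for i in range(20)
        ]
        assert abs(np.mean(rs)) < 0.08

    def test_requires_network_spec(self, training_design, default_params):
        with pytest.raises(ValueError, match="network"):
            simulate_network_run(training_design, default_params, seed=0)


class TestLocalizerVolume:
    def test_signal_only_at_active_voxels(self, localizer_design):
        acq = AcquisitionSpec(n_scans_total=166, grid_shape=(6, 6, 2))
        vol, mask = simulate_localizer_volume(localizer_design, acq, [(2, 3, 1)],
                                              seed=0, noise_sd=0.0)
        flat_var = vol.var(axis=-1)
        assert np.unravel_index(np.argmax(flat_var), mask.shape) == (2, 3, 1)
        assert mask.sum() == 1

    def test_active_voxel_outside_grid_rejected(self, localizer_design):
        acq = AcquisitionSpec(n_scans_total=166, grid_shape=(6, 6, 2))
        with pytest.raises(ValueError, match="outside grid"):
            simulate_localizer_volume(localizer_design, acq, [(6, 0, 0)], seed=0)

    def test_deterministic(self, localizer_design):
        acq = AcquisitionSpec(n_scans_total=166, grid_shape=(4, 4, 2))
        a, _ = simulate_localizer_volume(localizer_design, acq, [(1, 1, 1)], seed=9)
        b, _ = simulate_localizer_volume(localizer_design, acq, [(1, 1, 1)], seed=9)
        assert np.array_equal(a, b)


class TestDatasetRoundTrip:
    def test_series_designs_params_survive(self, tmp_path, training_design, acq,
                                           default_params):
        runs = []
        for ses in (1, 2):
            series = {
                roi: simulate_roi_run(training_design, default_params, roi,
                                      seed=ses * 10, subject="sub-01",
                                      session=ses, run=1)
                for roi in ("roi1_left", "roi2")
            }
            runs.append({"session": ses, "run": 1, "series": series})
        dataset = {"sub-01": {"params": default_params, "acquisition": acq,
                              "runs": runs}}
        out = write_dataset(dataset, tmp_path / "missing" / "nested")
        back = read_dataset(out)
        orig = dataset["sub-01"]["runs"][0]["series"]["roi1_left"].values
        got = back["sub-01"]["runs"][0]["series"]["roi1_left"].values
        assert np.array_equal(orig, got)  # bit-for-bit at full TSV precision
        assert back["sub-01"]["params"].noise_sd == default_params.noise_sd
        assert back["sub-01"]["runs"][0]["series"]["roi1_left"].design == training_design

    def test_events_file_places_first_regulate_at_45s(self, tmp_path,
                                                      training_design, acq,
                                                      default_params):
        import pandas as pd

        series = {"roi1_left": simulate_roi_run(training_design, default_params,
                                                seed=0)}
        write_dataset({"sub-01": {"params": default_params, "acquisition": acq,
                                  "runs": [{"session": 1, "run": 1,
                                            "series": series}]}}, tmp_path)
        ev = pd.read_csv(tmp_path / "sub-01" / "ses-1" /
                         "sub-01_ses-1_run-1_events.tsv", sep="\t")
        assert ev[ev.trial_type == "regulate"].iloc[0]["onset"] == 45.0
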