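import numpy as np
import pytest

from nfloop import (
    AcquisitionSpec,
    SubjectParams,
    make_localizer_design,
    make_training_design,
    simulate_roi_run,
)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def training_design(acq):
    return make_training_design(acq)


@pytest.fixture(scope="session")
def localizer_design():
    return make_localizer_design(AcquisitionSpec(n_scans_total=166))


@pytest.fixture
def quiet_params():
    """Noise-free subject: isolates the planted regulation response."""
    return SubjectParams(noise_sd=0.0, drift_slope=0.0, spike_prob=0.0,
                         regulation_gain={"roi1_left": 0.3, "roi1_right": 0.3,
                                          "roi2": 0.0})


@pytest.fixture
def default_params():
    return SubjectParams()


@pytest.fixture
def feedback_series(training_design):
    """Factory: the three feedback-ROI series for one simulated run."""

    def make(params=None, seed=0):
        params = params or SubjectParams()
        return {
            roi: simulate_roi_run(training_design, params, roi, seed=seed + i)
            for i, roi in enumerate(("roi1_left", "roi1_right", "roi2"))
        }

    return make


def constant_block_series(design, levels, roi="roi1_left"):
    """Piecewise-constant run: one level per condition label."""
    from nfloop import RoiBoldSeries

    labels = design.retained_labels()
    values = np.array([levels[lab] for lab in labels], dtype=float)
    return RoiBoldSeries(subject="sub-01", session=1, run=1, roi=roi,
                         values=values, design=design)
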