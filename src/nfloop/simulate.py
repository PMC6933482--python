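"""Ground-truth-known synthetic BOLD data.

Generates per-ROI time series and small 4-D volumes with the timing, noise
and group structure the downstream analyses assume: a baseline level around
1000 arbitrary units, a planted regulation gain expressed in percent of
baseline (HRF-convolved boxcar), linear scanner drift, stationary AR(1)
Gaussian noise, occasional one-sided positive signal spikes (head motion /
swallowing artifacts), and optionally a planted inter-ROI correlation
structure for connectivity recovery experiments.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .design import AcquisitionSpec, BlockDesign, condition_regressor

logger = logging.getLogger(__name__)

GROUPS = ("AG", "CG1", "CG2sham")

#: Canonical feedback ROI labels: bilateral fusiform face area patches and
#: the reference slab anterior to the third ventricle.
FEEDBACK_ROIS = ("roi1_left", "roi1_right", "roi2")


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters for one simulated participant.

    ``regulation_gain`` maps ROI label -> planted percent signal change in
    regulation blocks.  Defaults put the contingent effect near the 0.1-0.4%
    scale typical of single-ROI neurofeedback, on a baseline of 1000 a.u.
    ``noise_sd`` is the stationary (marginal) SD of the AR(1) process.
    """

    group: str = "AG"
    baseline_level: float = 1000.0
    regulation_gain: dict = field(
        default_factory=lambda: {"roi1_left": 0.28, "roi1_right": 0.28, "roi2": 0.0}
    )
    ar_coefficient: float = 0.3
    noise_sd: float = 5.0
    drift_slope: float = 0.01
    spike_prob: float = 0.01
    spike_magnitude: float = 30.0
    network_labels: tuple = ()
    network_correlation: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not self.baseline_level > 0:
            raise ValueError("baseline_level must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if not 0 <= self.spike_prob <= 1:
            raise ValueError("spike_prob must lie in [0, 1]")
        for name in ("baseline_level", "noise_sd", "drift_slope", "spike_prob",
                     "spike_magnitude", "ar_coefficient"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.network_correlation is not None:
            c = np.asarray(self.network_correlation, dtype=float)
            if c.shape != (len(self.network_labels),) * 2:
                raise ValueError("network_correlation shape must match network_labels")
            if not np.allclose(c, c.T):
                raise ValueError("network_correlation must be symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError("network_correlation must have a unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("network_correlation must be positive semi-definite")

    def gain_for(self, roi: str) -> float:
        return float(self.regulation_gain.get(roi, 0.0))


@dataclass(frozen=True)
class RoiBoldSeries:
    """Mean BOLD time series of one ROI for one run (dummy scans removed)."""

    subject: str
    session: int
    run: int
    roi: str
    values: np.ndarray
    design: BlockDesign

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(v) != self.design.acquisition.n_retained:
            raise ValueError(
                f"series length {len(v)} != retained scans "
                f"{self.design.acquisition.n_retained}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("series values must be finite")
        if not 1 <= self.session <= 2:
            raise ValueError(f"session must be 1 or 2, got {self.session}")
        if not 1 <= self.run <= 8:
            raise ValueError(f"run must lie in 1..8, got {self.run}")

    @property
    def acquisition(self) -> AcquisitionSpec:
        return self.design.acquisition


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float,
         innovations: np.ndarray | None = None) -> np.ndarray:
    """Stationary AR(1) path with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    if innovations is None:
        innovations = rng.standard_normal(n)
    e = innovations * (sd * np.sqrt(1.0 - phi**2))
    e = e.copy()
    e[0] = innovations[0] * sd  # stationary start: x0 has the marginal SD
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -phi], e)


def _noise_components(rng, n, params: SubjectParams, innovations=None) -> np.ndarray:
    noise = _ar1(rng, n, params.ar_coefficient, params.noise_sd, innovations)
    drift = params.drift_slope * np.arange(n)
    spikes = np.zeros(n)
    if params.spike_prob > 0:
        hits = rng.random(n) < params.spike_prob
        spikes[hits] = params.spike_magnitude
    return noise + drift + spikes


def simulate_roi_run(
    design: BlockDesign,
    params: SubjectParams,
    roi: str = "roi1_left",
    seed: int = 0,
    subject: str = "sub-01",
    session: int = 1,
    run: int = 1,
) -> RoiBoldSeries:
    """Simulate one ROI's run: baseline x (1 + gain * HRF-boxcar / 100) + noise.

    The regulation response is the HRF-convolved regulate-block boxcar scaled
    by the planted gain (percent of baseline); dummy scans are generated and
    then discarded from the returned series.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = design.acquisition.n_scans_total
    resp = condition_regressor(design, "regulate", retained=False)
    if not design.blocks_for("regulate"):
        resp = np.zeros(n)
    signal = params.baseline_level * (1.0 + params.gain_for(roi) * resp / 100.0)
    values = signal + _noise_components(rng, n, params)
    return RoiBoldSeries(
        subject=subject, session=session, run=run, roi=roi,
        values=values[design.acquisition.n_dummy :], design=design,
    )


def _correlation_sqrt(corr: np.ndarray) -> np.ndarray:
    """Symmetric matrix square root; rejects non-PSD input."""
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-10:
        raise ValueError(f"correlation matrix is not positive semi-definite (min eig {w.min():.3g})")
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T


def simulate_network_run(
    design: BlockDesign,
    params: SubjectParams,
    seed: int = 0,
    subject: str = "sub-01",
    session: int = 1,
    run: int = 1,
) -> dict[str, RoiBoldSeries]:
    """Simulate a set of ROIs whose AR(1) noise shares a target correlation.

    Innovations are drawn independently and mixed through the symmetric
    square root of ``params.network_correlation``; as the series lengthen the
    empirical inter-ROI correlation converges to the target (all ROIs share
    the AR coefficient, so the mixing survives the recursion).
    """
    if params.network_correlation is None or not params.network_labels:
        raise ValueError("params must define network_labels and network_correlation")
    labels = list(params.network_labels)
    corr = np.asarray(params.network_correlation, dtype=float)
    root = _correlation_sqrt(corr)
    rng = np.random.default_rng(seed)
    n = design.acquisition.n_scans_total
    z = rng.standard_normal((n, len(labels))) @ root.T
    out = {}
    for j, roi in enumerate(labels):
        resp = condition_regressor(design, "regulate", retained=False)
        signal = params.baseline_level * (1.0 + params.gain_for(roi) * resp / 100.0)
        values = signal + _noise_components(rng, n, params, innovations=z[:, j])
        out[roi] = RoiBoldSeries(
            subject=subject, session=session, run=run, roi=roi,
            values=values[design.acquisition.n_dummy :], design=design,
        )
    return out


def simulate_localizer_volume(
    design: BlockDesign,
    acq: AcquisitionSpec,
    active_voxels: list[tuple[int, int, int]],
    seed: int = 0,
    baseline_level: float = 1000.0,
    amplitude_pct: float = 1.0,
    noise_sd: float = 5.0,
    condition: str = "faces",
) -> tuple[np.ndarray, np.ndarray]:
    """Small 4-D localizer volume with a planted condition response.

    Voxels in ``active_voxels`` carry an HRF-convolved ``condition`` boxcar of
    ``amplitude_pct`` percent of baseline; every voxel carries white Gaussian
    noise.  Returns ``(volume, truth_mask)`` where the volume has shape
    ``grid_shape + (n_retained,)`` and the mask flags the planted voxels.
    """
    shape = acq.grid_shape
    for v in active_voxels:
        if len(v) != 3 or any(not 0 <= v[i] < shape[i] for i in range(3)):
            raise ValueError(f"active voxel {v} outside grid {shape}")
    rng = np.random.default_rng(seed)
    nt = acq.n_retained
    resp = condition_regressor(design, condition, retained=True)
    vol = baseline_level + rng.normal(0.0, noise_sd, size=shape + (nt,))
    mask = np.zeros(shape, dtype=bool)
    bump = baseline_level * amplitude_pct / 100.0 * resp
    for v in active_voxels:
        vol[tuple(v)] += bump
        mask[tuple(v)] = True
    return vol, mask


# ----------------------------------------------------------------------
# Dataset on disk: TSV series, BIDS-style events, JSON parameter sidecars.
# ----------------------------------------------------------------------

def _params_to_json(params: SubjectParams) -> dict:
    d = {
        "group": params.group,
        "baseline_level": params.baseline_level,
        "regulation_gain": dict(params.regulation_gain),
        "ar_coefficient": params.ar_coefficient,
        "noise_sd": params.noise_sd,
        "drift_slope": params.drift_slope,
        "spike_prob": params.spike_prob,
        "spike_magnitude": params.spike_magnitude,
        "seed": params.seed,
    }
    if params.network_correlation is not None:
        d["network_labels"] = list(params.network_labels)
        d["network_correlation"] = np.asarray(params.network_correlation).tolist()
    return d


def _params_from_json(d: dict) -> SubjectParams:
    kw = dict(d)
    if "network_correlation" in kw:
        kw["network_correlation"] = np.asarray(kw["network_correlation"], dtype=float)
        kw["network_labels"] = tuple(kw.get("network_labels", ()))
    return SubjectParams(**kw)


def write_dataset(dataset: dict, out_dir: str | Path) -> Path:
    """Write a simulated dataset as a TSV/JSON file tree.

    ``dataset`` maps subject id -> ``{"params": SubjectParams,
    "acquisition": AcquisitionSpec, "runs": [{"session", "run",
    "series": {roi: RoiBoldSeries}}, ...]}``.  Series go to wide TSV (one
    column per ROI, full float precision), designs to BIDS-style events TSV
    (onset/duration/trial_type in seconds from the first acquired scan), and
    parameters to JSON sidecars.  Round-trips losslessly through
    :func:`read_dataset`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub, entry in dataset.items():
        sub_dir = out / sub
        sub_dir.mkdir(exist_ok=True)
        acq = entry["acquisition"]
        sidecar = {
            "params": _params_to_json(entry["params"]),
            "acquisition": {
                "tr": acq.tr, "n_dummy": acq.n_dummy,
                "n_scans_total": acq.n_scans_total,
                "grid_shape": list(acq.grid_shape),
                "voxel_size": list(acq.voxel_size),
            },
        }
        (sub_dir / "params.json").write_text(json.dumps(sidecar, indent=2))
        for rec in entry["runs"]:
            ses_dir = sub_dir / f"ses-{rec['session']}"
            ses_dir.mkdir(exist_ok=True)
            stem = f"{sub}_ses-{rec['session']}_run-{rec['run']}"
            series = rec["series"]
            frame = pd.DataFrame({roi: s.values for roi, s in series.items()})
            # default (shortest-repr) float formatting round-trips bit-for-bit
            frame.to_csv(ses_dir / f"{stem}_bold.tsv", sep="\t", index=False)
            any_series = next(iter(series.values()))
            any_series.design.to_events().to_csv(
                ses_dir / f"{stem}_events.tsv", sep="\t", index=False
            )
    logger.info("wrote dataset for %d subjects to %s", len(dataset), out)
    return out


def read_dataset(in_dir: str | Path) -> dict:
    """Inverse of :func:`write_dataset`."""
    root = Path(in_dir)
    dataset = {}
    for sub_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        sidecar = json.loads((sub_dir / "params.json").read_text())
        acq_d = sidecar["acquisition"]
        acq = AcquisitionSpec(
            tr=acq_d["tr"], n_dummy=acq_d["n_dummy"],
            n_scans_total=acq_d["n_scans_total"],
            grid_shape=tuple(acq_d["grid_shape"]),
            voxel_size=tuple(acq_d["voxel_size"]),
        )
        runs = []
        for bold_path in sorted(sub_dir.glob("ses-*/*_bold.tsv")):
            stem = bold_path.name[: -len("_bold.tsv")]
            parts = dict(p.split("-", 1) for p in stem.split("_")[1:])
            session, run = int(parts["ses"]), int(parts["run"])
            events = pd.read_csv(bold_path.with_name(f"{stem}_events.tsv"), sep="\t")
            design = BlockDesign.from_events(events, acq)
            frame = pd.read_csv(bold_path, sep="\t", float_precision="round_trip")
            series = {
                roi: RoiBoldSeries(
                    subject=sub_dir.name, session=session, run=run, roi=roi,
                    values=frame[roi].to_numpy(), design=design,
                )
                for roi in frame.columns
            }
            runs.append({"session": session, "run": run, "series": series})
        dataset[sub_dir.name] = {
            "params": _params_from_json(sidecar["params"]),
            "acquisition": acq,
            "runs": runs,
        }
    return dataset
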