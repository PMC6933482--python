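"""Closed-loop feedback computation, replayed as a streaming algorithm.

The feedback presented to the participant every TR during regulation blocks
is

    F = (BOLD_upreg - BOLD_base)_ROI1 - (BOLD_upreg - BOLD_base)_ROI2

where BOLD_upreg is the mean over a moving window of the last (up to) three
accepted scans of the current regulation block, BOLD_base the mean of the
preceding baseline block, ROI1 the average of the left and right feedback
patches, and ROI2 a reference slab that cancels global activation.
Incoming samples pass an online despiking rule that replaces abrupt
increases with the mean of the preceding accepted samples.  Sham feedback
is a seeded bounded random walk, independent of the brain data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BlockDesign
from .simulate import RoiBoldSeries

ROI1_PARTS = ("roi1_left", "roi1_right")
REFERENCE_ROI = "roi2"


@dataclass(frozen=True)
class FeedbackConfig:
    """Despike and display parameters for one feedback session."""

    despike_k: float = 3.0
    despike_m: int = 3
    despike_reference: bool = True  # also despike the ROI2 slab
    baseline_trim: int = 0  # scans dropped from the start of each baseline block
    n_bars: int = 10
    scale: float = 1.0  # F units per thermometer bar (0.1% of a 1000-a.u. baseline)
    sham_step_sd: float = 1.0
    sham_bound: float | None = None  # defaults to (n_bars / 2) * scale

    def __post_init__(self) -> None:
        if self.despike_m < 2:
            raise ValueError("despike window m must be >= 2")
        if self.n_bars < 1 or self.scale <= 0:
            raise ValueError("need n_bars >= 1 and scale > 0")

    @property
    def bound(self) -> float:
        return self.sham_bound if self.sham_bound is not None else self.n_bars / 2 * self.scale


@dataclass
class FeedbackTrace:
    """Per-update feedback record for one regulation run."""

    frame: pd.DataFrame  # columns: scan, block, F, level
    contingent: bool
    n_bars: int
    scale: float

    def __post_init__(self) -> None:
        levels = self.frame["level"].to_numpy()
        if len(levels) and (levels.min() < 0 or levels.max() > self.n_bars):
            raise ValueError("thermometer levels out of range")

    @property
    def f_values(self) -> np.ndarray:
        return self.frame["F"].to_numpy()

    @property
    def levels(self) -> np.ndarray:
        return self.frame["level"].to_numpy()


def despike_online(
    history: np.ndarray | list,
    incoming: float,
    k: float = 3.0,
    m: int = 3,
    two_sided: bool = False,
) -> float:
    """Accept or replace one incoming sample against its recent history.

    A sample is a spike when it exceeds the median of the last ``m`` accepted
    samples by more than ``k`` robust SDs; spikes are replaced by the mean of
    those samples.  One-sided (increases only) by default, matching the
    artifacts this guards against (motion and swallowing transients push the
    signal up).  The robust SD is 1.4826*MAD with a small floor relative to
    the signal level so a near-constant history does not reject ordinary
    noise.
    """
    if m < 2:
        raise ValueError("despike window m must be >= 2")
    hist = np.asarray(history, dtype=float)
    if hist.size == 0:
        return float(incoming)
    w = hist[-m:]
    med = np.median(w)
    scale = 1.4826 * np.median(np.abs(w - med))
    scale = max(scale, 1e-3 * max(abs(med), 1.0))
    dev = incoming - med
    spike = dev > k * scale or (two_sided and -dev > k * scale)
    return float(np.mean(w)) if spike else float(incoming)


def thermometer_level(f: float, n_bars: int = 10, scale: float = 1.0) -> int:
    """Map a feedback value to a thermometer bar count; F = 0 is the center bar."""
    return int(np.clip(round(n_bars / 2 + f / scale), 0, n_bars))


def sham_trace(
    n_updates: int,
    seed: int,
    config: FeedbackConfig | None = None,
    update_scans: np.ndarray | None = None,
    update_blocks: np.ndarray | None = None,
) -> FeedbackTrace:
    """Pseudorandom (non-contingent) feedback: a reflected Gaussian walk.

    The walk lives on the feedback scale, starts at 0 (center bar) and
    reflects at ``+/- config.bound``; it is a pure function of
    ``(n_updates, seed, config)``.
    """
    cfg = config or FeedbackConfig()
    rng = np.random.default_rng(seed)
    b = cfg.bound
    f = np.empty(n_updates)
    x = 0.0
    for i in range(n_updates):
        x += rng.normal(0.0, cfg.sham_step_sd)
        # reflect into [-b, b]
        while abs(x) > b:
            x = np.sign(x) * (2 * b) - x
        f[i] = x
    frame = pd.DataFrame(
        {
            "scan": update_scans if update_scans is not None else np.arange(n_updates),
            "block": update_blocks if update_blocks is not None else np.zeros(n_updates, int),
            "F": f,
            "level": [thermometer_level(v, cfg.n_bars, cfg.scale) for v in f],
        }
    )
    return FeedbackTrace(frame, contingent=False, n_bars=cfg.n_bars, scale=cfg.scale)


@dataclass
class OnlineState:
    """Streaming state: accepted samples per ROI plus baseline bookkeeping."""

    config: FeedbackConfig
    accepted: dict = field(default_factory=lambda: {r: [] for r in ROI1_PARTS + (REFERENCE_ROI,)})
    baseline_mean: dict = field(default_factory=dict)  # roi -> mean of preceding baseline block
    block_label: str = ""
    block_start: int = 0  # index into accepted history where the current block began

    def ingest(self, scan_values: dict, label: str, scan_index: int) -> None:
        if label != self.block_label:
            # close the previous block: a completed baseline becomes the reference
            if self.block_label == "baseline":
                for roi, hist in self.accepted.items():
                    block = hist[self.block_start + self.config.baseline_trim :]
                    self.baseline_mean[roi] = float(np.mean(block))
            self.block_label = label
            self.block_start = len(next(iter(self.accepted.values())))
        for roi, hist in self.accepted.items():
            x = scan_values[roi]
            if roi != REFERENCE_ROI or self.config.despike_reference:
                x = despike_online(hist, x, self.config.despike_k, self.config.despike_m)
            hist.append(float(x))

    def feedback_value(self) -> float:
        """F for the scan just ingested; only valid inside a regulate block."""
        if self.block_label != "regulate":
            raise ValueError("feedback is only defined during regulate blocks")
        if not self.baseline_mean:
            raise ValueError("no preceding baseline block")
        window_means = {}
        for roi, hist in self.accepted.items():
            block = hist[self.block_start :]
            window_means[roi] = float(np.mean(block[-3:]))
        u1 = (window_means["roi1_left"] + window_means["roi1_right"]) / 2.0
        b1 = (self.baseline_mean["roi1_left"] + self.baseline_mean["roi1_right"]) / 2.0
        u2 = window_means[REFERENCE_ROI]
        b2 = self.baseline_mean[REFERENCE_ROI]
        return (u1 - b1) - (u2 - b2)


def run_feedback_session(
    series: dict[str, RoiBoldSeries],
    design: BlockDesign | None = None,
    mode: str = "contingent",
    config: FeedbackConfig | None = None,
    seed: int = 0,
) -> FeedbackTrace:
    """Replay one run scan-by-scan and emit one feedback update per regulate scan.

    ``series`` must contain ``roi1_left``, ``roi1_right`` and ``roi2`` of equal
    length.  In sham mode the brain data are ignored entirely and a seeded
    random walk of the same length is returned.
    """
    cfg = config or FeedbackConfig()
    missing = [r for r in ROI1_PARTS + (REFERENCE_ROI,) if r not in series]
    if missing:
        raise ValueError(f"missing ROI series: {missing}")
    design = design or next(iter(series.values())).design
    lengths = {len(s.values) for s in series.values()}
    if len(lengths) != 1:
        raise ValueError(f"ROI series lengths differ: {sorted(lengths)}")
    labels = design.retained_labels()
    if lengths != {len(labels)}:
        raise ValueError("series length does not match design")

    regulate_scans = np.flatnonzero(labels == "regulate")
    block_of = np.cumsum(np.r_[0, labels[1:] != labels[:-1]])
    if mode == "sham":
        return sham_trace(len(regulate_scans), seed, cfg,
                          update_scans=regulate_scans,
                          update_blocks=block_of[regulate_scans])
    if mode != "contingent":
        raise ValueError(f"mode must be 'contingent' or 'sham', got {mode!r}")

    state = OnlineState(config=cfg)
    records = []
    for t, label in enumerate(labels):
        state.ingest({roi: series[roi].values[t] for roi in state.accepted}, label, t)
        if label == "regulate":
            f = state.feedback_value()
            records.append((t, int(block_of[t]), f, thermometer_level(f, cfg.n_bars, cfg.scale)))
    frame = pd.DataFrame(records, columns=["scan", "block", "F", "level"])
    return FeedbackTrace(frame, contingent=True, n_bars=cfg.n_bars, scale=cfg.scale)


def batch_feedback(
    series: dict[str, RoiBoldSeries],
    design: BlockDesign | None = None,
    config: FeedbackConfig | None = None,
) -> np.ndarray:
    """Recompute every F from the full stored run by array slicing.

    Independent batch formulation of the streaming rule (despike each ROI
    sequentially over the whole run, then take window/baseline means by
    index); used to verify streaming/batch equivalence.
    """
    cfg = config or FeedbackConfig()
    design = design or next(iter(series.values())).design
    labels = design.retained_labels()
    n = len(labels)

    accepted = {}
    for roi in ROI1_PARTS + (REFERENCE_ROI,):
        raw = series[roi].values
        hist: list[float] = []
        for t in range(n):
            x = raw[t]
            if roi != REFERENCE_ROI or cfg.despike_reference:
                x = despike_online(hist, x, cfg.despike_k, cfg.despike_m)
            hist.append(float(x))
        accepted[roi] = np.asarray(hist)

    starts = np.flatnonzero(np.r_[True, labels[1:] != labels[:-1]])
    bounds = np.r_[starts, n]
    f_out = []
    base = {}
    for i, s in enumerate(starts):
        e = bounds[i + 1]
        label = labels[s]
        if label == "regulate":
            for t in range(s, e):
                win = slice(max(s, t - 2), t + 1)
                u1 = (accepted["roi1_left"][win].mean() + accepted["roi1_right"][win].mean()) / 2
                b1 = (base["roi1_left"] + base["roi1_right"]) / 2
                f_out.append((u1 - b1) - (accepted[REFERENCE_ROI][win].mean() - base[REFERENCE_ROI]))
        elif label == "baseline":
            for roi in accepted:
                base[roi] = accepted[roi][s + cfg.baseline_trim : e].mean()
    return np.asarray(f_out)


def write_trace(trace: FeedbackTrace, path) -> None:
    trace.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
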