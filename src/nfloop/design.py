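"""Run timing: acquisition specs, block designs, and HRF-convolved regressors.

A run is described by an :class:`AcquisitionSpec` (TR, dummy scans, totals)
plus a :class:`BlockDesign`, an ordered, contiguous partition of the scan
axis into labelled condition blocks.  The two canonical layouts are the
neurofeedback training run (10 dummy scans, then baseline/regulation blocks
of 30 s alternating B R B R B R B, 150 scans at TR = 1.5 s) and the
faces/houses functional localizer (166 scans).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from nilearn.glm.first_level import spm_hrf

CONDITIONS = ("dummy", "baseline", "regulate", "faces", "houses", "rest")

#: Stimulation block length in seconds shared by training and localizer runs.
BLOCK_SECONDS = 30.0


@dataclass(frozen=True)
class AcquisitionSpec:
    """EPI acquisition timing and geometry.

    Defaults mirror a 1.5 T protocol: TR 1.5 s, 10 dummy scans discarded
    to reach T1 steady state, 64 x 64 matrix with 16 slices.
    """

    tr: float = 1.5
    n_dummy: int = 10
    n_scans_total: int = 150
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    voxel_size: tuple[float, float, float] = (3.2, 3.3, 4.0)

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not 0 <= self.n_dummy < self.n_scans_total:
            raise ValueError(
                f"need 0 <= n_dummy < n_scans_total, got {self.n_dummy}, {self.n_scans_total}"
            )
        if len(self.grid_shape) != 3 or any(d < 1 for d in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")

    @property
    def n_retained(self) -> int:
        """Scans kept for analysis after discarding dummies."""
        return self.n_scans_total - self.n_dummy

    @property
    def duration_s(self) -> float:
        return self.n_scans_total * self.tr


class Block(NamedTuple):
    label: str
    onset_scan: int  # 0-based index into the full (pre-dummy-discard) run
    n_scans: int


@dataclass(frozen=True)
class BlockDesign:
    """Ordered, contiguous, non-overlapping condition blocks covering a run."""

    blocks: tuple[Block, ...]
    acquisition: AcquisitionSpec

    def __post_init__(self) -> None:
        cursor = 0
        for b in self.blocks:
            if b.label not in CONDITIONS:
                raise ValueError(f"unknown condition label {b.label!r}")
            if b.onset_scan != cursor:
                raise ValueError(
                    f"blocks must be contiguous: expected onset {cursor}, got {b.onset_scan}"
                )
            if b.n_scans < 1:
                raise ValueError("blocks must span at least one scan")
            cursor += b.n_scans
        if cursor != self.acquisition.n_scans_total:
            raise ValueError(
                f"blocks cover {cursor} scans but acquisition has "
                f"{self.acquisition.n_scans_total}"
            )

    def labels(self) -> np.ndarray:
        """Condition label per scan, full run including dummies."""
        out = np.empty(self.acquisition.n_scans_total, dtype=object)
        for b in self.blocks:
            out[b.onset_scan : b.onset_scan + b.n_scans] = b.label
        return out

    def retained_labels(self) -> np.ndarray:
        """Condition label per scan after dummy discard."""
        return self.labels()[self.acquisition.n_dummy :]

    def scans_for(self, label: str, retained: bool = True) -> np.ndarray:
        """Scan indices carrying ``label`` (0-based; retained axis by default)."""
        lab = self.retained_labels() if retained else self.labels()
        return np.flatnonzero(lab == label)

    def blocks_for(self, label: str) -> list[Block]:
        return [b for b in self.blocks if b.label == label]

    @property
    def duration_s(self) -> float:
        return self.acquisition.duration_s

    # ------------------------------------------------------------------
    # BIDS-style events round trip (onset/duration in seconds from the
    # first acquired, pre-discard scan).
    # ------------------------------------------------------------------
    def to_events(self) -> pd.DataFrame:
        tr = self.acquisition.tr
        return pd.DataFrame(
            {
                "onset": [b.onset_scan * tr for b in self.blocks],
                "duration": [b.n_scans * tr for b in self.blocks],
                "trial_type": [b.label for b in self.blocks],
            }
        )

    @classmethod
    def from_events(cls, events: pd.DataFrame, acquisition: AcquisitionSpec) -> "BlockDesign":
        tr = acquisition.tr
        blocks = []
        for _, row in events.sort_values("onset").iterrows():
            onset = int(round(row["onset"] / tr))
            n = int(round(row["duration"] / tr))
            blocks.append(Block(str(row["trial_type"]), onset, n))
        return cls(tuple(blocks), acquisition)


def make_training_design(acq: AcquisitionSpec) -> BlockDesign:
    """Neurofeedback training run layout: dummies, then B R B R B R B.

    Four baseline and three up-regulation blocks of 30 s each; with 10 dummy
    scans at TR 1.5 s the run is 150 scans (225 s = 3.75 min) and 140 scans
    enter analysis.
    """
    n_block = BLOCK_SECONDS / acq.tr
    if abs(n_block - round(n_block)) > 1e-9:
        raise ValueError(f"TR {acq.tr} does not divide the {BLOCK_SECONDS}-s block length")
    n_block = int(round(n_block))
    needed = acq.n_dummy + 7 * n_block
    if acq.n_scans_total != needed:
        raise ValueError(
            f"training layout needs {needed} scans "
            f"({acq.n_dummy} dummy + 7 x {n_block}), got {acq.n_scans_total}"
        )
    blocks = [Block("dummy", 0, acq.n_dummy)] if acq.n_dummy else []
    cursor = acq.n_dummy
    for i in range(7):
        label = "baseline" if i % 2 == 0 else "regulate"
        blocks.append(Block(label, cursor, n_block))
        cursor += n_block
    return BlockDesign(tuple(blocks), acq)


def make_localizer_design(
    acq: AcquisitionSpec,
    rest_scans: int | None = None,
    allow_nonstandard_total: bool = False,
) -> BlockDesign:
    """Faces/houses localizer: F H F H F H F stimulation blocks with rest gaps.

    Seven 30-s stimulation blocks (four faces, three houses, each 40 images
    at 750 ms) alternate, separated by rest.  The canonical run is 166
    volumes at TR 1.5 s (4.15 min); the printed 21-s rest gaps do not fit
    that total, so by default the gaps shrink to what the volume budget
    allows (2 scans) and residual scans are appended as terminal rest.
    Pass ``allow_nonstandard_total=True`` to build other totals, e.g. with
    the nominal 14-scan (21 s) gaps.
    """
    if acq.n_scans_total != 166 and not allow_nonstandard_total:
        raise ValueError(
            f"localizer expects 166 scans, got {acq.n_scans_total} "
            "(set allow_nonstandard_total=True to override)"
        )
    n_block = int(round(BLOCK_SECONDS / acq.tr))
    available = acq.n_scans_total - acq.n_dummy - 7 * n_block
    if rest_scans is None:
        rest_scans = available // 6
    if available < 6 * rest_scans or available < 0:
        raise ValueError(
            f"layout does not fit: {acq.n_scans_total} scans cannot host 7 x {n_block} "
            f"stimulation scans + 6 x {rest_scans} rest scans + {acq.n_dummy} dummies"
        )
    blocks = [Block("dummy", 0, acq.n_dummy)] if acq.n_dummy else []
    cursor = acq.n_dummy
    for i in range(7):
        label = "faces" if i % 2 == 0 else "houses"
        blocks.append(Block(label, cursor, n_block))
        cursor += n_block
        if i < 6 and rest_scans:
            blocks.append(Block("rest", cursor, rest_scans))
            cursor += rest_scans
    residual = acq.n_scans_total - cursor
    if residual:
        blocks.append(Block("rest", cursor, residual))
    return BlockDesign(tuple(blocks), acq)


from functools import lru_cache


@lru_cache(maxsize=8)
def _hrf_cached(tr: float) -> np.ndarray:
    h = spm_hrf(tr, oversampling=1)
    return h / h.sum()


def canonical_hrf(tr: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR, normalized to unit sum.

    Double-gamma with 6-s peak, 16-s undershoot, peak/undershoot ratio 6,
    32-s support.  Unit sum makes the plateau of a sustained convolved
    boxcar equal 1, so a planted gain is expressed in percent of baseline.
    """
    return _hrf_cached(tr).copy()


def condition_regressor(design: BlockDesign, label: str, retained: bool = True) -> np.ndarray:
    """HRF-convolved boxcar for one condition, on the full-run time axis.

    The convolution runs over the complete acquisition (dummies included)
    so early retained scans carry the correct transient; with
    ``retained=True`` dummy scans are then dropped.
    """
    box = (design.labels() == label).astype(float)
    h = canonical_hrf(design.acquisition.tr)
    reg = np.convolve(box, h)[: len(box)]
    return reg[design.acquisition.n_dummy :] if retained else reg
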