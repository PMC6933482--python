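"""Block-restricted seed-based functional connectivity.

Region time series are denoised (despike, linear detrend, confound
regression, 0.008-0.09 Hz band-pass), restricted to regulation-block
samples, and correlated seed-against-target per run:

    r = (x'x)^(-1/2) (x'y) (y'y)^(-1/2)

on mean-centered restricted samples, i.e. the product-moment correlation.
Per-run r values are Fisher-z transformed and averaged across runs; group
inference is a one-sample t on the z values per target with one-sided
(positive) p and Benjamini-Hochberg FDR across the targets of each seed
("seed-corrected" FDR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from scipy import stats as sps

from .design import BlockDesign
from .stats import fdr_bh

#: Ventral visual stream region labels used for subnetwork strength comparisons.
VENTRAL_VISUAL_STREAM = (
    "occipital_sup", "occipital_mid", "occipital_inf", "calcarine", "cuneus",
    "lingual", "fusiform", "parahippocampal", "temporal_inf", "temporal_pole_mid",
)


@dataclass(frozen=True)
class DenoiseConfig:
    """Denoising recipe applied before connectivity estimation."""

    band: tuple[float, float] = (0.008, 0.09)
    detrend: bool = True
    despike: bool = True
    despike_k: float = 3.0
    despike_window: int = 5  # rolling-median window, scans

    def validate(self, tr: float) -> None:
        low, high = self.band
        nyq = 0.5 / tr
        if not 0 < low < high < nyq:
            raise ValueError(f"band {self.band} must satisfy 0 < low < high < {nyq} Hz")


def _despike_two_sided(x: np.ndarray, k: float, window: int) -> np.ndarray:
    """Clamp samples deviating from a rolling median by more than k robust SDs.

    Two-sided, unlike the online feedback rule: offline artifacts can deflect
    either way once motion parameters are regressed.
    """
    med = ndimage.median_filter(x, size=window, mode="nearest")
    resid = x - med
    scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if scale == 0:
        return x.copy()
    return med + np.clip(resid, -k * scale, k * scale)


def denoise(
    series: np.ndarray,
    tr: float,
    confounds: np.ndarray | None = None,
    config: DenoiseConfig | None = None,
) -> np.ndarray:
    """Denoise (n_scans, n_rois) series: despike, detrend, regress, band-pass.

    Confounds are detrended identically before regression so the projection
    removes their fluctuating part rather than re-introducing drift.
    Deterministic.
    """
    cfg = config or DenoiseConfig()
    cfg.validate(tr)
    series = np.asarray(series, float)
    x = series[:, None] if series.ndim == 1 else series.copy()
    n = x.shape[0]
    if cfg.despike:
        x = np.column_stack([_despike_two_sided(x[:, j], cfg.despike_k, cfg.despike_window)
                             for j in range(x.shape[1])])
    if cfg.detrend:
        x = signal.detrend(x, axis=0, type="linear")
    if confounds is not None:
        c = np.atleast_2d(np.asarray(confounds, float))
        if c.shape[0] != n:
            c = c.T
        if c.shape[0] != n:
            raise ValueError(f"confound length {confounds.shape} does not match {n} scans")
        if cfg.detrend:
            c = signal.detrend(c, axis=0, type="linear")
        design = np.column_stack([np.ones(n), c])
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        x = x - design @ beta
    sos = signal.butter(2, cfg.band, btype="bandpass", fs=1.0 / tr, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=0)
    return x if series.ndim > 1 else x[:, 0]


def block_correlation(
    x: np.ndarray,
    y: np.ndarray,
    design: BlockDesign,
    condition: str = "regulate",
    shift: int = 0,
) -> float:
    """Correlation of two series restricted to one condition's samples.

    Samples are restricted to ``condition`` blocks (optionally shifted by
    ``shift`` scans of hemodynamic lag) and mean-centered within the
    restricted support; the normalized inner product of the centered
    restricted vectors is then the ordinary product-moment correlation.
    Zero variance on the restricted support is flagged as NaN.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    idx = design.scans_for(condition) + shift
    idx = idx[(idx >= 0) & (idx < len(x))]
    if idx.size < 3:
        raise ValueError(f"too few {condition!r} samples ({idx.size})")
    xr = x[idx] - x[idx].mean()
    yr = y[idx] - y[idx].mean()
    sx, sy = np.sqrt(xr @ xr), np.sqrt(yr @ yr)
    if sx == 0 or sy == 0:
        warnings.warn("zero variance on the restricted support; correlation undefined")
        return float("nan")
    return float((xr @ yr) / (sx * sy))


@dataclass
class SeedConnectivityMap:
    """Per-target connectivity of one seed with group-level FDR selection."""

    seed: str
    table: pd.DataFrame  # columns: target, r, z, t, p, selected
    q: float

    @property
    def selected(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "target"])


def seed_map(
    runs: list[dict[str, np.ndarray]],
    seed_label: str,
    design: BlockDesign,
    q: float = 0.01,
    condition: str = "regulate",
    shift: int = 0,
) -> SeedConnectivityMap:
    """Across-run seed connectivity with seed-corrected BH-FDR selection.

    ``runs`` is a list of per-run mappings label -> (already denoised)
    series; every non-seed label is a target.  Per run and target the
    block-restricted correlation is Fisher-z transformed; the across-run z
    values feed a one-sample t against zero with one-sided (positive) p,
    and BH selection at level ``q`` runs across this seed's targets.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for across-run inference")
    targets = [lab for lab in runs[0] if lab != seed_label]
    if not targets:
        raise ValueError("no target regions besides the seed")
    z_by_target = {}
    for target in targets:
        rs = [block_correlation(run[seed_label], run[target], design, condition, shift)
              for run in runs]
        z_by_target[target] = np.arctanh(np.asarray(rs))
    rows = []
    for target in targets:
        z = z_by_target[target]
        t, p = sps.ttest_1samp(z, 0.0, alternative="greater")
        rows.append({"target": target, "r": float(np.tanh(z.mean())),
                     "z": float(z.mean()), "t": float(t), "p": float(p)})
    table = pd.DataFrame(rows)
    table["selected"] = fdr_bh(table["p"].to_numpy(), q)
    return SeedConnectivityMap(seed=seed_label, table=table, q=q)


def strength_group_compare(
    z_by_group: dict[str, pd.DataFrame],
    subnetwork: tuple[str, ...] | None = VENTRAL_VISUAL_STREAM,
):
    """Compare connection strength (mean z) between groups within a subnetwork.

    ``z_by_group`` maps group label -> a frame with ``target`` and ``z``
    columns (one row per subject x connection).  Rows are restricted to the
    subnetwork label set (pass ``None`` for all areas) and the pooled z
    values per group feed the normality-gated omnibus comparison.
    """
    from .stats import compare_groups

    pooled = {}
    for group, frame in z_by_group.items():
        if subnetwork is not None:
            frame = frame[frame["target"].isin(subnetwork)]
        if frame.empty:
            raise ValueError(f"group {group!r}: no connections in the requested subnetwork")
        pooled[group] = frame["z"].to_numpy()
    return compare_groups(pooled)
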