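"""Simplified two-level activation analysis for the Regulation > Rest contrast.

First level: per-voxel OLS with HRF-convolved regulation and baseline
regressors, six motion confounds and an intercept; the contrast is
regulate - baseline.  Second level: a voxelwise one-sample t across
subjects' contrast maps with one-sided voxel thresholding (p < 0.001), a
Bonferroni family-wise-error mask (labelled as such in the provenance),
and removal of clusters below a minimum extent K under 6-connectivity.
Spatial smoothing is an explicit separable-Gaussian step, not an implicit
part of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from nilearn.glm.contrasts import compute_contrast
from nilearn.glm.first_level import run_glm
from scipy import ndimage
from scipy import stats as sps

from .design import BlockDesign, condition_regressor


@dataclass
class ContrastMap:
    """Effect and t maps with the thresholding provenance that produced them."""

    effect: np.ndarray
    t: np.ndarray
    provenance: dict = field(default_factory=dict)
    mask_uncorrected: np.ndarray | None = None
    mask_fwe: np.ndarray | None = None
    cluster_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.effect.shape != self.t.shape:
            raise ValueError("effect and t maps must share a shape")


def first_level(
    volume: np.ndarray,
    design: BlockDesign,
    motion_confounds: np.ndarray | None = None,
    conditions: tuple[str, str] = ("regulate", "baseline"),
) -> ContrastMap:
    """Per-voxel OLS contrast of ``conditions[0] - conditions[1]`` for one run.

    ``volume`` holds retained scans, shape ``grid + (n_retained,)``; motion
    confounds, when given, are six columns over the retained scans.
    """
    grid, nt = volume.shape[:-1], volume.shape[-1]
    if nt != design.acquisition.n_retained:
        raise ValueError("volume scan count does not match the design")
    regs = [condition_regressor(design, c) for c in conditions]
    cols = regs + [np.ones(nt)]
    names = list(conditions) + ["intercept"]
    if motion_confounds is not None:
        mc = np.asarray(motion_confounds, float)
        if mc.shape[0] != nt:
            raise ValueError("motion confounds must cover the retained scans")
        cols += [mc[:, j] for j in range(mc.shape[1])]
        names += [f"motion{j}" for j in range(mc.shape[1])]
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient first-level design")
    y = volume.reshape(-1, nt).T
    labels, results = run_glm(y, x, noise_model="ols")
    con = np.zeros(x.shape[1])
    con[0], con[1] = 1.0, -1.0
    contrast = compute_contrast(labels, results, con, stat_type="t")
    return ContrastMap(
        effect=np.asarray(contrast.effect_size()).reshape(grid),
        t=np.asarray(contrast.stat()).reshape(grid),
        provenance={"level": 1, "regressors": names, "contrast": list(con)},
    )


def label_clusters(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components of a boolean mask under 6-connectivity."""
    structure = ndimage.generate_binary_structure(3, 1)
    return ndimage.label(mask, structure=structure)


def _prune_clusters(mask: np.ndarray, k: int, tmap: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    labels, n = label_clusters(mask)
    keep = np.zeros_like(mask)
    rows = []
    for lab in range(1, n + 1):
        cluster = labels == lab
        size = int(cluster.sum())
        if size >= k:
            keep |= cluster
            peak_flat = np.flatnonzero(cluster.ravel())[np.argmax(tmap[cluster])]
            rows.append({
                "size": size,
                "peak_t": float(tmap[cluster].max()),
                "peak_index": tuple(int(i) for i in np.unravel_index(peak_flat, mask.shape)),
            })
    rows.sort(key=lambda r: -r["size"])
    return keep, pd.DataFrame(rows, columns=["size", "peak_t", "peak_index"])


def second_level(
    contrast_maps: list[ContrastMap] | list[np.ndarray],
    voxel_p: float = 0.001,
    fwe_p: float = 0.05,
    k: int = 10,
) -> ContrastMap:
    """Voxelwise one-sample t across subjects with the study's thresholds.

    Reports both the uncorrected one-sided ``voxel_p`` mask and a
    Bonferroni-FWE mask at ``fwe_p``; clusters smaller than ``k`` voxels
    (6-connectivity) are removed from both.
    """
    effects = np.stack([
        m.effect if isinstance(m, ContrastMap) else np.asarray(m, float)
        for m in contrast_maps
    ])
    if effects.shape[0] < 3:
        raise ValueError("need at least 3 subject maps")
    t, p = sps.ttest_1samp(effects, 0.0, axis=0, alternative="greater")
    t = np.asarray(t)
    p = np.asarray(p)
    n_vox = t.size
    mask_unc, clusters = _prune_clusters(p < voxel_p, k, t)
    mask_fwe, _ = _prune_clusters(p * n_vox < fwe_p, k, t)
    return ContrastMap(
        effect=effects.mean(axis=0),
        t=t,
        provenance={
            "level": 2, "n_subjects": int(effects.shape[0]),
            "voxel_p": voxel_p, "fwe_p": fwe_p, "k": k,
            "fwe_method": "Bonferroni-FWE", "connectivity": 6,
        },
        mask_uncorrected=mask_unc,
        mask_fwe=mask_fwe,
        cluster_table=clusters,
    )


def smooth_volume(volume: np.ndarray, fwhm_mm: float,
                  voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Separable Gaussian smoothing (FWHM in mm, truncated at 4 SD).

    Applied over the three spatial axes only; a trailing time axis, if
    present, is left untouched.
    """
    sigmas = [fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v for v in voxel_size]
    if volume.ndim == 4:
        sigmas = sigmas + [0.0]
    return ndimage.gaussian_filter(volume, sigma=sigmas, truncate=4.0)
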