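"""Feedback ROI selection from a faces/houses localizer run.

A per-voxel GLM of the localizer (HRF-convolved faces and houses
regressors, intercept, linear drift) yields a Faces > Houses t map; the
bilateral feedback ROI (ROI1) is placed where an axis-aligned patch of
configured shape maximizes the summed t within each hemisphere's ventral
temporal search mask, and the reference ROI (ROI2) is a configured
transversal slab anterior to the third ventricle (in simulation its
location comes from config, as no anatomy exists).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from nilearn.glm.first_level import run_glm
from nilearn.glm.contrasts import compute_contrast
from numpy.lib.stride_tricks import sliding_window_view

from .design import BlockDesign, condition_regressor

VoxelSet = frozenset


@dataclass(frozen=True)
class RoiSpec:
    """The three feedback voxel sets: bilateral ROI1 patches and ROI2 slab."""

    roi1_left: frozenset
    roi1_right: frozenset
    roi2_reference: frozenset
    source: str = "localizer"

    def __post_init__(self) -> None:
        sets = {"roi1_left": self.roi1_left, "roi1_right": self.roi1_right,
                "roi2_reference": self.roi2_reference}
        for name, s in sets.items():
            if not s:
                raise ValueError(f"{name} is empty")
            object.__setattr__(self, name, frozenset(tuple(map(int, v)) for v in s))
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if getattr(self, a) & getattr(self, b):
                    raise ValueError(f"{a} and {b} overlap")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "source": self.source,
            "roi1_left": sorted(self.roi1_left),
            "roi1_right": sorted(self.roi1_right),
            "roi2_reference": sorted(self.roi2_reference),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "RoiSpec":
        if isinstance(text_or_path, Path) or not str(text_or_path).lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        else:
            text = str(text_or_path)
        d = json.loads(text)
        return cls(
            roi1_left=frozenset(map(tuple, d["roi1_left"])),
            roi1_right=frozenset(map(tuple, d["roi1_right"])),
            roi2_reference=frozenset(map(tuple, d["roi2_reference"])),
            source=d.get("source", "config"),
        )

    def to_label_volume(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        """Label volume: 0 background, 1 roi1-left, 2 roi1-right, 3 roi2."""
        vol = np.zeros(grid_shape, dtype=np.int16)
        for code, voxels in ((1, self.roi1_left), (2, self.roi1_right),
                             (3, self.roi2_reference)):
            for v in voxels:
                vol[v] = code
        return vol


def localizer_contrast_map(volume: np.ndarray, design: BlockDesign) -> np.ndarray:
    """Per-voxel t map for the Faces > Houses contrast.

    ``volume`` holds retained scans only, shape ``grid + (n_retained,)``.
    OLS per voxel with HRF-convolved faces and houses regressors, an
    intercept, and a linear drift term.
    """
    grid = volume.shape[:-1]
    nt = volume.shape[-1]
    if nt != design.acquisition.n_retained:
        raise ValueError("volume scan count does not match the design")
    faces = condition_regressor(design, "faces")
    houses = condition_regressor(design, "houses")
    x = np.column_stack([faces, houses, np.ones(nt), np.linspace(-1, 1, nt)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient localizer design")
    y = volume.reshape(-1, nt).T  # (n_scans, n_voxels)
    labels, results = run_glm(y, x, noise_model="ols")
    contrast = compute_contrast(labels, results,
                                np.array([1.0, -1.0, 0.0, 0.0]), stat_type="t")
    return np.asarray(contrast.stat()).reshape(grid)


def _best_patch(tmap: np.ndarray, mask: np.ndarray, patch_shape) -> frozenset:
    """Axis-aligned patch maximizing summed t among placements inside the mask.

    Ties resolve to the placement with the smallest voxel index (first in
    C order), so selection is deterministic.
    """
    patch_shape = tuple(patch_shape)
    if any(p > s for p, s in zip(patch_shape, tmap.shape)):
        raise ValueError(f"patch {patch_shape} larger than grid {tmap.shape}")
    t_wins = sliding_window_view(tmap, patch_shape).sum(axis=(-3, -2, -1))
    m_wins = sliding_window_view(mask.astype(int), patch_shape).sum(axis=(-3, -2, -1))
    inside = m_wins == int(np.prod(patch_shape))
    if not inside.any():
        raise ValueError(f"mask cannot host a {patch_shape} patch")
    t_valid = np.where(inside, t_wins, -np.inf)
    corner = np.unravel_index(np.argmax(t_valid), t_valid.shape)
    return frozenset(
        (corner[0] + i, corner[1] + j, corner[2] + k)
        for i in range(patch_shape[0])
        for j in range(patch_shape[1])
        for k in range(patch_shape[2])
    )


def select_ffa_patches(
    tmap: np.ndarray,
    hemisphere_masks: dict[str, np.ndarray],
    patch_shape: tuple[int, int, int] = (5, 3, 1),
) -> dict[str, frozenset]:
    """Place the maximal-activation patch in each hemisphere search mask.

    ``hemisphere_masks`` maps ``"left"``/``"right"`` to boolean masks of the
    ventral temporal search regions (config-supplied index boxes; no atlas
    in scope).  Default patch shape 5 x 3 x 1 voxels.
    """
    out = {}
    for hemi in ("left", "right"):
        mask = np.asarray(hemisphere_masks[hemi], bool)
        if mask.shape != tmap.shape:
            raise ValueError(f"{hemi} mask shape {mask.shape} != t-map {tmap.shape}")
        out[hemi] = _best_patch(tmap, mask, patch_shape)
    return out


def box_mask(grid_shape, lo, hi) -> np.ndarray:
    """Boolean mask for the half-open index box [lo, hi)."""
    m = np.zeros(grid_shape, dtype=bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


def select_reference_roi(
    grid_shape: tuple[int, int, int],
    corner: tuple[int, int, int],
    slab_shape: tuple[int, int, int] = (9, 3, 1),
    avoid: frozenset | None = None,
) -> frozenset:
    """Configured reference slab (default 9 x 3 x 1 transversal cut).

    Errors when the slab leaves the grid or overlaps the voxels in
    ``avoid`` (disjointness with the feedback patches).
    """
    for d in range(3):
        if corner[d] < 0 or corner[d] + slab_shape[d] > grid_shape[d]:
            raise ValueError(f"slab {slab_shape} at {corner} leaves grid {grid_shape}")
    voxels = frozenset(
        (corner[0] + i, corner[1] + j, corner[2] + k)
        for i in range(slab_shape[0])
        for j in range(slab_shape[1])
        for k in range(slab_shape[2])
    )
    if avoid and voxels & avoid:
        raise ValueError("reference slab overlaps the feedback ROI")
    return voxels


def build_roi_spec(
    tmap: np.ndarray,
    hemisphere_masks: dict[str, np.ndarray],
    reference_corner: tuple[int, int, int],
    patch_shape: tuple[int, int, int] = (5, 3, 1),
    reference_shape: tuple[int, int, int] = (9, 3, 1),
) -> RoiSpec:
    """Assemble the full feedback ROI set from a localizer t map and config."""
    patches = select_ffa_patches(tmap, hemisphere_masks, patch_shape)
    roi2 = select_reference_roi(tmap.shape, reference_corner, reference_shape,
                                avoid=patches["left"] | patches["right"])
    return RoiSpec(roi1_left=patches["left"], roi1_right=patches["right"],
                   roi2_reference=roi2, source="localizer")
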