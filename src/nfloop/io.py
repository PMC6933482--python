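"""Small file-format helpers: NIfTI volumes and YAML experiment configs."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml


def save_volume(volume: np.ndarray, path: str | Path,
                voxel_size=(3.2, 3.3, 4.0)) -> Path:
    """Write a 3-D or 4-D array as NIfTI-1 with a diagonal voxel-size affine."""
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return out
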