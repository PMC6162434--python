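"""Standard-format I/O: NIfTI grids, JSON sidecars, PNG/TIFF images, CSV.

Grid data (dynamic series, diffusion stacks, ADC maps) travel as NIfTI with
a JSON sidecar that preserves acquisition metadata whose order matters
(flip-angle schedules, interleaved b-values); histology images are 8-bit
RGB PNG/TIFF; tables are UTF-8 CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np


def save_nifti(path: str | Path, data: np.ndarray, sidecar: dict | None = None) -> Path:
    """Write an array as NIfTI; optional metadata goes to a .json sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4))
    nib.save(img, str(path))
    if sidecar is not None:
        sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, dict | None]:
    """Read a NIfTI array and its JSON sidecar (None when absent)."""
    path = Path(path)
    data = np.asarray(nib.load(str(path)).get_fdata())
    sc = sidecar_path(path)
    meta = json.loads(sc.read_text()) if sc.exists() else None
    return data, meta


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_image(path: str | Path, rgb: np.ndarray) -> Path:
    """Write an 8-bit RGB image (PNG or TIFF chosen by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(rgb)
    if arr.dtype != np.uint8:
        arr = (np.clip(arr, 0, 1) * 255 + 0.5).astype(np.uint8)
    iio.imwrite(path, arr)
    return path


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def save_table(path: str | Path, df) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
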