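"""NIfTI and sidecar file I/O.

Volumes travel as NIfTI-1 with a diagonal affine built from the voxel
spacing; b-values use the FSL convention of a single space-separated
line in a ``.bval`` text file.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .adcfit import ADCMap, DWISeries

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_bvals",
    "load_bvals",
    "read_dwi",
    "write_adc_map",
    "read_adc_map",
    "read_mask",
]


def save_nifti(array: np.ndarray, voxel_spacing, path, dtype=np.float32) -> None:
    affine = np.diag([*voxel_spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(array).astype(dtype), affine)
    img.header.set_zooms([*voxel_spacing] + [1.0] * (array.ndim - 3))
    nib.save(img, str(path))


def load_nifti(path):
    """Return (data, voxel_spacing) from a NIfTI file."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def save_bvals(b_values, path) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in np.asarray(b_values)) + "\n")


def load_bvals(path) -> np.ndarray:
    return np.array([float(t) for t in Path(path).read_text().split()])


def read_dwi(dwi_path, bval_path) -> DWISeries:
    data, spacing = load_nifti(dwi_path)
    if data.ndim != 4:
        raise ValueError(f"{dwi_path}: expected a 4-D DWI series")
    return DWISeries(signal=data, b_values=load_bvals(bval_path), voxel_spacing=spacing)


def write_adc_map(adc_map: ADCMap, adc_path, valid_path=None) -> None:
    save_nifti(adc_map.adc, adc_map.voxel_spacing, adc_path, dtype=np.float32)
    if valid_path is not None:
        save_nifti(
            adc_map.fit_valid.astype(np.uint8),
            adc_map.voxel_spacing,
            valid_path,
            dtype=np.uint8,
        )


def read_adc_map(adc_path, valid_path=None) -> ADCMap:
    adc, spacing = load_nifti(adc_path)
    if valid_path is not None:
        valid, _ = load_nifti(valid_path)
        valid = valid > 0
    else:
        valid = np.isfinite(adc)
    return ADCMap(adc=adc, voxel_spacing=spacing, fit_valid=valid)


def read_mask(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    data, spacing = load_nifti(path)
    return data > 0.5, spacing
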