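"""Volumetric input handling: ROI extraction and confound signals.

Volumes are assumed already normalised to atlas space; instead of
resampling, a strict grid-equality check (shape + affine) is enforced
between the functional image and the label/mask images. The mean time
series of an ROI is the arithmetic voxel mean within its label at each
volume. Motion parameters are read from 6-column whitespace-delimited
text (the SPM ``rp_*.txt`` dialect: 3 translations in mm, 3 rotations in
radians) and passed through unmodified.
"""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .atlas import Parcellation
from .containers import ConfoundSet, RoiTimeSeriesSet

__all__ = [
    "extract_roi_timeseries",
    "extract_confounds",
    "read_motion_params",
    "load_parcellation",
]


def _as_data_and_affine(img):
    if isinstance(img, nib.spatialimages.SpatialImage):
        return np.asanyarray(img.dataobj), img.affine
    return np.asarray(img), None


def _check_grid(name: str, data4d, affine4d, other, affine_other) -> None:
    if data4d.shape[:3] != other.shape[:3]:
        raise ValueError(
            f"{name} grid {other.shape[:3]} does not match image grid {data4d.shape[:3]}"
        )
    if affine4d is not None and affine_other is not None:
        if not np.allclose(affine4d, affine_other, atol=1e-4):
            raise ValueError(f"{name} affine differs from image affine")


def extract_roi_timeseries(
    image4d,
    parcellation: Parcellation,
    tr_seconds: float = 0.906,
) -> RoiTimeSeriesSet:
    """Mean time series of each of the 116 ROIs of the parcellation.

    ``image4d`` may be a nibabel image or a plain 4-D array on the same
    grid as the label image. Every label listed in the table must own at
    least one voxel; an empty ROI is an error naming the region.
    """
    data, affine = _as_data_and_affine(image4d)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D image, got shape {data.shape}")
    labels_img, affine_lab = _as_data_and_affine(parcellation.label_image)
    _check_grid("label image", data, affine, labels_img, affine_lab)

    table = parcellation.label_table
    flat_labels = labels_img.ravel()
    present = set(int(v) for v in np.unique(flat_labels))
    unknown = sorted(present - {0} - set(table.labels))
    if unknown:
        raise ValueError(f"label image contains labels not in the table: {unknown[:8]}")
    flat_data = data.reshape(-1, data.shape[3])
    out = np.empty((data.shape[3], len(table)), dtype=float)
    for j, (value, name) in enumerate(zip(table.labels, table.names)):
        mask = flat_labels == value
        n_vox = int(mask.sum())
        if n_vox == 0:
            raise ValueError(f"ROI {name!r} (label {value}) contains no voxels")
        out[:, j] = flat_data[mask].mean(axis=0)
    return RoiTimeSeriesSet(out, tr_seconds, table.names)


def extract_confounds(image4d, wm_mask, csf_mask, motion_table) -> ConfoundSet:
    """Mask-mean WM/CSF series plus the motion table, unmodified."""
    data, affine = _as_data_and_affine(image4d)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D image, got shape {data.shape}")
    series = {}
    for name, mask in (("wm", wm_mask), ("csf", csf_mask)):
        m, aff_m = _as_data_and_affine(mask)
        _check_grid(f"{name} mask", data, affine, m, aff_m)
        m = m.astype(bool)
        if not m.any():
            raise ValueError(f"{name} mask is empty")
        series[name] = data[m].mean(axis=0)
    motion = np.asarray(motion_table, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion table must be T x 6, got {motion.shape}")
    if motion.shape[0] != data.shape[3]:
        raise ValueError(
            f"motion table rows ({motion.shape[0]}) != volumes ({data.shape[3]})"
        )
    return ConfoundSet(series["wm"], series["csf"], motion)


def read_motion_params(path: str | Path) -> np.ndarray:
    """Read a 6-column whitespace-delimited motion parameter file."""
    motion = np.loadtxt(path)
    if motion.ndim == 1:
        motion = motion[None, :]
    if motion.shape[1] != 6:
        raise ValueError(f"expected 6 motion columns, got {motion.shape[1]}")
    return motion


def load_parcellation(label_path: str | Path, label_table=None) -> Parcellation:
    """Load a label NIfTI and pair it with a label table (AAL-116 default)."""
    from .atlas import load_aal116

    img = nib.load(str(label_path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError("label image has non-integer values")
        data = rounded.astype(np.int32)
    return Parcellation(data, label_table or load_aal116())
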