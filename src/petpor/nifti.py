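"""NIfTI-1 I/O for volumes and label maps (nibabel-backed)."""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .image import Volume
from .voi import LabelMap

__all__ = ["read_volume", "write_volume", "read_label_map", "write_label_map"]


def read_volume(path, unit: str = "arbitrary") -> Volume:
    """Load a 3-D NIfTI-1 volume (.nii or .nii.gz).

    4-D inputs raise: dynamic frames must be pre-averaged upstream.
    """
    try:
        img = nib.load(str(path))
    except Exception as e:  # nibabel raises several types for bad files
        raise ValueError(f"cannot read {path} as NIfTI: {e}") from e
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        data = np.asanyarray(img.dataobj)[..., 0]
    elif len(shape) != 3:
        raise ValueError(
            f"{path} is {len(shape)}-D; pre-average frames to a single 3-D volume first"
        )
    else:
        data = np.asanyarray(img.dataobj)
    return Volume(np.asarray(data), np.asarray(img.affine, np.float64), unit)


def write_volume(v: Volume, path) -> None:
    data = v.data
    if not np.issubdtype(data.dtype, np.integer):
        data = np.asarray(data, np.float64)
    img = nib.Nifti1Image(data, v.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_label_map(path, regions=None) -> LabelMap:
    """Load an integer label NIfTI; region table inferred unless given."""
    v = read_volume(path, unit="unitless")
    data = np.asarray(v.data)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path} is not integer-valued; not a label map")
        data = np.round(data).astype(np.int32)
    lv = Volume(data.astype(np.int32), v.affine, "unitless")
    if regions is not None:
        return LabelMap(lv, regions)
    return LabelMap.from_volume(lv)


def write_label_map(lm: LabelMap, path) -> None:
    write_volume(lm.labels, path)
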