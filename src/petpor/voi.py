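"""Volume-of-interest (VOI) label handling.

A :class:`LabelMap` pairs an integer label volume (0 = background) with a
region table.  Atlas labels (e.g. FreeSurfer aparc+aseg) are merged into
analysis regions through a many-to-one CSV table; an extracerebral "shell"
region of configurable thickness captures activity spilling from the brain
into scalp and air; regional statistics (mean, SD, CoV) are the substrate of
all downstream quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import Volume

__all__ = ["LabelMap", "merge_labels", "make_shell", "region_stats", "read_merge_table"]

SHELL_NAME = "shell"


@dataclass
class LabelMap:
    """Integer label volume plus a (region_id, region_name) table."""

    labels: Volume
    regions: pd.DataFrame  # columns: region_id, region_name

    def __post_init__(self) -> None:
        if not np.issubdtype(self.labels.data.dtype, np.integer):
            data = np.asarray(self.labels.data)
            if not np.allclose(data, np.round(data)):
                raise ValueError("label volume must be integer-valued")
            self.labels = Volume(data.astype(np.int32), self.labels.affine, "unitless")
        self.regions = self.regions.reset_index(drop=True)
        ids = self.regions["region_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        present = set(np.unique(self.labels.data)) - {0}
        missing = present - set(int(i) for i in ids)
        if missing:
            raise ValueError(f"labels present in volume but absent from region table: {sorted(missing)}")

    @classmethod
    def from_volume(cls, labels: Volume, names: dict[int, str] | None = None) -> "LabelMap":
        ids = sorted(int(i) for i in np.unique(labels.data) if i != 0)
        names = names or {}
        table = pd.DataFrame(
            {"region_id": ids, "region_name": [names.get(i, f"region_{i}") for i in ids]}
        )
        return cls(labels, table)

    @property
    def region_ids(self) -> list[int]:
        return [int(i) for i in self.regions["region_id"]]

    def name_of(self, region_id: int) -> str:
        row = self.regions[self.regions["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"no region {region_id}")
        return str(row["region_name"].iloc[0])

    def mask(self, region_id: int) -> np.ndarray:
        return self.labels.data == region_id

    def brain_mask(self, exclude_shell: bool = True) -> np.ndarray:
        """Union of all nonzero labels (optionally excluding the shell)."""
        m = self.labels.data != 0
        if exclude_shell:
            shell = self.regions[self.regions["region_name"] == SHELL_NAME]
            for sid in shell["region_id"]:
                m &= self.labels.data != int(sid)
        return m


def read_merge_table(path) -> pd.DataFrame:
    """Read a merge table CSV with columns source_label,region_id,region_name.

    Lines starting with ``#`` are comments.  Two tables ship with the
    package (``petpor.data``): a phantom-native one and an editable
    FreeSurfer aparc+aseg template.
    """
    df = pd.read_csv(path, comment="#")
    required = {"source_label", "region_id", "region_name"}
    if not required.issubset(df.columns):
        raise ValueError(f"merge table needs columns {sorted(required)}, got {list(df.columns)}")
    return df


def merge_labels(src: LabelMap, mapping: pd.DataFrame, strict: bool = True) -> LabelMap:
    """Merge source labels into analysis regions via a many-to-one table.

    Parameters
    ----------
    mapping : DataFrame with columns source_label, region_id, region_name.
    strict : bool
        If True, any nonzero label absent from the table raises; otherwise
        unmapped labels are routed to background (0).
    """
    if mapping["source_label"].duplicated().any():
        dup = sorted(mapping.loc[mapping["source_label"].duplicated(), "source_label"])
        raise ValueError(f"merge table maps source labels more than once: {dup}")
    present = set(int(i) for i in np.unique(src.labels.data)) - {0}
    mapped = set(int(i) for i in mapping["source_label"])
    unmapped = sorted(present - mapped)
    if unmapped and strict:
        raise ValueError(f"unmapped source labels: {unmapped}")

    lut_size = int(max(present | mapped, default=0)) + 1
    lut = np.zeros(lut_size, dtype=np.int32)
    for _, row in mapping.iterrows():
        lut[int(row["source_label"])] = int(row["region_id"])
    out = lut[src.labels.data]

    table = (
        mapping[["region_id", "region_name"]]
        .drop_duplicates("region_id")
        .sort_values("region_id")
        .reset_index(drop=True)
    )
    return LabelMap(Volume(out.astype(np.int32), src.labels.affine.copy(), "unitless"), table)


def make_shell(brain: LabelMap, thickness_mm: float = 15.0) -> LabelMap:
    """Add a shell region: voxels within ``thickness_mm`` outside the brain.

    The shell contains exactly the voxels with Euclidean distance d to the
    brain mask (union of nonzero labels) satisfying 0 < d <= thickness_mm,
    with distances measured in world mm (anisotropy-aware exact distance
    transform).  If part of the shell would fall outside the field of view a
    warning reports the truncated voxel count.
    """
    if thickness_mm <= 0:
        raise ValueError(f"thickness must be > 0, got {thickness_mm}")
    vox = brain.labels.voxel_sizes
    mask = brain.labels.data != 0
    pad = tuple(int(np.ceil(thickness_mm / s)) + 1 for s in vox)
    padded = np.pad(mask, [(p, p) for p in pad])
    d = ndimage.distance_transform_edt(~padded, sampling=vox)
    shell_padded = (d > 0) & (d <= thickness_mm)
    sl = tuple(slice(p, p + n) for p, n in zip(pad, mask.shape))
    shell = shell_padded[sl]
    n_trunc = int(shell_padded.sum() - shell.sum())
    if n_trunc:
        warnings.warn(
            f"shell truncated by the field of view: {n_trunc} voxels lost", stacklevel=2
        )
    new_id = max(brain.region_ids, default=0) + 1
    out = brain.labels.data.copy()
    out[shell] = new_id
    table = pd.concat(
        [brain.regions, pd.DataFrame({"region_id": [new_id], "region_name": [SHELL_NAME]})],
        ignore_index=True,
    )
    return LabelMap(Volume(out, brain.labels.affine.copy(), "unitless"), table)


def region_stats(v: Volume, labels: LabelMap) -> pd.DataFrame:
    """Per-region voxel count, volume, mean, sample SD and CoV (%).

    CoV = SD / mean x 100 (intra-region coefficient of variation).  Empty
    regions yield a row with n_voxels=0 and NaN statistics rather than an
    error.  ``v`` and ``labels`` must share a grid.
    """
    if v.shape != labels.labels.shape:
        raise ValueError(f"grid mismatch: {v.shape} vs {labels.labels.shape}")
    vv = labels.labels.voxel_volume_mm3
    rows = []
    data = np.asarray(v.data, np.float64)
    for rid in labels.region_ids:
        m = labels.mask(rid)
        n = int(m.sum())
        if n == 0:
            rows.append((rid, labels.name_of(rid), 0, 0.0, np.nan, np.nan, np.nan))
            continue
        vals = data[m]
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        cov = sd / mean * 100.0 if mean != 0 else np.nan
        rows.append((rid, labels.name_of(rid), n, n * vv, mean, sd, cov))
    return pd.DataFrame(
        rows,
        columns=["region_id", "region_name", "n_voxels", "volume_mm3", "mean", "sd", "cov_percent"],
    )


def region_means(v: Volume, labels: LabelMap, region_ids=None) -> np.ndarray:
    """Vector of regional means in region-id order (fast path for PVC)."""
    ids = labels.region_ids if region_ids is None else list(region_ids)
    data = np.asarray(v.data, np.float64)
    lab = labels.labels.data
    return np.array([data[lab == rid].mean() if np.any(lab == rid) else np.nan for rid in ids])
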