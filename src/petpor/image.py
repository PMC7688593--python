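"""Image container and rigid-body geometry.

The :class:`Volume` is the universal carrier for 3-D scalar images: a data
grid plus a NIfTI-style 4x4 voxel-to-world affine (RAS+, millimetres) and a
unit tag.  :class:`RigidTransform` is a 6-parameter rigid body motion
(3 translations in mm, 3 Euler rotations in degrees, applied x then y then z,
right-handed) about an explicit center point in world coordinates.  All
resampling maps world coordinates of the *moving* image through the transform
into a target grid with a single interpolation pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "Volume",
    "RigidTransform",
    "compose",
    "resample",
]

VALID_UNITS = ("arbitrary", "kBq/mL", "SUV", "unitless")


@dataclass
class Volume:
    """3-D scalar image with voxel-to-world affine (mm) and unit tag.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar grid. Stored as float64 unless it is an integer label image.
    affine : ndarray, shape (4, 4)
        Homogeneous voxel-index (0-based) to world-mm matrix; must be
        invertible.
    unit : str
        One of ``arbitrary``, ``kBq/mL``, ``SUV``, ``unitless``.
    """

    data: np.ndarray
    affine: np.ndarray
    unit: str = "arbitrary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got {self.data.ndim}-D")
        if any(n < 2 for n in self.data.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def fov_center_world(self) -> np.ndarray:
        """World coordinates of the geometric center of the field of view."""
        c = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return (self.affine @ np.append(c, 1.0))[:3]

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "Volume":
        return Volume(data, self.affine.copy(), unit if unit is not None else self.unit)

    def world_coords(self) -> np.ndarray:
        """World coordinates of every voxel, shape (3, nx, ny, nz)."""
        idx = np.indices(self.shape, dtype=np.float64)
        A = self.affine
        return np.einsum("ij,j...->i...", A[:3, :3], idx) + A[:3, 3].reshape(3, 1, 1, 1)


def _euler_matrix(r_deg: np.ndarray) -> np.ndarray:
    # extrinsic x -> y -> z, i.e. M = Rz @ Ry @ Rx
    return Rotation.from_euler("xyz", r_deg, degrees=True).as_matrix()


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    a = np.asarray(a, dtype=np.float64)
    w = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return w


@dataclass
class RigidTransform:
    """6-parameter rigid body transform.

    World mapping: ``y = R (x - center) + center + t`` with ``R`` built from
    Euler angles applied in x-then-y-then-z order (extrinsic, right-handed,
    degrees).  ``center`` is a fixed point in world mm; by convention the
    geometric center of the fixed image's field of view.
    """

    t_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    r_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.t_mm = np.asarray(self.t_mm, dtype=np.float64).reshape(3)
        self.r_deg = _wrap_deg(np.asarray(self.r_deg, dtype=np.float64).reshape(3))
        self.center_mm = np.asarray(self.center_mm, dtype=np.float64).reshape(3)

    @classmethod
    def identity(cls, center_mm=None) -> "RigidTransform":
        c = np.zeros(3) if center_mm is None else np.asarray(center_mm, float)
        return cls(np.zeros(3), np.zeros(3), c)

    @property
    def params(self) -> np.ndarray:
        """(tx, ty, tz, rx, ry, rz) as one 6-vector (mm, deg)."""
        return np.concatenate([self.t_mm, self.r_deg])

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous world->world matrix."""
        R = _euler_matrix(self.r_deg)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = self.center_mm + self.t_mm - R @ self.center_mm
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray, center_mm) -> "RigidTransform":
        """Decompose a rigid 4x4 world matrix about the given center."""
        M = np.asarray(M, dtype=np.float64)
        c = np.asarray(center_mm, dtype=np.float64).reshape(3)
        R = M[:3, :3]
        r_deg = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
        t = (M @ np.append(c, 1.0))[:3] - c
        return cls(t, r_deg, c)

    def recentered(self, center_mm) -> "RigidTransform":
        """Same world mapping expressed about a different center."""
        return RigidTransform.from_matrix(self.matrix(), center_mm)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix()), self.center_mm)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to world points, shape (..., 3)."""
        p = np.asarray(points, dtype=np.float64)
        M = self.matrix()
        return p @ M[:3, :3].T + M[:3, 3]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "t_mm": [float(v) for v in self.t_mm],
            "r_deg": [float(v) for v in self.r_deg],
            "center_mm": [float(v) for v in self.center_mm],
            "convention": "xyz-RAS",
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        if d.get("convention", "xyz-RAS") != "xyz-RAS":
            raise ValueError(f"unsupported transform convention {d.get('convention')!r}")
        return cls(np.asarray(d["t_mm"]), np.asarray(d["r_deg"]), np.asarray(d["center_mm"]))

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        t = ", ".join(f"{v:+.3f}" for v in self.t_mm)
        r = ", ".join(f"{v:+.3f}" for v in self.r_deg)
        return f"RigidTransform(t_mm=[{t}], r_deg=[{r}])"


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``a`` then ``b``.

    The result is expressed about ``b``'s center; ``a`` is re-centered
    implicitly through its matrix, so differing center conventions are safe.
    """
    M = b.matrix() @ a.matrix()
    return RigidTransform.from_matrix(M, b.center_mm)


def resample(
    moving: Volume,
    transform: RigidTransform,
    target: Volume,
    interpolation: str = "trilinear",
    fill: float = 0.0,
    count_outside: bool = False,
):
    """Resample ``moving`` through ``transform`` onto ``target``'s grid.

    ``transform`` maps moving-image world coordinates to fixed/target world
    coordinates, so each target voxel samples the moving image at
    ``A_mov^-1 T^-1 A_tgt [i,j,k,1]``.  One interpolation pass; never chain
    resamplings.

    Parameters
    ----------
    interpolation : {"trilinear", "nearest"}
        ``nearest`` is mandatory for integer label data.
    fill : float
        Value for voxels mapping outside the moving field of view.
    count_outside : bool
        If True, return ``(Volume, n_outside)``.
    """
    is_label = np.issubdtype(moving.data.dtype, np.integer)
    if interpolation == "trilinear":
        if is_label:
            raise ValueError("label (integer) data must use nearest interpolation")
        order = 1
    elif interpolation == "nearest":
        order = 0
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")

    # output index -> input index map for ndimage.affine_transform
    M = np.linalg.inv(moving.affine) @ np.linalg.inv(transform.matrix()) @ target.affine
    out = ndimage.affine_transform(
        moving.data if is_label else np.asarray(moving.data, np.float64),
        M[:3, :3],
        offset=M[:3, 3],
        output_shape=target.shape,
        order=order,
        mode="constant",
        cval=fill,
        prefilter=False,
    )
    vol = Volume(out, target.affine.copy(), moving.unit)
    if count_outside:
        n_out = _count_outside(M, target.shape, moving.shape)
        return vol, n_out
    return vol


def _count_outside(M: np.ndarray, out_shape, in_shape) -> int:
    idx = np.indices(out_shape, dtype=np.float64).reshape(3, -1)
    src = M[:3, :3] @ idx + M[:3, 3:4]
    lim = np.asarray(in_shape, dtype=np.float64).reshape(3, 1)
    inside = np.all((src >= -0.5) & (src <= lim - 0.5), axis=0)
    return int(np.size(inside) - np.count_nonzero(inside))


def grid_like(shape, voxel_mm, center_world=(0.0, 0.0, 0.0), unit="arbitrary") -> Volume:
    """Empty volume whose FOV center sits at ``center_world`` (RAS+ mm)."""
    shape = tuple(int(n) for n in shape)
    voxel = np.broadcast_to(np.asarray(voxel_mm, float), (3,))
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel)
    half = voxel * (np.asarray(shape) - 1) / 2.0
    aff[:3, 3] = np.asarray(center_world, float) - half
    return Volume(np.zeros(shape), aff, unit)
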