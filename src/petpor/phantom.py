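"""Synthetic brain phantom: the test substrate for PVC and registration.

Emulates the geometry and contrast of an amyloid PET study without any real
data: an ellipsoidal white-matter (WM) core wrapped in a thin cortical
gray-matter (GM) ribbon whose thickness is sinusoidally modulated (a crude
stand-in for gyral folding, the main partial-volume stressor), subcortical
nuclei, and a separate cerebellum placed posterior-inferior to the cerebrum
so the object is asymmetric along y and z like a real head.  Amyloid
tracers accumulate strongly in WM regardless of disease, so the default
"amyloid-negative" activity set is WM-dominant (WM 2.0, GM 1.0, cerebellum
1.0); the "amyloid-positive" set raises cortical GM to 2.2.

A PET acquisition is simulated as truth -> PSF blur -> rigid motion ->
coarser PET grid -> additive Gaussian noise, so the rigid transform that a
registration should recover is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import RigidTransform, Volume, grid_like, resample
from .psf import PSFModel, smooth
from .voi import LabelMap

__all__ = [
    "PhantomSpec",
    "REGION_NAMES",
    "ACTIVITY_PRESETS",
    "generate_phantom",
    "simulate_pet_scan",
]

# region ids in the label map
(WM, GM_FRONTAL, GM_PARIETAL, GM_TEMPORAL, GM_OCCIPITAL, SUBCORTICAL,
 CEREBELLUM, CEREBELLUM_WM) = range(1, 9)
GM_REGIONS = (GM_FRONTAL, GM_PARIETAL, GM_TEMPORAL, GM_OCCIPITAL)

REGION_NAMES = {
    WM: "white_matter",
    GM_FRONTAL: "gm_frontal",
    GM_PARIETAL: "gm_parietal",
    GM_TEMPORAL: "gm_temporal",
    GM_OCCIPITAL: "gm_occipital",
    SUBCORTICAL: "subcortical",
    CEREBELLUM: "cerebellar_gm",
    CEREBELLUM_WM: "cerebellar_wm",
}

# WM-dominant PiB-like contrast; cerebellum is the SUVR reference
ACTIVITY_PRESETS = {
    "amyloid-negative": {
        WM: 2.0, GM_FRONTAL: 1.0, GM_PARIETAL: 1.0, GM_TEMPORAL: 1.0,
        GM_OCCIPITAL: 1.0, SUBCORTICAL: 1.6, CEREBELLUM: 1.0, CEREBELLUM_WM: 2.0,
    },
    "amyloid-positive": {
        WM: 2.0, GM_FRONTAL: 2.2, GM_PARIETAL: 2.2, GM_TEMPORAL: 2.2,
        GM_OCCIPITAL: 2.2, SUBCORTICAL: 1.6, CEREBELLUM: 1.0, CEREBELLUM_WM: 2.0,
    },
}


@dataclass
class PhantomSpec:
    """Deterministic description of a phantom study.

    Grids default to a desk-scale stand-in for clinical data: labels on a
    96^3 grid at 1 mm (MR space), PET on 48^3 at 2 mm.  Lengths in mm.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_mm: float = 1.0
    pet_shape: tuple[int, int, int] = (48, 48, 48)
    pet_voxel_mm: float = 2.0
    wm_center: tuple[float, float, float] = (0.0, 2.0, 6.0)
    wm_semiaxes: tuple[float, float, float] = (26.0, 32.0, 20.0)
    gm_thickness_mm: float = 3.5
    gyral_amp_mm: float = 1.0
    gyral_freq: int = 6
    # tucked directly beneath the posterior cerebrum, as in a real head —
    # activity above the cerebellum is what makes z-misregistration spill
    # cerebral signal into the cerebellar VOI
    cerebellum_center: tuple[float, float, float] = (0.0, -20.0, -20.0)
    cerebellum_semiaxes: tuple[float, float, float] = (17.0, 13.0, 10.0)
    cerebellum_gm_thickness_mm: float = 5.0
    n_subcortical: int = 2
    subcortical_radius_mm: float = 7.0
    activities: dict = field(default_factory=lambda: dict(ACTIVITY_PRESETS["amyloid-negative"]))
    truth_transform: RigidTransform = field(default_factory=RigidTransform.identity)
    psf_fwhm_mm: float = 8.0
    noise_sd: float = 0.05
    seed: int = 0


def _ellipsoid(coords: np.ndarray, center, semiaxes) -> np.ndarray:
    c = np.asarray(center, float).reshape(3, 1, 1, 1)
    a = np.asarray(semiaxes, float).reshape(3, 1, 1, 1)
    return (((coords - c) / a) ** 2).sum(axis=0) <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[LabelMap, dict[int, float]]:
    """Build the label map and its ground-truth activity table.

    Deterministic: identical spec (incl. seed) gives identical output.
    Raises if the blurred brain would not fit in the grid with a PSF-FWHM
    margin.
    """
    grid = grid_like(spec.shape, spec.voxel_mm)
    fov_half = np.min(grid.voxel_sizes * (np.asarray(spec.shape) - 1) / 2.0)
    max_extent = max(
        np.max(np.abs(np.asarray(spec.wm_center)) + np.asarray(spec.wm_semiaxes))
        + spec.gm_thickness_mm + spec.gyral_amp_mm,
        np.max(np.abs(np.asarray(spec.cerebellum_center)) + np.asarray(spec.cerebellum_semiaxes)),
    )
    if max_extent + spec.psf_fwhm_mm > fov_half:
        raise ValueError(
            f"phantom extent {max_extent:.1f} mm + PSF margin {spec.psf_fwhm_mm:.1f} mm "
            f"exceeds half-FOV {fov_half:.1f} mm"
        )

    xyz = grid.world_coords()
    labels = np.zeros(spec.shape, dtype=np.int32)

    wm = _ellipsoid(xyz, spec.wm_center, spec.wm_semiaxes)
    labels[wm] = WM

    # cortical ribbon: within a direction-modulated distance of the WM surface
    from scipy import ndimage

    d_out = ndimage.distance_transform_edt(~wm, sampling=grid.voxel_sizes)
    rel = xyz - np.asarray(spec.wm_center, float).reshape(3, 1, 1, 1)
    azimuth = np.arctan2(rel[1], rel[0])
    inclination = np.arctan2(rel[2], np.hypot(rel[0], rel[1]))
    # gyral stand-in: thickness modulated in both angular coordinates so the
    # cortical ribbon constrains all three rotations
    thickness = spec.gm_thickness_mm + spec.gyral_amp_mm * (
        np.sin(spec.gyral_freq * azimuth) * np.cos(2.0 * inclination)
        + 0.6 * np.sin(3.0 * inclination)
    )
    gm = (d_out > 0) & (d_out <= thickness)

    # sectors by direction from the WM center
    r = np.linalg.norm(rel, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        zfrac = np.where(r > 0, rel[2] / np.maximum(r, 1e-9), 0.0)
    parietal = zfrac >= 0.45
    temporal = zfrac <= -0.35
    frontal = (~parietal) & (~temporal) & (rel[1] > 0)
    occipital = (~parietal) & (~temporal) & (rel[1] <= 0)
    labels[gm & parietal] = GM_PARIETAL
    labels[gm & temporal] = GM_TEMPORAL
    labels[gm & frontal] = GM_FRONTAL
    labels[gm & occipital] = GM_OCCIPITAL

    # subcortical nuclei inside WM
    # deliberately non-mirror-symmetric placement (real deep nuclei are not
    # perfectly symmetric either); keeps rotations identifiable
    offsets = [(-11.0, 6.0, 2.0), (12.0, -4.0, 5.0), (0.0, 14.0, -2.0), (0.0, -8.0, 6.0)]
    sub = np.zeros_like(wm)
    for k in range(min(spec.n_subcortical, len(offsets))):
        c = np.asarray(spec.wm_center) + np.asarray(offsets[k])
        sub |= _ellipsoid(xyz, c, [spec.subcortical_radius_mm] * 3)
    labels[sub & wm] = SUBCORTICAL

    # cerebellum: cortical GM mantle over a WM core (the corpus medullare is
    # tracer-hot in amyloid PET, sitting directly against the GM reference)
    cer = _ellipsoid(xyz, spec.cerebellum_center, spec.cerebellum_semiaxes)
    cer_wm = _ellipsoid(
        xyz,
        np.asarray(spec.cerebellum_center) + np.array([0.0, 0.0, 1.0]),
        np.maximum(np.asarray(spec.cerebellum_semiaxes) - spec.cerebellum_gm_thickness_mm, 2.0),
    )
    labels[cer & (labels == 0)] = CEREBELLUM
    labels[cer_wm & (labels == CEREBELLUM)] = CEREBELLUM_WM

    import pandas as pd

    present = sorted(int(i) for i in np.unique(labels) if i != 0)
    table = pd.DataFrame(
        {"region_id": present, "region_name": [REGION_NAMES[i] for i in present]}
    )
    lm = LabelMap(Volume(labels, grid.affine, "unitless"), table)
    truth = {rid: float(spec.activities[rid]) for rid in present}
    return lm, truth


def activity_volume(labels: LabelMap, activities: dict[int, float]) -> Volume:
    """Piecewise-constant ground-truth activity map on the label grid."""
    lut = np.zeros(int(max(labels.region_ids)) + 1)
    for rid, val in activities.items():
        if rid in labels.region_ids:
            lut[int(rid)] = val
    return Volume(lut[labels.labels.data], labels.labels.affine.copy(), "arbitrary")


def simulate_pet_scan(
    labels: LabelMap,
    activities: dict[int, float],
    truth_transform: RigidTransform | None = None,
    psf: PSFModel | float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pet_grid: Volume | None = None,
) -> Volume:
    """Simulate a PET acquisition of the phantom.

    ``truth_transform`` is the PET-to-MR rigid transform a registration
    should recover; the scan is rendered by pulling the blurred truth
    through its inverse onto the PET grid, then adding seeded white
    Gaussian noise of standard deviation ``noise_sd`` (activity units).
    ``pet_grid`` defaults to the label grid itself (1 interpolation-free
    path when the transform is identity).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if not isinstance(psf, PSFModel):
        psf = PSFModel(float(psf))
    truth_transform = truth_transform or RigidTransform.identity()
    truth = activity_volume(labels, activities)
    blurred = smooth(truth, psf)
    if pet_grid is None and np.allclose(truth_transform.matrix(), np.eye(4)):
        pet = blurred
    else:
        target = pet_grid if pet_grid is not None else labels.labels
        pet = resample(blurred, truth_transform.inverse(), target, "trilinear")
    data = pet.data
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return Volume(data, pet.affine.copy(), "arbitrary")


def default_pet_grid(spec: PhantomSpec) -> Volume:
    return grid_like(spec.pet_shape, spec.pet_voxel_mm)
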