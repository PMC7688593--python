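"""Partial volume correction: geometric transfer matrix (GTM) and
region-based voxel-wise (RBV) methods.

Finite scanner resolution mixes signal between neighbouring structures
(spill-in / spill-out).  GTM models the mixing region-wise: with PSF kernel
h and region indicator functions I_j, the spill-over matrix has entries

    W_ij = mean over voxels x in region i of (I_j * h)(x)

(row = observing region, column = source region), and the true regional
concentrations c solve W c = b where b holds the observed regional means.
RBV extends the region-wise estimate to a voxel map using the
piecewise-constant synthetic image s built from c:

    f_rbv(x) = f(x) * s(x) / (s * h)(x).

Mass may spill outside all VOIs, so columns of W sum to <= 1; the
extracerebral shell region exists precisely to capture near-brain spill.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import Volume
from .psf import PSFModel, smooth
from .voi import LabelMap, region_means

__all__ = [
    "GTMResult",
    "compute_gtm_matrix",
    "mass_fraction_matrix",
    "gtm_correct",
    "make_synthetic",
    "rbv_correct",
]

log = logging.getLogger(__name__)

COND_LIMIT = 1e6  # switch to least-squares pseudo-solve beyond this


@dataclass
class GTMResult:
    """Outcome of a GTM solve.

    Attributes
    ----------
    region_ids : list of int, the ordering of all vectors/matrix axes.
    W : (n, n) spill-over matrix, row = observing region, column = source.
    observed : regional means of the registered PET image.
    corrected : concentrations c solving W c = observed.
    cond_W : condition number of W.
    residual_norm : ||W c - observed||_2.
    ill_conditioned : True when the least-squares fallback was used.
    """

    region_ids: list[int]
    W: np.ndarray
    observed: np.ndarray
    corrected: np.ndarray
    cond_W: float
    residual_norm: float
    ill_conditioned: bool = False

    def as_frame(self, labels: LabelMap | None = None) -> pd.DataFrame:
        names = (
            [labels.name_of(r) for r in self.region_ids]
            if labels is not None
            else [str(r) for r in self.region_ids]
        )
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "region_name": names,
                "observed": self.observed,
                "corrected": self.corrected,
            }
        )


def compute_gtm_matrix(labels: LabelMap, psf: PSFModel) -> tuple[np.ndarray, list[int]]:
    """Spill-over matrix W for a label map under a Gaussian PSF.

    Each region indicator is blurred with the PSF and averaged over every
    region, giving the fraction of region j's (unit) signal observed in
    region i.  Depends only on the label geometry and the PSF, so the matrix
    is computed once per (label map, PSF) pair and reused across the
    iterative loop.
    """
    ids = labels.region_ids
    masks = [labels.mask(rid) for rid in ids]
    for rid, m in zip(ids, masks):
        if not m.any():
            raise ValueError(f"region {rid} ({labels.name_of(rid)}) is empty")
    n = len(ids)
    W = np.empty((n, n))
    for j, mj in enumerate(masks):
        blurred = smooth(labels.labels.with_data(mj.astype(np.float64)), psf).data
        for i, mi in enumerate(masks):
            W[i, j] = blurred[mi].mean()
    return W, ids


def mass_fraction_matrix(W: np.ndarray, n_voxels) -> np.ndarray:
    """Volume-weighted spill matrix V_ij = W_ij * n_i / n_j.

    V_ij is the fraction of region j's total signal observed inside region
    i, so each column sums to <= 1 — the remainder spilled outside all VOIs.
    (The regional-mean W used in the solve does not have that property;
    means are not mass fractions.)
    """
    n = np.asarray(n_voxels, np.float64)
    return np.asarray(W, np.float64) * n[:, None] / n[None, :]


def gtm_correct(
    pet_in_mr: Volume,
    labels: LabelMap,
    W: np.ndarray,
    region_ids: list[int] | None = None,
) -> GTMResult:
    """Solve W c = observed for the PV-corrected regional concentrations.

    Direct LU solve; when cond(W) exceeds 1e6 a warning flag is set and a
    least-squares pseudo-solve is used instead.  A singular W raises with the
    condition diagnostic.
    """
    ids = labels.region_ids if region_ids is None else list(region_ids)
    if pet_in_mr.shape != labels.labels.shape:
        raise ValueError(
            f"PET grid {pet_in_mr.shape} does not match label grid "
            f"{labels.labels.shape}; resample the PET to the label grid first"
        )
    W = np.asarray(W, np.float64)
    if W.shape != (len(ids), len(ids)):
        raise ValueError(f"W shape {W.shape} does not match {len(ids)} regions")
    observed = region_means(pet_in_mr, labels, ids)
    cond = float(np.linalg.cond(W))
    if not np.isfinite(cond) or np.linalg.matrix_rank(W) < len(ids):
        raise np.linalg.LinAlgError(f"GTM matrix is singular (cond={cond:.3g})")
    ill = cond > COND_LIMIT
    if ill:
        warnings.warn(
            f"GTM matrix ill-conditioned (cond={cond:.3g} > {COND_LIMIT:g}); "
            "using least-squares pseudo-solve",
            stacklevel=2,
        )
        corrected = np.linalg.lstsq(W, observed, rcond=None)[0]
    else:
        corrected = np.linalg.solve(W, observed)
    resid = float(np.linalg.norm(W @ corrected - observed))
    return GTMResult(ids, W, observed, corrected, cond, resid, ill)


def make_synthetic(labels: LabelMap, corrected: np.ndarray, region_ids=None) -> Volume:
    """Piecewise-constant synthetic PET: value c_j inside region j, 0 outside.

    Negative corrected values (possible under noise) are preserved as-is and
    logged, not clipped — clipping would bias the registration target.
    """
    ids = labels.region_ids if region_ids is None else list(region_ids)
    corrected = np.asarray(corrected, np.float64).reshape(-1)
    if len(corrected) != len(ids):
        raise ValueError(f"{len(corrected)} values for {len(ids)} regions")
    neg = [rid for rid, c in zip(ids, corrected) if c < -1e-12]
    if neg:
        log.warning("negative PV-corrected values in regions %s (kept)", neg)
    lut = np.zeros(int(max(ids)) + 1)
    for rid, c in zip(ids, corrected):
        lut[int(rid)] = c
    out = lut[labels.labels.data]
    return Volume(out, labels.labels.affine.copy(), "arbitrary")


def rbv_correct(
    pet_in_mr: Volume,
    synthetic: Volume,
    psf: PSFModel,
    epsilon_frac: float = 1e-3,
) -> Volume:
    """Region-based voxel-wise correction f(x) s(x) / (s*h)(x).

    Voxels where the blurred synthetic falls below ``epsilon_frac`` times its
    maximum (air, far outside the brain) are set to 0 to suppress division
    blow-up; the count is logged.
    """
    if not (0 < epsilon_frac < 1):
        raise ValueError(f"epsilon_frac must be in (0, 1), got {epsilon_frac}")
    if pet_in_mr.shape != synthetic.shape:
        raise ValueError("PET and synthetic must share a grid")
    s = np.asarray(synthetic.data, np.float64)
    sh = smooth(synthetic, psf).data
    floor = epsilon_frac * np.abs(sh).max()
    ok = np.abs(sh) >= floor
    out = np.zeros_like(s)
    np.divide(pet_in_mr.data * s, sh, out=out, where=ok)
    n_zeroed = int(np.size(ok) - np.count_nonzero(ok))
    log.debug("RBV: %d voxels below epsilon floor set to 0", n_zeroed)
    return Volume(out, pet_in_mr.affine.copy(), pet_in_mr.unit)
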