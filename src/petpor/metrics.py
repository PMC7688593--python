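"""Quantification and comparison metrics: SUV, SUVR, CoV deltas, effect sizes.

SUV normalises tissue concentration by injected dose per body weight
(density 1 g/mL assumed, the standard PET convention); SUVR divides by the
mean over a reference region (cerebellar GM in amyloid studies).  The
comparison metrics mirror how registration strategies are evaluated:
intra-region coefficient of variation (CoV = SD/mean x 100%) as an index of
PVC consistency, and the paired effect size mean(diff)/SD(diff).

Group-level inference (Wilcoxon signed-rank, Pearson correlation) is left
to general stats packages; this module emits tidy per-region tables those
packages consume directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import Volume
from .voi import LabelMap, region_stats

__all__ = [
    "DoseInfo",
    "suv_map",
    "suvr_map",
    "paired_effect_size",
    "compare_cov",
    "composite_suvr",
]


@dataclass(frozen=True)
class DoseInfo:
    """Injected dose (MBq) and body weight (kg) for SUV scaling."""

    injected_dose_mbq: float
    body_weight_kg: float

    def __post_init__(self) -> None:
        for name, v in (("injected_dose_mbq", self.injected_dose_mbq),
                        ("body_weight_kg", self.body_weight_kg)):
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")


def suv_map(v: Volume, dose: DoseInfo) -> Volume:
    """Concentration (kBq/mL) -> SUV = c / (dose / body weight).

    1 mL is taken as 1 g of tissue, so the normaliser is
    dose_kBq / weight_g.
    """
    if v.unit != "kBq/mL":
        raise ValueError(f"SUV needs a kBq/mL input, got unit {v.unit!r}")
    norm = (dose.injected_dose_mbq * 1000.0) / (dose.body_weight_kg * 1000.0)
    return v.with_data(np.asarray(v.data, np.float64) / norm, unit="SUV")


def suvr_map(suv: Volume, labels: LabelMap, reference_region_id: int) -> Volume:
    """Divide by the mean over the reference region (its output mean is 1)."""
    m = labels.mask(reference_region_id)
    if not m.any():
        raise ValueError(f"reference region {reference_region_id} is empty")
    ref = float(np.asarray(suv.data, np.float64)[m].mean())
    if ref <= 0:
        raise ValueError(f"reference-region mean must be > 0, got {ref}")
    return suv.with_data(np.asarray(suv.data, np.float64) / ref, unit="unitless")


def paired_effect_size(x, y) -> float:
    """mean(y - x) / SD(y - x) with sample SD; zero SD raises.

    A pure constant offset (or identical inputs) has zero difference
    variance, for which the effect size is undefined — that raises rather
    than returning a spuriously huge number.
    """
    x = np.asarray(x, np.float64).reshape(-1)
    y = np.asarray(y, np.float64).reshape(-1)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError(
            "difference SD is 0 (identical inputs or a pure constant offset); "
            "paired effect size undefined"
        )
    return float(d.mean() / sd)


def compare_cov(map_a: Volume, map_b: Volume, labels: LabelMap) -> pd.DataFrame:
    """Per-region CoV of two maps and their difference (CoV_b - CoV_a).

    Regions empty on the shared grid appear with NaN CoVs and
    ``missing=True`` rather than being dropped.
    """
    sa = region_stats(map_a, labels)
    sb = region_stats(map_b, labels)
    out = sa[["region_id", "region_name", "n_voxels"]].copy()
    out["cov_a"] = sa["cov_percent"]
    out["cov_b"] = sb["cov_percent"]
    out["delta_cov"] = out["cov_b"] - out["cov_a"]
    out["missing"] = out["n_voxels"] == 0
    return out


def composite_suvr(
    suvr: Volume, labels: LabelMap, region_ids, weighted: bool = False
) -> float:
    """Cortical composite: average of regional SUVR means.

    ``weighted=False`` (default) is an unweighted mean of region means;
    ``weighted=True`` weights by voxel count.
    """
    stats = region_stats(suvr, labels)
    sel = stats[stats["region_id"].isin(list(region_ids))]
    if sel.empty or sel["n_voxels"].eq(0).any():
        raise ValueError("composite regions missing or empty")
    if weighted:
        return float(np.average(sel["mean"], weights=sel["n_voxels"]))
    return float(sel["mean"].mean())
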