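"""End-to-end pipeline: config validation, orchestration, artifact manifest.

The pipeline runs merge -> shell -> PoR -> (SUV/SUVR when dose info is
given) -> regional statistics, writing every artifact with a SHA-256
checksum into a manifest so a rerun of the same configuration can be
audited for determinism.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .image import Volume
from .metrics import DoseInfo, suv_map, suvr_map
from .nifti import read_label_map, read_volume, write_volume
from .por import PoRModel
from .psf import PSFModel
from .registration import RegistrationOptions
from .voi import make_shell, merge_labels, read_merge_table, region_stats

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (detected pre-compute)."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Paths plus the few numbers that matter: PSF FWHM (mm, default 8),
    shell thickness (mm; 0 disables), PoR tolerances, the SUVR reference
    region, and optional dose info for SUV scaling.
    """

    pet: str
    labels: str
    out_dir: str
    merge_table: str | None = None
    psf_fwhm_mm: float = 8.0
    shell_thickness_mm: float = 15.0
    reference_region_id: int | None = None
    injected_dose_mbq: float | None = None
    body_weight_kg: float | None = None
    max_iter: int = 10
    tol_t_mm: float = 0.05
    tol_r_deg: float = 0.05
    registration: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"pet", "labels", "out_dir"} - set(d)
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        for name in ("pet", "labels"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"{name} file not found: {p}")
        if self.merge_table is not None and not Path(self.merge_table).exists():
            raise ConfigError(f"merge table not found: {self.merge_table}")
        if self.psf_fwhm_mm < 0:
            raise ConfigError(f"psf_fwhm_mm must be >= 0, got {self.psf_fwhm_mm}")
        if self.shell_thickness_mm < 0:
            raise ConfigError("shell_thickness_mm must be >= 0 (0 disables the shell)")
        if (self.injected_dose_mbq is None) != (self.body_weight_kg is None):
            raise ConfigError("injected_dose_mbq and body_weight_kg must be given together")
        reg_known = {f.name for f in dataclasses.fields(RegistrationOptions)}
        bad = set(self.registration) - reg_known
        if bad:
            raise ConfigError(f"unknown registration options: {sorted(bad)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the artifact manifest dict.

    Any stage failure raises with the stage name; artifacts written before
    the failure are listed in a partial manifest saved alongside.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "artifacts": {}}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "load"
    try:
        pet = read_volume(config.pet)
        labels = read_label_map(config.labels)

        stage = "merge"
        if config.merge_table:
            labels = merge_labels(labels, read_merge_table(config.merge_table))

        stage = "shell"
        if config.shell_thickness_mm > 0:
            labels = make_shell(labels, config.shell_thickness_mm)

        stage = "por"
        model = PoRModel(
            pet,
            labels,
            psf=PSFModel(config.psf_fwhm_mm),
            reg_opts=RegistrationOptions(**config.registration),
        )
        res = model.fit(
            max_iter=config.max_iter,
            tol_t_mm=config.tol_t_mm,
            tol_r_deg=config.tol_r_deg,
        )

        stage = "write-por"
        trace_path = out / "transform_trace.csv"
        res.trace.to_csv(trace_path, index=False)
        record("transform_trace", trace_path)
        tf_path = out / "final_transform.json"
        res.final_transform.to_json(tf_path)
        record("final_transform", tf_path)
        conv_path = out / "conventional_transform.json"
        res.conventional_transform.to_json(conv_path)
        record("conventional_transform", conv_path)
        w_path = out / "gtm_matrix.csv"
        pd.DataFrame(res.gtm.W, index=res.gtm.region_ids, columns=res.gtm.region_ids).to_csv(w_path)
        record("gtm_matrix", w_path)
        gtm_path = out / "gtm_result.json"
        with open(gtm_path, "w") as fh:
            json.dump(
                {
                    "region_ids": res.gtm.region_ids,
                    "observed": list(res.gtm.observed),
                    "corrected": list(res.gtm.corrected),
                    "cond_W": res.gtm.cond_W,
                    "residual_norm": res.gtm.residual_norm,
                    "ill_conditioned": res.gtm.ill_conditioned,
                    "converged": res.converged,
                    "n_iterations": res.n_iterations,
                },
                fh,
                indent=2,
            )
        record("gtm_result", gtm_path)
        rbv_path = out / "rbv.nii.gz"
        write_volume(res.rbv_map, rbv_path)
        record("rbv", rbv_path)

        stage = "suv"
        quant = res.rbv_map
        if config.injected_dose_mbq is not None:
            dose = DoseInfo(config.injected_dose_mbq, config.body_weight_kg)
            quant = suv_map(Volume(res.rbv_map.data, res.rbv_map.affine, "kBq/mL"), dose)
            suv_path = out / "suv.nii.gz"
            write_volume(quant, suv_path)
            record("suv", suv_path)
        if config.reference_region_id is not None:
            suvr = suvr_map(quant, labels, config.reference_region_id)
            suvr_path = out / "suvr.nii.gz"
            write_volume(suvr, suvr_path)
            record("suvr", suvr_path)
            quant_stats = region_stats(suvr, labels)
        else:
            quant_stats = region_stats(quant, labels)

        stage = "stats"
        stats_path = out / "region_stats.csv"
        quant_stats.to_csv(stats_path, index=False)
        record("region_stats", stats_path)
    except Exception as e:
        manifest["failed_stage"] = stage
        manifest["error"] = str(e)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
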