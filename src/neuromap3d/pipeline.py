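"""One-command orchestration of the full workflow from a JSON config.

``run`` chains catalog loading, MSI reading and TIC normalisation, peak
annotation, per-peptide ion-volume assembly, landmark transform fitting,
resampling into CT space, and presence/volumetric reporting.  Every
output is derivable from the inputs and the config alone; a MANIFEST
records input hashes, stage timings and completeness so partial runs
remain interpretable.  The expert/manual steps of the original workflow
enter only through two files: the landmark CSV and the section z table.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import neuromap3d
from neuromap3d.anatomy import (
    component_volume,
    load_ct_volume,
    load_label_volume,
    presence_table,
    region_volumes,
    segment_threshold,
    volume_ratio,
)
from neuromap3d.catalog import read_catalog_csv
from neuromap3d.masscalc import annotate_peaklist, annotation_report, monoisotopic_mh
from neuromap3d.msi import extract_ion_image, read_imzml, tic_normalize
from neuromap3d.phantom import pooled_peaklist
from neuromap3d.register import LandmarkSet, apply_to_volume, estimate_similarity
from neuromap3d.volume import read_z_table, save_volume_nrrd, stack_sections


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


REQUIRED_FIELDS = (
    "catalog_csv",
    "imzml",
    "z_table",
    "ct_volume",
    "region_labels",
    "region_names",
    "landmarks",
    "out_dir",
)


@dataclass
class RunConfig:
    catalog_csv: str
    imzml: str
    z_table: str
    ct_volume: str
    region_labels: str
    region_names: str
    landmarks: str
    out_dir: str
    pixel_size: float = 1.0
    ppm: float = 5.0
    min_voxels: int = 5
    frac: float = 0.2
    ct_threshold: float | None = None
    seed: int = 0

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        missing = [f for f in REQUIRED_FIELDS if f not in d]
        if missing:
            raise ConfigError(f"config missing required fields: {missing}")
        cfg = cls(**d)
        if cfg.ppm <= 0:
            raise ConfigError("ppm tolerance must be > 0")
        for f in REQUIRED_FIELDS[:-1]:
            p = getattr(cfg, f)
            if not Path(p).exists():
                raise ConfigError(f"config field {f!r}: file not found: {p}")
        return cfg

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full workflow; returns the report bundle as a dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "neuromap3d",
        "version": neuromap3d.__version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "inputs": {},
        "stages": {},
        "complete": False,
    }
    for f in REQUIRED_FIELDS[:-1]:
        manifest["inputs"][f] = _sha256(getattr(config, f))

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 3),
                    "ok": exc_type is None,
                }
                (out / "MANIFEST.json").write_text(
                    json.dumps(manifest, indent=2)
                )
                if exc_type is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Timer()

    report: dict = {}
    with stage("catalog"):
        catalog = read_catalog_csv(config.catalog_csv)
        if not catalog:
            raise ValueError("empty catalog")

    with stage("msi_read"):
        z_positions, measured = read_z_table(config.z_table)
        z_measured = [z for z, m in zip(z_positions, measured) if m]
        sections = read_imzml(config.imzml, pixel_size=config.pixel_size)
        if len(sections) != len(z_measured):
            raise ValueError(
                f"{len(sections)} imzML sections vs "
                f"{len(z_measured)} measured z-table rows"
            )
        for s, z in zip(sections, z_measured):
            s.z_position = z
        sections = [tic_normalize(s) for s in sections]

    with stage("annotate"):
        hits = annotate_peaklist(pooled_peaklist(sections), catalog,
                                 tol=config.ppm)
        ann = annotation_report(hits)
        ann.to_csv(out / "annotation.csv", index=False)
        report["annotation"] = ann

    with stage("anatomy_load"):
        ct = load_ct_volume(config.ct_volume)
        regions = load_label_volume(config.region_labels,
                                    config.region_names)

    with stage("coregister"):
        landmarks = LandmarkSet.from_csv(config.landmarks)
        T, rms = estimate_similarity(landmarks)
        T.to_json(str(out / "transform.json"))
        report["transform"] = T
        report["rms_um"] = rms

    with stage("ion_volumes"):
        ion_ct = {}
        for h in hits:
            if not h.found:
                continue
            images = [
                extract_ion_image(s, h.calc_mz, config.ppm)
                for s in sections
            ]
            vol = stack_sections(images, z_measured, fill_gaps=True)
            ct_vol = apply_to_volume(
                vol, T, ct.data.shape, ct.voxel_size, ct.origin,
                interp="trilinear",
            )
            name = h.peptide.display_name
            ion_ct[name] = ct_vol
            safe = name.replace("/", "_").replace(" ", "_")
            save_volume_nrrd(ct_vol, str(out / f"ion_{safe}.nrrd"))

    with stage("presence"):
        pres = presence_table(ion_ct, regions,
                              min_voxels=config.min_voxels,
                              frac=config.frac)
        pres.to_csv(str(out / "presence.csv"))
        report["presence"] = pres

    with stage("volumetrics"):
        mask = segment_threshold(ct, thr=config.ct_threshold,
                                 min_component_voxels=27)
        _, total_mm3 = component_volume(mask, ct.voxel_size)
        regs = region_volumes(regions)
        brain_mm3 = sum(regs.values())
        vols = {
            "segmented_total_mm3": total_mm3,
            "region_mm3": regs,
            "regions_total_mm3": brain_mm3,
            "regions_over_segmented_pct": (
                volume_ratio(brain_mm3, total_mm3) if total_mm3 > 0 else None
            ),
        }
        (out / "volumes.json").write_text(json.dumps(vols, indent=2))
        report["volumes"] = vols

    manifest["complete"] = True
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    report["manifest"] = manifest
    return report
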