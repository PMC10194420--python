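"""Deterministic synthetic phantom: fake head CT + serial MSI sections.

The phantom emulates the study geometry end to end with known ground
truth: a contrasted "brain" ellipsoid inside a "head" ellipsoid in an
isotropic CT volume, labelled subregions (AL, OL, MB, CX, SEG by
default), and a serial MSI section stack related to CT space by a known
similarity pose.  Each MSI pixel whose CT-space position falls inside a
peptide's target regions receives a Gaussian-jittered peak at that
peptide's [M+H]+; background "lipid-like" species are seeded everywhere
(a brain-specific subset only inside the brain), drawn away from the
catalog m/z windows so that ground-truth presence is well defined.

``end_to_end`` runs the full pipeline — annotation, ion volumes,
stacking, landmark fitting, resampling, presence calls — against the
phantom and compares with its ground truth.  All randomness flows
through one seeded generator; a fixed config yields identical spectra,
volumes and tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from neuromap3d.anatomy import (
    CTVolume,
    PresenceTable,
    RegionLabelVolume,
    presence_table,
    region_volumes,
)
from neuromap3d.catalog import MaturePeptide
from neuromap3d.masscalc import annotate_peaklist, monoisotopic_mh
from neuromap3d.msi import MSISection, extract_ion_image
from neuromap3d.register import (
    LandmarkSet,
    SimilarityTransform,
    apply_to_volume,
    estimate_similarity,
)
from neuromap3d.volume import IonVolume, stack_sections


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class RegionSpec:
    """Ellipsoidal brain subregion: center offset from brain center (µm)."""

    name: str
    center: tuple[float, float, float]      # (z, y, x) offset, µm
    semiaxes: tuple[float, float, float]    # (z, y, x), µm


@dataclass(frozen=True)
class PeptidePlan:
    """One seeded peptide: where it occurs and how its peaks look."""

    peptide: MaturePeptide
    target_regions: tuple[str, ...]
    peak_sd: float = 0.001          # Da, Gaussian m/z jitter
    snr: float = 12.0               # signal over background intensity scale

    def __post_init__(self) -> None:
        if self.snr < 10:
            raise PhantomError("signal-to-background ratio must be >= 10")
        if self.peak_sd < 0:
            raise PhantomError("peak_sd must be >= 0")


def _default_regions() -> tuple[RegionSpec, ...]:
    r = (36.0, 36.0, 36.0)
    return (
        RegionSpec("AL", (0.0, -75.0, -75.0), r),
        RegionSpec("OL", (0.0, -75.0, 75.0), r),
        RegionSpec("MB", (0.0, 75.0, -75.0), r),
        RegionSpec("CX", (0.0, 75.0, 75.0), r),
        RegionSpec("SEG", (20.0, 0.0, 0.0), r),
    )


def _default_peptides() -> tuple[PeptidePlan, ...]:
    return (
        PeptidePlan(
            MaturePeptide("APMGFQGMR", amidated=True, name="TK1"),
            ("AL", "MB", "CX"),
        ),
        PeptidePlan(
            MaturePeptide("ITGQGNRLF", name="ITG-like"),
            ("OL", "CX", "SEG"),
        ),
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Full specification of a synthetic head + serial-MSI dataset.

    Defaults mirror the study conditions scaled to a desk-sized problem:
    10 µm sectioning with unmeasured (dropout) sections, tens-of-µm MSI
    raster, 300–3,000 Da mass range, isotropic CT voxels, and a modest
    similarity pose (rotation about the sectioning axis, proportional
    scale) between the section stack and CT space.
    """

    seed: int = 7
    # CT geometry (µm)
    ct_shape: tuple[int, int, int] = (60, 72, 72)       # (z, y, x) voxels
    voxel_size: float = 6.0
    head_semiaxes: tuple[float, float, float] = (150.0, 190.0, 190.0)
    brain_semiaxes: tuple[float, float, float] = (110.0, 160.0, 160.0)
    regions: tuple[RegionSpec, ...] = field(default_factory=_default_regions)
    # CT intensities
    ct_background: float = 20.0
    ct_head: float = 60.0
    ct_brain: float = 160.0
    ct_region: float = 200.0
    ct_noise_sd: float = 5.0
    # section plan
    n_sections: int = 12
    z_spacing: float = 10.0          # µm between sections
    pixel_size: float = 24.0         # µm MSI raster
    grid_shape: tuple[int, int] = (22, 22)
    dropout: tuple[int, ...] = (3, 8)   # sections cut but never measured
    # chemistry
    peptides: tuple[PeptidePlan, ...] = field(default_factory=_default_peptides)
    decoys: tuple[MaturePeptide, ...] = ()   # in the catalog, never seeded
    n_background: int = 40           # matrix/lipid species, everywhere
    n_brain_background: int = 20     # lipid species confined to the brain
    mz_range: tuple[float, float] = (300.0, 3000.0)
    guard_band: float = 0.05         # Da kept clear around catalog masses
    background_scale: float = 10.0   # base background intensity
    # pose of the section stack in CT space
    pose_rotation_deg: float = 10.0  # about the sectioning (z) axis
    pose_scale: float = 1.25
    landmark_noise_sd: float = 0.0   # µm, isotropic, 0 = exact landmarks

    def catalog(self) -> list[MaturePeptide]:
        return [pl.peptide for pl in self.peptides] + list(self.decoys)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, (frozenset, set)):
                return sorted(o)
            return str(o)
        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PhantomData:
    """Everything the phantom generated, plus its ground truth."""

    ct: CTVolume
    regions: RegionLabelVolume
    sections: list[MSISection]
    optical: list[np.ndarray]            # one image per section, all sections
    z_positions: list[float]             # µm, measured sections only
    optical_z_positions: list[float]     # µm, all sections
    landmarks: LandmarkSet
    true_pose: SimilarityTransform
    truth_presence: PresenceTable
    truth_region_volumes: dict[str, float]
    catalog: list[MaturePeptide]
    config_hash: str


def _ellipsoid_mask(shape, voxel, center, semiaxes):
    nz, ny, nx = shape
    z, y, x = np.meshgrid(
        np.arange(nz) * voxel, np.arange(ny) * voxel, np.arange(nx) * voxel,
        indexing="ij",
    )
    cz, cy, cx = center
    az, ay, ax = semiaxes
    return (
        ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2
    ) <= 1.0


def make_phantom(cfg: PhantomConfig) -> PhantomData:
    """Generate the synthetic CT volume, region labels and MSI sections."""
    rng = np.random.default_rng(cfg.seed)
    nz, ny, nx = cfg.ct_shape
    vox = cfg.voxel_size
    ct_center = ((nz - 1) / 2 * vox, (ny - 1) / 2 * vox, (nx - 1) / 2 * vox)

    head = _ellipsoid_mask(cfg.ct_shape, vox, ct_center, cfg.head_semiaxes)
    brain = _ellipsoid_mask(cfg.ct_shape, vox, ct_center, cfg.brain_semiaxes)

    labels = np.zeros(cfg.ct_shape, dtype=np.int32)
    name_map: dict[int, str] = {}
    for lab, spec in enumerate(cfg.regions, start=1):
        center = tuple(c + d for c, d in zip(ct_center, spec.center))
        mask = _ellipsoid_mask(cfg.ct_shape, vox, center, spec.semiaxes)
        if (mask & ~brain).any():
            raise PhantomError(
                f"region {spec.name!r} escapes the brain envelope"
            )
        if (labels[mask] != 0).any():
            raise PhantomError(f"region {spec.name!r} overlaps another region")
        labels[mask] = lab
        name_map[lab] = spec.name

    ct_data = np.full(cfg.ct_shape, cfg.ct_background)
    ct_data[head] = cfg.ct_head
    ct_data[brain] = cfg.ct_brain
    ct_data[labels > 0] = cfg.ct_region
    ct_data = ct_data + rng.normal(0.0, cfg.ct_noise_sd, cfg.ct_shape)
    ct = CTVolume(data=ct_data, voxel_size=vox)
    regions = RegionLabelVolume(labels=labels, name_map=name_map,
                                voxel_size=vox)

    # --- pose: rotation about z, proportional scale, brain-centred -------
    th = np.deg2rad(cfg.pose_rotation_deg)
    R = np.array(
        [[np.cos(th), -np.sin(th), 0.0],
         [np.sin(th), np.cos(th), 0.0],
         [0.0, 0.0, 1.0]]
    )
    rows, cols = cfg.grid_shape
    stack_center = np.array(
        [
            (cols - 1) / 2 * cfg.pixel_size,             # x
            (rows - 1) / 2 * cfg.pixel_size,             # y
            (cfg.n_sections - 1) / 2 * cfg.z_spacing,    # z
        ]
    )
    ct_center_xyz = np.array([ct_center[2], ct_center[1], ct_center[0]])
    t = ct_center_xyz - cfg.pose_scale * (R @ stack_center)
    pose = SimilarityTransform(R, cfg.pose_scale, t)

    # --- chemistry -------------------------------------------------------
    cat = cfg.catalog()
    targets = {p.display_name: monoisotopic_mh(p) for p in cat}
    lo, hi = cfg.mz_range
    avoid = sorted(targets.values())

    def draw_background(n):
        out = []
        while len(out) < n:
            mz = float(rng.uniform(lo, hi))
            if all(abs(mz - a) > cfg.guard_band for a in avoid):
                out.append(mz)
        return np.array(out)

    bg_mz = draw_background(cfg.n_background)
    brain_mz = draw_background(cfg.n_brain_background)
    plan_mz = {pl.peptide.display_name: targets[pl.peptide.display_name]
               for pl in cfg.peptides}
    region_of_name = {spec.name: lab + 1
                      for lab, spec in enumerate(cfg.regions)}
    targets_by_label: dict[int, list[PeptidePlan]] = {}
    for pl in cfg.peptides:
        for rname in pl.target_regions:
            if rname not in region_of_name:
                raise PhantomError(f"unknown target region {rname!r}")
            targets_by_label.setdefault(region_of_name[rname], []).append(pl)

    def ct_lookup(p_xyz):
        """CT voxel indices (z,y,x) of a physical (x,y,z) point, or None."""
        ix = int(round(p_xyz[0] / vox))
        iy = int(round(p_xyz[1] / vox))
        iz = int(round(p_xyz[2] / vox))
        if 0 <= iz < nz and 0 <= iy < ny and 0 <= ix < nx:
            return iz, iy, ix
        return None

    sections: list[MSISection] = []
    optical: list[np.ndarray] = []
    z_measured: list[float] = []
    z_all: list[float] = []
    for si in range(cfg.n_sections):
        z_m = si * cfg.z_spacing
        z_all.append(z_m)
        opt = np.zeros(cfg.grid_shape)
        spectra: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        measured = si not in cfg.dropout
        for r in range(rows):
            for c in range(cols):
                m = np.array([c * cfg.pixel_size, r * cfg.pixel_size, z_m])
                p = pose.apply(m)[0]
                idx = ct_lookup(p)
                in_brain = idx is not None and brain[idx]
                in_head = idx is not None and head[idx]
                lab = int(labels[idx]) if idx is not None else 0
                opt[r, c] = 1.0 if in_brain else (0.3 if in_head else 0.0)
                if not measured:
                    continue
                mzs = [bg_mz]
                ints = [cfg.background_scale * rng.uniform(0.5, 1.5,
                                                           len(bg_mz))]
                if in_brain:
                    mzs.append(brain_mz)
                    ints.append(
                        cfg.background_scale * rng.uniform(0.5, 1.5,
                                                           len(brain_mz))
                    )
                for pl in targets_by_label.get(lab, []):
                    mz0 = plan_mz[pl.peptide.display_name]
                    # truncated at 3 s.d. so every seeded peak stays inside
                    # the matching window of the default ppm tolerance
                    jit = (
                        float(np.clip(rng.normal(0.0, pl.peak_sd),
                                      -3 * pl.peak_sd, 3 * pl.peak_sd))
                        if pl.peak_sd else 0.0
                    )
                    mzs.append(np.array([mz0 + jit]))
                    ints.append(
                        np.array(
                            [pl.snr * cfg.background_scale
                             * rng.uniform(1.0, 1.5)]
                        )
                    )
                mz_arr = np.concatenate(mzs)
                in_arr = np.concatenate(ints)
                order = np.argsort(mz_arr)
                spectra[(r, c)] = (mz_arr[order], in_arr[order])
        optical.append(opt)
        if measured:
            sections.append(
                MSISection(
                    section_index=si,
                    grid_shape=cfg.grid_shape,
                    pixel_size=cfg.pixel_size,
                    spectra=spectra,
                    mz_range=cfg.mz_range,
                    z_position=z_m,
                )
            )
            z_measured.append(z_m)

    # --- landmarks: corresponding features, exact under the pose ---------
    fixed_pts = [ct_center_xyz]
    for spec in cfg.regions:
        fixed_pts.append(
            ct_center_xyz
            + np.array([spec.center[2], spec.center[1], spec.center[0]])
        )
    for ax, semi in ((0, cfg.head_semiaxes[2]), (1, cfg.head_semiaxes[1])):
        d = np.zeros(3)
        d[ax] = semi
        fixed_pts.extend([ct_center_xyz + d, ct_center_xyz - d])
    fixed = np.array(fixed_pts)
    moving = pose.inverse_apply(fixed)
    if cfg.landmark_noise_sd > 0:
        moving = moving + rng.normal(0.0, cfg.landmark_noise_sd,
                                     moving.shape)
    landmarks = LandmarkSet(moving=moving, fixed=fixed)

    # --- ground truth ----------------------------------------------------
    names = regions.region_names()
    truth = pd.DataFrame(
        {
            name: [name in pl.target_regions for pl in cfg.peptides]
            for name in names
        },
        index=[pl.peptide.display_name for pl in cfg.peptides],
    )
    truth_pt = PresenceTable(
        table=truth, parameters={"source": "phantom ground truth"}
    )
    return PhantomData(
        ct=ct,
        regions=regions,
        sections=sections,
        optical=optical,
        z_positions=z_measured,
        optical_z_positions=z_all,
        landmarks=landmarks,
        true_pose=pose,
        truth_presence=truth_pt,
        truth_region_volumes=region_volumes(regions),
        catalog=cat,
        config_hash=cfg.config_hash(),
    )


def write_phantom(data: PhantomData, cfg: PhantomConfig, outdir: str) -> dict:
    """Write a phantom dataset to disk in the toolkit's exchange formats.

    Emits imzML+ibd, CT and region-label NRRDs with a region name map,
    the landmark CSV, the section z table, ground-truth CSVs, the catalog
    CSV, and a ready-to-run pipeline config (``run.json``).  Returns the
    path map.
    """
    import tifffile

    from neuromap3d.anatomy import save_ct_volume
    from neuromap3d.catalog import write_catalog_csv
    from neuromap3d.msi import write_imzml
    from neuromap3d.volume import write_z_table
    import SimpleITK as sitk
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: str(out / v) for k, v in {
        "imzml": "msi.imzML",
        "z_table": "z_table.csv",
        "optical": "optical.tiff",
        "ct_volume": "ct.nrrd",
        "region_labels": "regions.nrrd",
        "region_names": "region_names.json",
        "landmarks": "landmarks.csv",
        "catalog_csv": "catalog.csv",
        "truth_presence": "truth_presence.csv",
        "truth_region_volumes": "truth_region_volumes.csv",
        "run_config": "run.json",
    }.items()}

    write_imzml(data.sections, paths["imzml"])
    measured = [z in data.z_positions for z in data.optical_z_positions]
    write_z_table(paths["z_table"], data.optical_z_positions, measured)
    tifffile.imwrite(paths["optical"],
                     np.asarray(data.optical, dtype=np.float32))
    save_ct_volume(data.ct, paths["ct_volume"])
    lab_img = sitk.GetImageFromArray(data.regions.labels.astype(np.int32))
    lab_img.SetSpacing((data.regions.voxel_size,) * 3)
    lab_img.SetOrigin(data.regions.origin)
    sitk.WriteImage(lab_img, paths["region_labels"])
    data.regions.save_name_map(paths["region_names"])
    data.landmarks.to_csv(paths["landmarks"])
    write_catalog_csv(data.catalog, paths["catalog_csv"])
    data.truth_presence.to_csv(paths["truth_presence"])
    pd.Series(data.truth_region_volumes, name="mm3").rename_axis(
        "region"
    ).to_csv(paths["truth_region_volumes"])
    run_cfg = {
        "catalog_csv": paths["catalog_csv"],
        "imzml": paths["imzml"],
        "z_table": paths["z_table"],
        "ct_volume": paths["ct_volume"],
        "region_labels": paths["region_labels"],
        "region_names": paths["region_names"],
        "landmarks": paths["landmarks"],
        "out_dir": str(out / "results"),
        "pixel_size": cfg.pixel_size,
        "ppm": 5.0,
        "min_voxels": 5,
        "frac": 0.2,
        "seed": cfg.seed,
    }
    Path(paths["run_config"]).write_text(json.dumps(run_cfg, indent=2))
    return paths


def pooled_peaklist(sections: list[MSISection]) -> list[tuple[float, float]]:
    """All (m/z, intensity) pairs of a dataset as one flat peak list."""
    peaks: list[tuple[float, float]] = []
    for s in sections:
        for (mz, inten) in s.spectra.values():
            peaks.extend(zip(map(float, mz), map(float, inten)))
    return peaks


def ion_volume_for(
    sections: list[MSISection],
    z_positions: list[float],
    mz: float,
    tol: float = 5.0,
) -> IonVolume:
    """Extract per-section ion images at ``mz`` and stack them."""
    images = [extract_ion_image(s, mz, tol) for s in sections]
    return stack_sections(images, z_positions, fill_gaps=True)


def end_to_end(
    cfg: PhantomConfig,
    tol: float = 5.0,
    min_voxels: int = 5,
    frac: float = 0.2,
) -> dict:
    """Run the full pipeline on a phantom and compare with ground truth.

    Stages: annotate the pooled peak list against the catalog, build an
    ion volume per annotated peptide, fit the similarity transform from
    the landmarks, resample every ion volume onto the CT grid with the
    single fitted transform, and call the presence table.  Returns the
    recovered artifacts plus the ground truth for comparison.
    """
    data = make_phantom(cfg)
    hits = annotate_peaklist(pooled_peaklist(data.sections), data.catalog,
                             tol=tol)
    T, rms = estimate_similarity(data.landmarks)
    ct_shape = data.ct.data.shape
    vox = data.ct.voxel_size
    ion_ct: dict[str, IonVolume] = {}
    for pl in cfg.peptides:
        vol = ion_volume_for(
            data.sections, data.z_positions,
            monoisotopic_mh(pl.peptide), tol=tol,
        )
        ion_ct[pl.peptide.display_name] = apply_to_volume(
            vol, T, ct_shape, vox, interp="trilinear"
        )
    recovered = presence_table(
        ion_ct, data.regions, min_voxels=min_voxels, frac=frac
    )
    return {
        "phantom": data,
        "hits": hits,
        "transform": T,
        "rms": rms,
        "ion_volumes_ct": ion_ct,
        "presence": recovered,
        "truth_presence": data.truth_presence,
        "presence_matches_truth": recovered.table.equals(
            data.truth_presence.table
        ),
    }
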