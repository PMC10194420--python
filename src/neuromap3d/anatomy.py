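"""CT anatomy: segmentation, volumetrics and peptide-by-region presence.

MicroCT of contrast-stained heads yields isotropic-voxel volumes in
which nervous tissue is bright.  This module thresholds and cleans such
volumes into masks, measures component volumes in mm³ (head capsule,
brain) and their percentage ratios, consumes region label volumes
(antennal lobe AL, optic lobe OL, mushroom bodies MB, central complex
CX, subesophageal ganglion SEG, ...), and reduces CT-space ion volumes
to a peptide x region presence/absence table under an explicit, recorded
detection rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk
from skimage import filters, measure

from neuromap3d.volume import IonVolume


class AnatomyError(ValueError):
    pass


@dataclass
class CTVolume:
    """Isotropic-voxel CT intensity volume ([z, y, x], µm units)."""

    data: np.ndarray
    voxel_size: float                  # µm, identical along all axes
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.voxel_size <= 0:
            raise AnatomyError("voxel_size must be > 0")
        if self.data.ndim != 3:
            raise AnatomyError("CT volume must be 3D")

    @property
    def grid(self) -> tuple[tuple[int, int, int], float, tuple]:
        return self.data.shape, self.voxel_size, self.origin


@dataclass
class RegionLabelVolume:
    """Integer-labelled brain regions on a CT grid (0 = background)."""

    labels: np.ndarray
    name_map: dict[int, str]
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise AnatomyError("labels must be integer")
        present = set(np.unique(self.labels)) - {0}
        unnamed = present - set(self.name_map)
        if unnamed:
            raise AnatomyError(f"unnamed labels: {sorted(unnamed)}")

    def region_names(self) -> list[str]:
        return [self.name_map[k] for k in sorted(self.name_map)]

    def save_name_map(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({str(k): v for k, v in self.name_map.items()}, fh,
                      indent=2)


@dataclass
class PresenceTable:
    """Peptide x region detection matrix with its detection parameters."""

    table: pd.DataFrame            # bool, index=peptide, columns=region
    parameters: dict

    def __post_init__(self) -> None:
        if not self.parameters:
            raise AnatomyError("detection parameters must be recorded")

    def to_csv(self, path: str) -> None:
        """Write with '+' (presence) / '−' (absence) cells."""
        out = self.table.replace({True: "+", False: "−"})
        out.to_csv(path)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceTable):
            return NotImplemented
        return self.table.equals(other.table)


def load_ct_volume(path: str) -> CTVolume:
    """Read a CT volume (NRRD/MetaImage/...); requires isotropic voxels."""
    img = sitk.ReadImage(path)
    sx, sy, sz = img.GetSpacing()
    if not (np.isclose(sx, sy) and np.isclose(sx, sz)):
        raise AnatomyError(f"anisotropic voxels {img.GetSpacing()}")
    return CTVolume(
        data=sitk.GetArrayFromImage(img).astype(float),
        voxel_size=float(sx),
        origin=tuple(img.GetOrigin()),
    )


def save_ct_volume(ct: CTVolume, path: str) -> None:
    img = sitk.GetImageFromArray(ct.data.astype(np.float32))
    img.SetSpacing((ct.voxel_size,) * 3)
    img.SetOrigin(ct.origin)
    sitk.WriteImage(img, path)


def load_label_volume(path: str, name_map_path: str) -> RegionLabelVolume:
    img = sitk.ReadImage(path)
    with open(name_map_path) as fh:
        nm = {int(k): v for k, v in json.load(fh).items()}
    return RegionLabelVolume(
        labels=sitk.GetArrayFromImage(img).astype(np.int32),
        name_map=nm,
        voxel_size=float(img.GetSpacing()[0]),
        origin=tuple(img.GetOrigin()),
    )


def segment_threshold(
    ct: CTVolume,
    thr: float | None = None,
    min_component_voxels: int = 0,
) -> np.ndarray:
    """Threshold a CT volume and drop small connected components.

    Voxels >= ``thr`` (Otsu's threshold when not given) are kept, then
    26-connected components smaller than ``min_component_voxels`` are
    removed.  An empty result is returned with a warning, not an error.
    """
    if thr is None:
        thr = float(filters.threshold_otsu(ct.data))
    mask = ct.data >= thr
    if min_component_voxels > 0 and mask.any():
        lab = measure.label(mask, connectivity=3)
        counts = np.bincount(lab.ravel())
        keep = np.nonzero(counts >= min_component_voxels)[0]
        keep = keep[keep != 0]
        mask = np.isin(lab, keep)
    if not mask.any():
        warnings.warn("segment_threshold: empty mask")
    return mask


def component_volume(
    mask: np.ndarray, voxel_size: float
) -> tuple[dict[int, float], float]:
    """Volumes (mm³) of the 26-connected components of a mask.

    Volume = voxel count x voxel_size³ (µm³), converted to mm³ (x 1e-9).
    Returns (per-component volumes keyed by component label, total).
    """
    if voxel_size <= 0:
        raise AnatomyError("voxel_size must be > 0")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return {}, 0.0
    lab = measure.label(mask, connectivity=3)
    counts = np.bincount(lab.ravel())
    scale = (voxel_size ** 3) * 1e-9
    per = {
        int(i): float(c) * scale
        for i, c in enumerate(counts)
        if i != 0 and c > 0
    }
    return per, float(mask.sum()) * scale


def volume_ratio(a: float, b: float) -> float:
    """Percentage ratio 100·a/b (e.g. brain volume over head volume)."""
    if b <= 0:
        raise AnatomyError("denominator volume must be > 0")
    return 100.0 * a / b


def region_volumes(regions: RegionLabelVolume) -> dict[str, float]:
    """Volume (mm³) of every named region."""
    counts = np.bincount(regions.labels.ravel())
    scale = (regions.voxel_size ** 3) * 1e-9
    return {
        name: float(counts[lab]) * scale if lab < len(counts) else 0.0
        for lab, name in sorted(regions.name_map.items())
    }


def presence_table(
    ion_volumes: dict[str, IonVolume],
    regions: RegionLabelVolume,
    min_voxels: int = 5,
    frac: float = 0.2,
) -> PresenceTable:
    """Call peptide presence per brain region from CT-space ion volumes.

    A peptide is present in a region iff at least ``min_voxels`` measured
    voxels of that region exceed ``frac`` x the peptide volume's global
    max.  Only voxels marked measured (``meta['voxel_mask']``) count.
    The rule is monotone: raising either threshold never turns an absent
    call into a present one.
    """
    if not (0 <= frac <= 1):
        raise AnatomyError("frac must be in [0, 1]")
    names = regions.region_names()
    rows = {}
    for pep, vol in ion_volumes.items():
        if vol.data.shape != regions.labels.shape:
            raise AnatomyError(
                f"ion volume for {pep!r} not aligned to the region grid: "
                f"{vol.data.shape} vs {regions.labels.shape}"
            )
        meas = vol.meta.get("voxel_mask")
        if meas is None:
            meas = np.ones(vol.data.shape, dtype=bool)
            meas[~vol.plane_mask] = False
        vmax = vol.data[meas].max() if meas.any() else 0.0
        row = {}
        for lab, name in sorted(regions.name_map.items()):
            if vmax <= 0:
                row[name] = False
                continue
            sel = (regions.labels == lab) & meas
            n_hot = int((vol.data[sel] > frac * vmax).sum())
            row[name] = n_hot >= max(min_voxels, 1)
        rows[pep] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    return PresenceTable(
        table=table,
        parameters={"min_voxels": min_voxels, "frac": frac},
    )
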