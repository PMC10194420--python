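"""Serial-section assembly into anisotropic 3D volumes.

Serial MSI sections are acquired tens of micrometres apart while pixels
are tens of micrometres wide, so stacks are strongly anisotropic.  Planes
are placed on a uniform z grid from their documented physical z
positions; sections that were cut but never measured leave gaps, which
are filled with empty (zero) planes carried as ``plane_mask = False`` so
downstream statistics can distinguish "not measured" from "measured
zero".  No interpolation happens at this stage.

Coordinate convention: arrays are indexed [plane, row, col]; physical
coordinates are right-handed (x = columns, y = rows, z = sectioning
order), voxel-center, micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from neuromap3d.msi import IonImage


class VolumeError(ValueError):
    pass


@dataclass
class IonVolume:
    """Anisotropic stack of per-section images with a measured-plane mask."""

    data: np.ndarray                 # planes x rows x cols, >= 0, finite
    plane_mask: np.ndarray           # bool per plane; False = gap-filled
    pixel_size: float                # µm in-plane
    z_spacing: float                 # µm between consecutive planes
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # µm, (x, y, z)
    mz_center: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.plane_mask = np.asarray(self.plane_mask, dtype=bool)
        if self.z_spacing <= 0:
            raise VolumeError("z_spacing must be > 0")
        if self.data.ndim != 3:
            raise VolumeError("data must be planes x rows x cols")
        if len(self.plane_mask) != self.data.shape[0]:
            raise VolumeError("plane_mask length must equal plane count")
        if not np.isfinite(self.data).all() or (self.data < 0).any():
            raise VolumeError("intensities must be finite and >= 0")
        if self.data[~self.plane_mask].any():
            raise VolumeError("gap-filled planes must be all zero")

    @property
    def depth(self) -> int:
        return self.data.shape[0]

    def physical_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center physical coordinates (x, y, z arrays, µm)."""
        ox, oy, oz = self.origin
        z = oz + np.arange(self.depth) * self.z_spacing
        y = oy + np.arange(self.data.shape[1]) * self.pixel_size
        x = ox + np.arange(self.data.shape[2]) * self.pixel_size
        return x, y, z


def stack_sections(
    images: list[IonImage] | list[np.ndarray],
    z_positions: list[float],
    fill_gaps: bool = True,
    pixel_size: float | None = None,
    z_spacing: float | None = None,
) -> IonVolume:
    """Place section images on a uniform z grid, zero-filling gaps.

    ``z_positions`` (µm) must be strictly increasing and multiples of a
    common spacing; the spacing is inferred as the greatest common
    divisor of the gaps unless given.  Plane index = (z - z0)/z_spacing;
    indices without an input section are zero planes with
    ``plane_mask = False`` (only allowed when ``fill_gaps``).  Input
    intensities are preserved bit-exactly.
    """
    if len(images) == 0:
        raise VolumeError("no images to stack")
    if len(images) != len(z_positions):
        raise VolumeError("images and z_positions length mismatch")
    z = np.asarray(z_positions, dtype=float)
    if len(z) > 1 and not (np.diff(z) > 0).all():
        raise VolumeError("z_positions must be strictly increasing")

    arrays = []
    mz_center = None
    for im in images:
        if isinstance(im, IonImage):
            arrays.append(np.asarray(im.intensities, dtype=float))
            if pixel_size is None and im.pixel_size:
                pixel_size = im.pixel_size
            mz_center = im.mz_center
        else:
            arrays.append(np.asarray(im, dtype=float))
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise VolumeError(f"inconsistent image shapes: {a.shape} vs {shape}")
    if pixel_size is None:
        raise VolumeError("pixel_size required for plain-array input")

    if z_spacing is None:
        if len(z) == 1:
            z_spacing = pixel_size  # arbitrary but positive; single plane
        else:
            diffs = np.diff(z)
            z_spacing = float(diffs[0])
            for d in diffs[1:]:
                z_spacing = float(np.gcd(
                    np.round(z_spacing * 1000).astype(int),
                    np.round(d * 1000).astype(int),
                )) / 1000.0
    idx = (z - z[0]) / z_spacing
    idx_int = np.round(idx).astype(int)
    if not np.allclose(idx, idx_int, atol=1e-6):
        raise VolumeError(
            f"z_positions are not multiples of z_spacing={z_spacing}"
        )
    depth = int(idx_int[-1]) + 1
    if depth > len(images) and not fill_gaps:
        raise VolumeError("non-uniform z grid requires fill_gaps=True")
    data = np.zeros((depth,) + shape)
    mask = np.zeros(depth, dtype=bool)
    for a, i in zip(arrays, idx_int):
        data[i] = a
        mask[i] = True
    first = images[0]
    origin_z = float(z[0])
    return IonVolume(
        data=data,
        plane_mask=mask,
        pixel_size=float(pixel_size),
        z_spacing=float(z_spacing),
        origin=(0.0, 0.0, origin_z),
        mz_center=mz_center,
    )


def threshold_volume(v: IonVolume, frac: float) -> np.ndarray:
    """Binary mask: intensity >= frac x global max, on measured planes only."""
    if not (0 < frac <= 1):
        raise VolumeError("frac must be in (0, 1]")
    vmax = v.data[v.plane_mask].max() if v.plane_mask.any() else 0.0
    if vmax <= 0:
        raise VolumeError("threshold_volume: volume has no positive maximum")
    mask = v.data >= frac * vmax
    mask[~v.plane_mask] = False
    return mask


def transparency_map(v: IonVolume, frac: float = 0.0) -> np.ndarray:
    """Per-voxel opacity in [0, 1]: linear ramp to the max, clipped below.

    Opacity = intensity/max, except values below ``frac`` are forced to 0
    so that low-intensity voxels render fully transparent.
    """
    vmax = v.data[v.plane_mask].max() if v.plane_mask.any() else 0.0
    if vmax <= 0:
        return np.zeros_like(v.data)
    alpha = np.clip(v.data / vmax, 0.0, 1.0)
    alpha[alpha < frac] = 0.0
    alpha[~v.plane_mask] = 0.0
    return alpha


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_z_table(path: str, z_positions: list[float],
                  measured: list[bool] | None = None) -> None:
    """Sidecar CSV (section_index,z_um,measured) documenting z positions."""
    n = len(z_positions)
    measured = measured if measured is not None else [True] * n
    pd.DataFrame(
        {"section_index": range(n), "z_um": z_positions, "measured": measured}
    ).to_csv(path, index=False)


def read_z_table(path: str) -> tuple[list[float], list[bool]]:
    df = pd.read_csv(path)
    for col in ("section_index", "z_um", "measured"):
        if col not in df.columns:
            raise VolumeError(f"z table missing column {col!r}")
    df = df.sort_values("section_index")
    return list(df["z_um"].astype(float)), list(df["measured"].astype(bool))


def save_volume_nrrd(v: IonVolume, path: str) -> None:
    """Write a volume as NRRD with physical spacing/origin in µm."""
    img = sitk.GetImageFromArray(v.data)
    img.SetSpacing((v.pixel_size, v.pixel_size, v.z_spacing))
    img.SetOrigin(v.origin)
    sitk.WriteImage(img, path)


def load_volume_nrrd(path: str) -> IonVolume:
    img = sitk.ReadImage(path)
    data = sitk.GetArrayFromImage(img).astype(float)
    sx, sy, sz = img.GetSpacing()
    return IonVolume(
        data=data,
        plane_mask=np.ones(data.shape[0], dtype=bool),
        pixel_size=float(sx),
        z_spacing=float(sz),
        origin=tuple(img.GetOrigin()),
    )


def save_volume_tiff(v: IonVolume, path: str) -> None:
    """Write the plane stack as a 32-bit float multi-page TIFF."""
    tifffile.imwrite(path, v.data.astype(np.float32))
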