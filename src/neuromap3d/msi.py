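"""2D mass-spectrometry-imaging processing.

Sections are rastered grids of sparse centroided spectra (per-pixel
(m/z, intensity) arrays).  The operations here mirror the standard MSI
workflow for high-mass-resolution data: TIC normalisation to the section
median, dataset mean spectra on a binned axis, ion-image extraction at
ppm (or Da) tolerance, and an unsupervised spatial segmentation of the
full data by k-means over median-smoothed channel images.

Missing pixels (never measured, or empty spectra) are carried as an
explicit mask and never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter
from scipy import ndimage
from sklearn.cluster import KMeans


class MSIError(ValueError):
    pass


@dataclass
class MSISection:
    """One serial MSI section: a grid of sparse spectra.

    ``spectra`` maps (row, col) -> (mz array, intensity array); pixels
    absent from the dict (or with empty arrays) are missing.  ``tic_flags``
    records pixels whose TIC was zero at normalisation time.
    """

    section_index: int
    grid_shape: tuple[int, int]
    pixel_size: float                      # µm, in-plane
    spectra: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]
    mz_range: tuple[float, float] = (300.0, 3000.0)
    z_position: float = 0.0                # µm
    tic_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise MSIError("pixel_size must be > 0")
        rows, cols = self.grid_shape
        if len(self.spectra) > rows * cols:
            raise MSIError("more spectra than grid pixels")
        lo, hi = self.mz_range
        for (r, c), (mz, inten) in self.spectra.items():
            if not (0 <= r < rows and 0 <= c < cols):
                raise MSIError(f"pixel ({r},{c}) outside grid {self.grid_shape}")
            if len(mz) and (mz.min() < lo or mz.max() > hi):
                raise MSIError(
                    f"pixel ({r},{c}): m/z outside range {self.mz_range}"
                )

    def measured_mask(self) -> np.ndarray:
        """Boolean grid: True where a non-empty spectrum was acquired."""
        mask = np.zeros(self.grid_shape, dtype=bool)
        for (r, c), (mz, _) in self.spectra.items():
            if len(mz):
                mask[r, c] = True
        return mask


@dataclass
class IonImage:
    """Per-section intensity map of one m/z window."""

    section_index: int
    mz_center: float
    tol: float
    tol_unit: str                          # "ppm" or "Da"
    intensities: np.ndarray                # rows x cols, float
    mask: np.ndarray                       # True where measured
    pixel_size: float = 0.0
    z_position: float = 0.0


def write_imzml(sections: list[MSISection], path: str) -> None:
    """Write sections to a processed-mode imzML/ibd pair.

    The 1-based imzML z coordinate stores ``section_index + 1``; physical
    z positions and pixel sizes travel in a sidecar table (see
    :mod:`neuromap3d.volume`).
    """
    with ImzMLWriter(path, mode="processed",
                     intensity_dtype=np.float64) as w:
        for s in sections:
            for (r, c), (mz, inten) in sorted(s.spectra.items()):
                if len(mz) == 0:
                    continue  # empty spectra round-trip as missing pixels
                w.addSpectrum(mz, inten, (c + 1, r + 1, s.section_index + 1))


def read_imzml(
    path: str,
    pixel_size: float = 1.0,
    z_positions: dict[int, float] | None = None,
    mz_range: tuple[float, float] | None = None,
) -> list[MSISection]:
    """Read an imzML file into per-z-coordinate sections.

    Pixels are mapped to 0-based row/col; spectra are grouped into
    sections by the imzML z coordinate.  ``z_positions`` optionally maps
    section_index -> physical z (µm); default is index order.
    """
    parser = ImzMLParser(path)
    by_z: dict[int, dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]] = {}
    lo, hi = np.inf, -np.inf
    for i, (x, y, z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        by_z.setdefault(z - 1, {})[(y - 1, x - 1)] = (mz, inten)
        if len(mz):
            lo = min(lo, mz.min())
            hi = max(hi, mz.max())
    if mz_range is None:
        mz_range = (lo, hi) if np.isfinite(lo) else (0.0, np.inf)
    sections = []
    for zi in sorted(by_z):
        spectra = by_z[zi]
        rows = 1 + max(r for r, _ in spectra)
        cols = 1 + max(c for _, c in spectra)
        zpos = z_positions[zi] if z_positions else float(zi)
        sections.append(
            MSISection(
                section_index=zi,
                grid_shape=(rows, cols),
                pixel_size=pixel_size,
                spectra=spectra,
                mz_range=mz_range,
                z_position=zpos,
            )
        )
    return sections


def tic_normalize(section: MSISection) -> MSISection:
    """Scale each spectrum to the section's median total ion count.

    Every non-empty spectrum is multiplied by (median TIC)/(own TIC), so
    all spectra end up with the same TIC (the section median, numpy
    mid-point convention for even counts).  Zero-TIC spectra are left
    untouched and flagged in ``tic_flags``.
    """
    tics = {
        pc: float(inten.sum()) for pc, (mz, inten) in section.spectra.items()
    }
    positive = [t for t in tics.values() if t > 0]
    if not positive:
        raise MSIError("tic_normalize: all spectra have zero TIC")
    target = float(np.median(positive))
    new_spectra = {}
    flags = set(section.tic_flags)
    for pc, (mz, inten) in section.spectra.items():
        t = tics[pc]
        if t > 0:
            new_spectra[pc] = (mz, inten * (target / t))
        else:
            new_spectra[pc] = (mz, inten)
            flags.add(pc)
    return replace(section, spectra=new_spectra, tic_flags=flags)


def mean_spectrum(
    sections: list[MSISection], bin_width: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Dataset mean spectrum on a common binned m/z axis.

    Intensities are accumulated into ``bin_width``-wide bins and averaged
    over all non-missing pixels of all sections.  Returns (bin centers,
    mean intensity) for the occupied extent of the axis.
    """
    if bin_width <= 0:
        raise MSIError("bin_width must be > 0")
    if not sections:
        raise MSIError("mean_spectrum: no sections")
    lo = min(s.mz_range[0] for s in sections)
    acc: dict[int, float] = {}
    n_pixels = 0
    for s in sections:
        for (r, c), (mz, inten) in s.spectra.items():
            if len(mz) == 0:
                continue
            n_pixels += 1
            idx = np.floor((mz - lo) / bin_width).astype(int)
            for i, v in zip(idx, inten):
                acc[i] = acc.get(i, 0.0) + float(v)
    if n_pixels == 0:
        raise MSIError("mean_spectrum: no measured pixels")
    if not acc:
        return np.array([]), np.array([])
    imax = max(acc)
    imin = min(acc)
    centers = lo + (np.arange(imin, imax + 1) + 0.5) * bin_width
    mean = np.zeros(imax - imin + 1)
    for i, v in acc.items():
        mean[i - imin] = v / n_pixels
    return centers, mean


def extract_ion_image(
    section: MSISection,
    mz: float,
    tol: float = 5.0,
    tol_unit: str = "ppm",
) -> IonImage:
    """Sum per-pixel intensity inside an m/z window around ``mz``.

    The window is mz·(1 ± tol·1e-6) for ppm tolerance, mz ± tol for Da.
    Missing pixels are masked out rather than set to zero.
    """
    lo_r, hi_r = section.mz_range
    if not (lo_r <= mz <= hi_r):
        raise MSIError(f"m/z {mz} outside section range ({lo_r}, {hi_r})")
    if tol <= 0:
        raise MSIError("tolerance must be > 0")
    if tol_unit == "ppm":
        lo, hi = mz * (1 - tol * 1e-6), mz * (1 + tol * 1e-6)
    elif tol_unit == "Da":
        lo, hi = mz - tol, mz + tol
    else:
        raise MSIError(f"unknown tolerance unit {tol_unit!r}")
    img = np.zeros(section.grid_shape)
    mask = np.zeros(section.grid_shape, dtype=bool)
    for (r, c), (mzs, inten) in section.spectra.items():
        if len(mzs) == 0:
            continue
        mask[r, c] = True
        sel = (mzs >= lo) & (mzs <= hi)
        if sel.any():
            img[r, c] = float(inten[sel].sum())
    return IonImage(
        section_index=section.section_index,
        mz_center=mz,
        tol=tol,
        tol_unit=tol_unit,
        intensities=img,
        mask=mask,
        pixel_size=section.pixel_size,
        z_position=section.z_position,
    )


def spatial_cluster(
    sections: list[MSISection],
    k: int,
    seed: int = 0,
    bin_width: float = 0.01,
    max_channels: int = 300,
    smooth: bool = True,
) -> list[np.ndarray]:
    """Segment pixels by chemistry: k-means over smoothed channel images.

    Spectra are TIC-normalised and binned; the ``max_channels`` most
    intense bins (dataset-wide) become channel images, each smoothed with
    a 3x3 spatial median filter, and the per-pixel channel vectors are
    clustered with k-means.  Deterministic for a fixed seed.  Returns one
    label image per section (missing pixels = -1).
    """
    if k < 1:
        raise MSIError("k must be >= 1")
    normed = [tic_normalize(s) for s in sections]
    lo = min(s.mz_range[0] for s in normed)
    totals: dict[int, float] = {}
    for s in normed:
        for (r, c), (mz, inten) in s.spectra.items():
            if len(mz) == 0:
                continue
            idx = np.floor((mz - lo) / bin_width).astype(int)
            for i, v in zip(idx, inten):
                totals[i] = totals.get(i, 0.0) + float(v)
    if not totals:
        raise MSIError("spatial_cluster: no measured pixels")
    channels = sorted(totals, key=lambda i: -totals[i])[:max_channels]
    chan_pos = {b: j for j, b in enumerate(channels)}
    feats = []
    coords = []
    for si, s in enumerate(normed):
        imgs = np.zeros((len(channels),) + s.grid_shape)
        meas = s.measured_mask()
        for (r, c), (mz, inten) in s.spectra.items():
            if len(mz) == 0:
                continue
            idx = np.floor((mz - lo) / bin_width).astype(int)
            for i, v in zip(idx, inten):
                j = chan_pos.get(i)
                if j is not None:
                    imgs[j, r, c] += float(v)
        if smooth:
            for j in range(len(channels)):
                imgs[j] = ndimage.median_filter(imgs[j], size=3)
        rr, cc = np.nonzero(meas)
        for r, c in zip(rr, cc):
            feats.append(imgs[:, r, c])
            coords.append((si, r, c))
    feats = np.asarray(feats)
    if len(feats) < k:
        raise MSIError(f"k={k} exceeds the {len(feats)} measured pixels")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(feats)
    out = [np.full(s.grid_shape, -1, dtype=int) for s in normed]
    for (si, r, c), lab in zip(coords, labels):
        out[si][r, c] = int(lab)
    return out
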